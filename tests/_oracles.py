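"""Independent reference implementations used only to cross-check the
package: deliberately written in a different style (explicit enumeration)
from the production code."""

from __future__ import annotations

import itertools
import math
from bisect import bisect_left
from collections import Counter

import numpy as np

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def alignment_score_oracle(mirna: str, site: str, cfg) -> float:
    """Minimum alignment penalty by explicit enumeration of every alignment
    structure: a set of unpaired miRNA positions (gaps), a multiset of
    internal site-bulge slots, and the site offset of the aligned block.
    Site overhangs on both sides are free; gap/bulge penalties are charged
    at the weight of the next miRNA position."""
    m = mirna.upper().replace("U", "T")
    s = site.upper().replace("U", "T")
    L, n = len(m), len(s)
    srev = s[::-1]

    def w(i: int) -> float:  # 1-based miRNA position weight
        return (
            cfg.seed_multiplier
            if cfg.seed_start <= i <= cfg.seed_end
            else 1.0
        )

    def pair_cost(a: str, b: str) -> float:
        if (a, b) in _WC:
            return 0.0
        if (a, b) in _WOBBLE:
            return cfg.wobble
        return cfg.mismatch

    best = math.inf
    G = cfg.max_gaps
    for gm in range(G + 1):
        for gap_set in itertools.combinations(range(1, L + 1), gm):
            gaps = set(gap_set)
            for gs in range(G + 1 - gm):
                for slots in itertools.combinations_with_replacement(
                    range(1, L), gs
                ):
                    bulge_at = Counter(slots)
                    consumed = (L - gm) + gs
                    if consumed > n:
                        continue
                    for q0 in range(n - consumed + 1):
                        cost, q = 0.0, q0
                        for i in range(1, L + 1):
                            if i in gaps:
                                cost += w(i) * cfg.gap
                            else:
                                cost += w(i) * pair_cost(m[i - 1], srev[q])
                                q += 1
                            for _ in range(bulge_at.get(i, 0)):
                                cost += w(i + 1) * cfg.gap
                                q += 1
                        if cost < best:
                            best = cost
    return best


def longest_orf_oracle(seq: str) -> tuple[int, int, int]:
    """All-starts scan: from every ATG walk codon by codon to the first stop;
    longest ORF wins, ties to the smallest start. Returns
    (start_1based, length_nt, length_aa), zeros when none."""
    s = seq.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    best = (0, 0, 0)
    for a in range(len(s) - 2):
        if s[a : a + 3] != "ATG":
            continue
        j = a + 3
        while j + 3 <= len(s):
            if s[j : j + 3] in stops:
                length = j + 3 - a
                if length > best[1]:
                    best = (a + 1, length, length // 3 - 1)
                break
            j += 3
    return best


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values by the textbook step-up rule:
    sort ascending, q_i = p_i * m / i, enforce monotonicity from the largest
    rank downward, cap at 1, restore the input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return np.minimum(q, 1.0)


def hypergeom_enumeration_table(M: int) -> dict[tuple[int, int, int], float]:
    """P(X >= k) for X ~ HG(M, K, n) for every (K, n, k), by enumerating all
    n-subsets of range(M) against the fixed K-set {0..K-1}. Overlap with the
    first-K prefix is a bisect, so one subset enumeration serves all K."""
    out: dict[tuple[int, int, int], float] = {}
    for n in range(M + 1):
        # counts[K][overlap] over all n-subsets
        counts = [[0] * (M + 1) for _ in range(M + 1)]
        total = 0
        for subset in itertools.combinations(range(M), n):
            total += 1
            for K in range(M + 1):
                counts[K][bisect_left(subset, K)] += 1
        for K in range(M + 1):
            upper = 0
            for k in range(min(K, n), -1, -1):
                upper += counts[K][k]
                out[(K, n, k)] = upper / total
    return out
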