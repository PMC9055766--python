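"""miRNA, cis and trans target prediction.

miRNA targets use plant-style complementarity scoring (the TargetFinder
convention): the miRNA is aligned antiparallel against the candidate site,
each miRNA position contributing 0 for a Watson–Crick pair, 0.5 for a G:U
wobble and 1.0 for a mismatch or gap, with penalties doubled over miRNA
positions 2–13 from the 5' end (the seed-proximal region); the site score is
the minimum total penalty over gapped alignments (at most two gaps). lncRNA
cis targets are genes within a genomic window (default 100 kb) of the lncRNA
locus; trans targets use a documented complementarity surrogate for
free-energy pairing tools: the best ungapped window of Watson–Crick pairing
fraction (G:U counting one half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .annotation_io import GenomicInterval, TranscriptRecord

_BASES = "ACGTN"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Watson–Crick pairs and G:U wobbles, expressed as (miRNA base, site base)
WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character {exc} in sequence") from exc


def _normalize(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(_BASES)
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)} in {what}")
    return s


@dataclass(frozen=True)
class ScoringConfig:
    """Plant miRNA-target penalty scheme (TargetFinder-style defaults)."""

    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 1.0
    seed_start: int = 2  # 1-based miRNA positions with doubled penalties
    seed_end: int = 13
    seed_multiplier: float = 2.0
    max_gaps: int = 2


DEFAULT_SCORING = ScoringConfig()
UNIFORM_SCORING = ScoringConfig(seed_multiplier=1.0)


def _pair_cost_table(cfg: ScoringConfig) -> np.ndarray:
    """cost[miRNA base, site base]; N never pairs."""
    t = np.full((5, 5), cfg.mismatch)
    for m, s in WC_PAIRS:
        t[_CODE[m], _CODE[s]] = 0.0
    for m, s in WOBBLE_PAIRS:
        t[_CODE[m], _CODE[s]] = cfg.wobble
    return t


def _position_weights(length: int, cfg: ScoringConfig) -> np.ndarray:
    w = np.ones(length + 1)  # 1-based indexing; w[0] unused
    lo = max(1, cfg.seed_start)
    hi = min(length, cfg.seed_end)
    if hi >= lo:
        w[lo : hi + 1] = cfg.seed_multiplier
    return w


def mirna_target_score(
    mirna: str, site: str, cfg: ScoringConfig | None = None
) -> float:
    """Minimum alignment penalty of a miRNA (5'→3') against a candidate
    site, antiparallel, with free site overhangs at both ends and at most
    ``cfg.max_gaps`` gaps. Gap penalties are charged at the weight of the
    next miRNA position. Returns ``inf`` when no alignment fits the gap
    budget (site shorter than the miRNA by more than the budget).
    """
    cfg = cfg or DEFAULT_SCORING
    m = _normalize(mirna, "miRNA")
    s = _normalize(site, "site")
    if not 18 <= len(m) <= 26:
        raise ValueError(f"miRNA length {len(m)} outside 18–26 nt")
    L, n = len(m), len(s)
    srev = s[::-1]  # miRNA position i pairs site read 3'→5'
    cost = _pair_cost_table(cfg)
    w = _position_weights(L, cfg)
    mi = [_CODE[b] for b in m]
    qi = [_CODE[b] for b in srev]
    G = cfg.max_gaps
    INF = math.inf

    # dp[g][i][q]: min penalty with i miRNA and q site bases consumed, g gaps
    dp = [[[INF] * (n + 1) for _ in range(L + 1)] for _ in range(G + 1)]
    for q in range(n + 1):
        dp[0][0][q] = 0.0  # free leading site overhang
    for g in range(G + 1):
        for i in range(L + 1):
            row = dp[g][i]
            for q in range(n + 1):
                cur = row[q]
                if cur == INF:
                    continue
                if i < L and q < n:  # pair
                    c = cur + w[i + 1] * cost[mi[i]][qi[q]]
                    if c < dp[g][i + 1][q + 1]:
                        dp[g][i + 1][q + 1] = c
                if g < G:
                    if i < L:  # miRNA base unpaired (gap in site)
                        c = cur + w[i + 1] * cfg.gap
                        if c < dp[g + 1][i + 1][q]:
                            dp[g + 1][i + 1][q] = c
                    if q < n and 0 < i < L:  # site base bulged internally
                        c = cur + w[i + 1] * cfg.gap
                        if c < dp[g + 1][i][q + 1]:
                            dp[g + 1][i][q + 1] = c
    # free trailing site overhang: min over remaining site bases
    return min(dp[g][L][q] for g in range(G + 1) for q in range(n + 1))


@dataclass(frozen=True)
class TargetHit:
    """One regulator→target relationship.

    ``score`` semantics follow ``mode``: alignment penalty (lower is better)
    for miRNA_target, genomic gap in bp for cis, pairing fraction for trans.
    """

    regulator_id: str
    target_id: str
    mode: str  # miRNA_target | cis | trans
    score: float
    site_start: int = 0
    method_note: str = ""


def _ungapped_site_scores(
    mc: np.ndarray, tc: np.ndarray, cost: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Penalty of the ungapped alignment at every window offset."""
    L = len(mc)
    windows = sliding_window_view(tc, L)[:, ::-1]
    return (cost[mc[None, :], windows] * w[None, 1:]).sum(axis=1)


def predict_mirna_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    max_penalty: float = 4.0,
    cfg: ScoringConfig | None = None,
) -> list[TargetHit]:
    """Scan every transcript for the best-scoring site per (miRNA,
    transcript); keep hits with penalty ≤ max_penalty.

    All window offsets are scored ungapped (vectorized); the most promising
    offsets are then refined with the full gapped alignment, so bulged sites
    within the gap budget are still found. Ties go to the smallest offset.
    """
    cfg = cfg or DEFAULT_SCORING
    hits: list[TargetHit] = []
    refine_slack = 2 * cfg.gap * cfg.seed_multiplier
    for mid in sorted(mirnas):
        m = _normalize(mirnas[mid], "miRNA")
        mc = _encode(m)
        L = len(m)
        cost = _pair_cost_table(cfg)
        w = _position_weights(L, cfg)
        for tid in sorted(transcripts):
            if tid == mid:
                continue
            t = _normalize(transcripts[tid], "transcript")
            if len(t) < L:
                continue
            tc = _encode(t)
            ungapped = _ungapped_site_scores(mc, tc, cost, w)
            cutoff = max_penalty + refine_slack
            cand = np.flatnonzero(ungapped <= cutoff)
            if cand.size == 0:
                cand = np.array([int(np.argmin(ungapped))])
            best_pen, best_off = math.inf, -1
            for off in cand:
                pen = mirna_target_score(m, t[off : off + L], cfg)
                if pen < best_pen:
                    best_pen, best_off = pen, int(off)
            if best_pen <= max_penalty:
                hits.append(
                    TargetHit(mid, tid, "miRNA_target", best_pen, best_off + 1)
                )
    return hits


# ---------------------------------------------------------------------------
# cis targets
# ---------------------------------------------------------------------------

def _as_interval_list(
    items: Sequence,
) -> list[tuple[str, GenomicInterval]]:
    out = []
    for it in items:
        if isinstance(it, TranscriptRecord):
            out.append((it.transcript_id, it.locus))
        else:
            out.append((it[0], it[1]))
    return out


def cis_targets(
    lncrnas: Sequence, genes: Sequence, window_bp: int = 100_000
) -> list[TargetHit]:
    """Genes whose interval lies within ``window_bp`` of the lncRNA locus on
    the same chromosome (gap between boundaries; 0 on overlap; strand
    ignored). Score is the gap in bp."""
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    lns = _as_interval_list(lncrnas)
    gns = _as_interval_list(genes)
    by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for gid, iv in gns:
        by_chrom.setdefault(iv.chrom, []).append((gid, iv))
    hits: list[TargetHit] = []
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda x: (x[1].start, x[0]))
    for lid, liv in lns:
        glist = by_chrom.get(liv.chrom, [])
        if not glist:
            continue
        starts = np.array([iv.start for _, iv in glist])
        ends = np.array([iv.end for _, iv in glist])
        gaps = np.maximum(
            0, np.maximum(liv.start, starts) - np.minimum(liv.end, ends) - 1
        )
        for idx in np.flatnonzero(gaps <= window_bp):
            gid, _ = glist[idx]
            if gid == lid:
                continue
            hits.append(TargetHit(lid, gid, "cis", float(gaps[idx])))
    hits.sort(key=lambda h: (h.regulator_id, h.target_id))
    return hits


# ---------------------------------------------------------------------------
# trans targets (lncTar surrogate)
# ---------------------------------------------------------------------------

def _pair_value_table() -> np.ndarray:
    """Watson–Crick pairing value per (lncRNA base, target base): 1 for WC,
    0.5 for G:U, 0 otherwise (N never pairs)."""
    t = np.zeros((5, 5))
    for a, b in WC_PAIRS:
        t[_CODE[a], _CODE[b]] = 1.0
    for a, b in WOBBLE_PAIRS:
        t[_CODE[a], _CODE[b]] = 0.5
    return t


def trans_pairing_score(
    lnc_seq: str, target_seq: str, window: int = 100
) -> tuple[float, int]:
    """Best ungapped antiparallel pairing window between a lncRNA and a
    target: returns (fraction of paired positions with G:U = 0.5, 1-based
    start of the window in the target)."""
    a = _encode(_normalize(lnc_seq, "lncRNA"))
    brev = _encode(_normalize(target_seq, "target"))[::-1]
    L1, L2 = len(a), len(brev)
    if L1 < window or L2 < window:
        return 0.0, 0
    P = _pair_value_table()[a[:, None], brev[None, :]]
    best, best_j0 = -1.0, 0
    for d in range(-(L1 - window), L2 - window + 1):
        diag = np.diagonal(P, offset=d)
        if len(diag) < window:
            continue
        c = np.concatenate([[0.0], np.cumsum(diag)])
        sums = c[window:] - c[:-window]
        k = int(np.argmax(sums))
        if sums[k] > best:
            best = float(sums[k])
            # window occupies brev[j0 : j0+window] on this diagonal
            j0 = (d if d >= 0 else 0) + k
            best_j0 = j0
    start_in_target = L2 - (best_j0 + window) + 1
    return best / window, start_in_target


def trans_targets(
    lncrnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    min_pair_fraction: float = 0.8,
    window: int = 100,
) -> list[TargetHit]:
    """Complementarity surrogate for free-energy trans-target tools: hit iff
    the best ungapped pairing window reaches ``min_pair_fraction``."""
    if not 0 < min_pair_fraction <= 1:
        raise ValueError("min_pair_fraction must be in (0, 1]")
    hits: list[TargetHit] = []
    for lid in sorted(lncrnas):
        for tid in sorted(transcripts):
            if tid == lid:
                continue
            score, start = trans_pairing_score(lncrnas[lid], transcripts[tid], window)
            if score >= min_pair_fraction:
                hits.append(
                    TargetHit(lid, tid, "trans", score, start, "lncTar-surrogate")
                )
    return hits


# ---------------------------------------------------------------------------
# TargetMap
# ---------------------------------------------------------------------------

@dataclass
class TargetMap:
    """miRNA → targeted lncRNA and mRNA id sets; the substrate of the ceRNA
    screen."""

    lnc_targets: dict[str, set[str]] = field(default_factory=dict)
    mrna_targets: dict[str, set[str]] = field(default_factory=dict)

    def add(self, mirna_id: str, target_id: str, target_class: str) -> None:
        if mirna_id == target_id:
            raise ValueError(f"self-target {mirna_id}")
        if target_class == "lncRNA":
            self.lnc_targets.setdefault(mirna_id, set()).add(target_id)
        elif target_class == "mRNA":
            self.mrna_targets.setdefault(mirna_id, set()).add(target_id)
        else:
            raise ValueError(f"unknown target class {target_class!r}")

    @property
    def mirna_ids(self) -> set[str]:
        return set(self.lnc_targets) | set(self.mrna_targets)

    def universe_size(self) -> int:
        """miRNAs with at least one target — the hypergeometric background."""
        return len(self.mirna_ids)

    def mirnas_targeting(self, target_id: str, target_class: str) -> set[str]:
        pool = self.lnc_targets if target_class == "lncRNA" else self.mrna_targets
        return {m for m, ts in pool.items() if target_id in ts}

    @classmethod
    def from_hits(
        cls, hits: Iterable[TargetHit], class_of: Mapping[str, str]
    ) -> "TargetMap":
        tm = cls()
        for h in hits:
            tm.add(h.regulator_id, h.target_id, class_of[h.target_id])
        return tm

    @classmethod
    def from_table(cls, rows: Iterable[tuple[str, str, str]]) -> "TargetMap":
        """Rows of (miRNA_id, target_id, target_class) — the ingestion path
        for externally computed target tables."""
        tm = cls()
        for mid, tid, tcls in rows:
            tm.add(mid, tid, tcls)
        return tm

    def to_rows(self) -> list[tuple[str, str, str]]:
        rows = [
            (m, t, "lncRNA") for m, ts in self.lnc_targets.items() for t in ts
        ] + [(m, t, "mRNA") for m, ts in self.mrna_targets.items() for t in ts]
        return sorted(rows)
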