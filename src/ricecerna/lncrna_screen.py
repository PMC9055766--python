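"""lncRNA candidate screening and classification.

The screen follows the standard plant lncRNA discovery recipe: keep assembled
transcripts whose assembler class code marks them as novel relative to the
reference ('u' intergenic, 'i' intronic, 'x' antisense overlap, 'o'/'e' sense
overlap), require length ≥ 200 nt, ≥ 2 exons and detectable expression
(FPKM ≥ 0.1), then intersect the non-coding verdicts of four independent
coding-potential classifiers (CPC, CNCI, CPAT, PFAM). Surviving transcripts
are classified positionally from their class code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .annotation_io import CodingVerdictTable, ExpressionMatrix, TranscriptRecord

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class ScreenConfig:
    """Thresholds of the basic lncRNA screen.

    min_length_nt/min_exons/min_fpkm are the published screening rules;
    accepted_class_codes is the set of assembler codes treated as novel
    lncRNA candidates; novel_min_orf_aa is the short-peptide cutoff applied
    at novel-transcript discovery. fpkm_statistic selects whether the
    expression rule is evaluated against the per-feature max (default) or
    mean across samples.
    """

    min_length_nt: int = 200
    min_exons: int = 2
    min_fpkm: float = 0.1
    accepted_class_codes: frozenset[str] = frozenset({"i", "x", "u", "o", "e"})
    novel_min_orf_aa: int = 50
    fpkm_statistic: str = "max"
    missing_expression: str = "reject"  # or "keep", "error"

    def __post_init__(self) -> None:
        if self.min_length_nt <= 0 or self.min_exons <= 0 or self.min_fpkm <= 0:
            raise ValueError("all screen thresholds must be > 0")
        if self.fpkm_statistic not in ("max", "mean"):
            raise ValueError("fpkm_statistic must be 'max' or 'mean'")


class OrfResult(NamedTuple):
    """Longest open reading frame of a transcript sequence.

    length_nt runs from the ATG through the stop codon inclusive; length_aa
    excludes the stop. start_nt is 1-based, 0 when no ORF exists.
    """

    start_nt: int
    length_nt: int
    length_aa: int


class ScreenResult(NamedTuple):
    kept: list[TranscriptRecord]
    rejected: list[tuple[str, str]]  # (transcript_id, failing rule)


class ConsensusResult(NamedTuple):
    consensus: set[str]
    venn_counts: dict[tuple[str, ...], int]  # exact tool-subset → count


def basic_screen(
    transcripts: Sequence[TranscriptRecord],
    expr: ExpressionMatrix,
    cfg: ScreenConfig | None = None,
) -> ScreenResult:
    """Apply the class-code / length / exon-count / expression rules.

    Rules are checked in that order and the first failing rule is recorded
    per rejected transcript.
    """
    cfg = cfg or ScreenConfig()
    if expr.unit != "FPKM":
        raise ValueError(f"basic_screen expects FPKM, got {expr.unit}")
    kept: list[TranscriptRecord] = []
    rejected: list[tuple[str, str]] = []
    vals = expr.values
    for t in transcripts:
        if t.class_code not in cfg.accepted_class_codes:
            rejected.append((t.transcript_id, "class_code"))
            continue
        if t.length < cfg.min_length_nt:
            rejected.append((t.transcript_id, "length"))
            continue
        if t.n_exons < cfg.min_exons:
            rejected.append((t.transcript_id, "exons"))
            continue
        if t.transcript_id not in vals.index:
            if cfg.missing_expression == "error":
                raise KeyError(f"{t.transcript_id} absent from expression matrix")
            if cfg.missing_expression == "reject":
                rejected.append((t.transcript_id, "no_expression_data"))
                continue
        else:
            row = vals.loc[t.transcript_id]
            stat = row.max() if cfg.fpkm_statistic == "max" else row.mean()
            if stat < cfg.min_fpkm:
                rejected.append((t.transcript_id, "expression"))
                continue
        kept.append(t)
    return ScreenResult(kept, rejected)


def consensus_noncoding(
    candidates: Sequence[TranscriptRecord] | Sequence[str],
    verdicts: Sequence[CodingVerdictTable],
) -> ConsensusResult:
    """Intersect the non-coding calls of the coding-potential classifiers.

    Returns the candidate ids called non-coding by *all* tools, plus the
    Venn breakdown (count of candidates per exact tool subset) for
    reporting.
    """
    names = [v.tool_name for v in verdicts]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate tool names: {names}")
    if not verdicts:
        raise ValueError("at least one verdict table required")
    cand_ids = [
        c.transcript_id if isinstance(c, TranscriptRecord) else c for c in candidates
    ]
    membership: dict[str, tuple[str, ...]] = {}
    for cid in cand_ids:
        membership[cid] = tuple(
            sorted(v.tool_name for v in verdicts if cid in v.noncoding_ids)
        )
    venn = dict(Counter(membership.values()))
    all_tools = tuple(sorted(names))
    consensus = {cid for cid, m in membership.items() if m == all_tools}
    return ConsensusResult(consensus, venn)


_CODE_TO_BIOTYPE = {
    "u": "lincRNA",
    "i": "intronic-lncRNA",
    "x": "antisense-lncRNA",
    "o": "sense-lncRNA",
    "e": "sense-lncRNA",
}

#: class codes whose category depends on knowing the strand
_STRAND_DEPENDENT = {"x", "o", "e"}


def classify_lncrna(t: TranscriptRecord) -> str:
    """Positional category from the assembler class code (u→lincRNA,
    i→intronic, x→antisense, o/e→sense); strand-dependent categories need a
    known strand, otherwise 'unknown'."""
    biotype = _CODE_TO_BIOTYPE.get(t.class_code, "unknown")
    if t.class_code in _STRAND_DEPENDENT and t.strand == ".":
        return "unknown"
    return biotype


def find_longest_orf(sequence: str) -> OrfResult:
    """Longest forward-strand ORF: ATG through the first in-frame stop
    (TAA/TAG/TGA), all three frames scanned; ties broken by the smallest
    start position. N never matches a start or stop codon."""
    seq = sequence.upper().replace("U", "T")
    best = OrfResult(0, 0, 0)
    n = len(seq)
    for frame in range(3):
        stops: list[int] = []
        atgs: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                atgs.append(i)
            elif codon in STOP_CODONS:
                stops.append(i)
        si = 0
        for a in atgs:
            while si < len(stops) and stops[si] < a:
                si += 1
            if si == len(stops):
                break
            length = stops[si] + 3 - a
            if length > best.length_nt or (
                length == best.length_nt and best.start_nt and a + 1 < best.start_nt
            ):
                best = OrfResult(a + 1, length, length // 3 - 1)
    return best


def novel_transcript_filter(
    transcripts: Sequence[TranscriptRecord],
    sequences: Mapping[str, str],
    cfg: ScreenConfig | None = None,
) -> list[TranscriptRecord]:
    """Pre-filter applied at novel-transcript discovery: drop single-exon
    transcripts and transcripts encoding only short peptides
    (< novel_min_orf_aa residues keeps them as non-coding candidates; here
    the filter removes putative coding transcripts below the cutoff from the
    *novel mRNA* side)."""
    cfg = cfg or ScreenConfig()
    kept = []
    for t in transcripts:
        if t.n_exons < 2:
            continue
        seq = sequences.get(t.transcript_id, t.sequence)
        if seq is None:
            continue
        if find_longest_orf(seq).length_aa < cfg.novel_min_orf_aa:
            continue
        kept.append(t)
    return kept


def category_table(counts: Mapping[str, int]) -> pd.DataFrame:
    """Category counts with percentages (100·count/total, 1 decimal)."""
    total = sum(counts.values())
    rows = [
        {
            "category": cat,
            "count": c,
            "percent": round(100.0 * c / total, 1) if total else 0.0,
        }
        for cat, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def feature_stats(
    lncrnas: Sequence[TranscriptRecord],
    mrnas: Sequence[TranscriptRecord],
    expr: ExpressionMatrix | None = None,
    length_bins: Sequence[int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Descriptive comparison of the lncRNA and mRNA sets: length, exon
    count and ORF-length histograms, per-chromosome counts, expression
    summary, and lncRNA category percentages."""
    if not lncrnas or not mrnas:
        raise ValueError("both transcript lists must be non-empty")
    length_bins = list(
        length_bins
        if length_bins is not None
        else [0, 300, 500, 700, 900, 1100, 1300, 1500, 1700, 1900, np.inf]
    )

    def _hist(values: Sequence[float], bins) -> pd.DataFrame:
        counts, edges = np.histogram(list(values), bins=bins)
        return pd.DataFrame(
            {
                "bin_left": edges[:-1],
                "bin_right": edges[1:],
                "count": counts,
            }
        )

    out: dict[str, pd.DataFrame] = {}
    for label, recs in (("lncRNA", lncrnas), ("mRNA", mrnas)):
        out[f"length_hist_{label}"] = _hist([t.length for t in recs], length_bins)
        max_ex = max(t.n_exons for t in recs)
        out[f"exon_hist_{label}"] = _hist(
            [t.n_exons for t in recs], np.arange(0.5, max_ex + 1.5)
        )
        orf_lengths = [
            find_longest_orf(t.sequence).length_nt for t in recs if t.sequence
        ]
        if orf_lengths:
            out[f"orf_hist_{label}"] = _hist(
                orf_lengths, np.arange(0, max(orf_lengths) + 100, 100)
            )
        chrom_counts = Counter(t.locus.chrom for t in recs)
        out[f"chrom_counts_{label}"] = pd.DataFrame(
            sorted(chrom_counts.items()), columns=["chrom", "count"]
        )
        if expr is not None:
            ids = [t.transcript_id for t in recs if t.transcript_id in expr.values.index]
            if ids:
                v = expr.values.loc[ids]
                out[f"expression_summary_{label}"] = pd.DataFrame(
                    {
                        "statistic": ["mean", "median", "max"],
                        "value": [
                            float(v.to_numpy().mean()),
                            float(np.median(v.to_numpy())),
                            float(v.to_numpy().max()),
                        ],
                    }
                )
    cats = Counter(
        t.biotype if t.biotype != "lncRNA_candidate" else classify_lncrna(t)
        for t in lncrnas
    )
    out["categories"] = category_table(cats)
    return out
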