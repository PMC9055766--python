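"""Readers and writers for the annotation, sequence and expression formats
the pipeline consumes, plus the shared transcript data model.

Coordinates are 1-based inclusive throughout (GTF convention); conversion to
0-based half-open happens only at export boundaries, never internally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

VALID_STRANDS = ("+", "-", ".")

#: decimal precision used when round-tripping expression matrices to TSV
MATRIX_FLOAT_FORMAT = "%.10g"


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted."""


class AnnotationIntegrityError(ValueError):
    """Raised when parsed features violate the transcript model."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates are 1-based positive integers")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Base pairs strictly between two intervals; 0 on overlap/adjacency,
        None on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.start <= other.end and other.start <= self.end:
            return 0
        if other.start > self.end:
            return other.start - self.end - 1
        return self.start - other.end - 1


#: biotype vocabulary used by the lncRNA classifier
BIOTYPES = (
    "mRNA",
    "lncRNA_candidate",
    "lincRNA",
    "intronic-lncRNA",
    "sense-lncRNA",
    "antisense-lncRNA",
    "unknown",
)


@dataclass
class TranscriptRecord:
    """One assembled transcript: locus, exon model, assembler class code and
    optionally its spliced sequence."""

    transcript_id: str
    gene_id: str
    locus: GenomicInterval
    exons: list[GenomicInterval]
    class_code: str = ""
    sequence: str | None = None
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationIntegrityError(
                f"{self.transcript_id}: transcript must have at least one exon"
            )
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise AnnotationIntegrityError(
                f"{self.transcript_id}: exons on multiple chromosomes {sorted(chroms)}"
            )
        if len(strands) > 1:
            raise AnnotationIntegrityError(
                f"{self.transcript_id}: exons on multiple strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise AnnotationIntegrityError(
                    f"{self.transcript_id}: overlapping exons {a} / {b}"
                )
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationIntegrityError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"exon-model length {self.length}"
            )

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression values plus the sample→condition map.

    ``values`` is a pandas DataFrame with feature ids as the index and sample
    ids as columns; ``unit`` declares the scale (count, FPKM, TPM or
    normalized).
    """

    values: pd.DataFrame
    unit: str
    condition_of: dict[str, str]

    UNITS = ("count", "FPKM", "TPM", "normalized")

    def __post_init__(self) -> None:
        if self.unit not in self.UNITS:
            raise ValueError(f"unit must be one of {self.UNITS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.isna().any().any():
            raise ValueError("matrix contains missing values (ragged input?)")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of[s] == condition]

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)].copy(), self.unit, dict(self.condition_of)
        )

    def with_unit(self, values: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, unit, dict(self.condition_of))


@dataclass
class CodingVerdictTable:
    """Transcript ids one coding-potential classifier called non-coding."""

    tool_name: str
    noncoding_ids: set[str]

    TOOLS = ("CPC", "CNCI", "CPAT", "PFAM")

    def unknown_ids(self, annotation_ids: set[str]) -> set[str]:
        """Ids in the verdict table absent from the annotation (reported,
        not fatal)."""
        return self.noncoding_ids - annotation_ids


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _validate_gtf_lines(path: Path) -> None:
    """Cheap structural pass so malformed lines are reported with their
    line number before gffutils ingests the file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if fields[2] == "exon" and "transcript_id" not in fields[8]:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon feature without transcript_id "
                    "attribute"
                )


def read_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Parse a GTF (Ensembl-dialect attributes) into transcript records.

    Exons are grouped per transcript and sorted; an optional ``class_code``
    attribute (StringTie/gffcompare) is captured from transcript or exon
    lines. Coordinates stay 1-based inclusive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_gtf_lines(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises several parse exception types
        raise GtfParseError(f"{path}: failed to parse GTF: {exc}") from exc

    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    class_code: dict[str, str] = {}
    order: list[str] = []
    for feat in db.all_features():
        attrs = feat.attributes
        tids = attrs.get("transcript_id")
        if not tids:
            continue
        tid = tids[0]
        if "class_code" in attrs and tid not in class_code:
            class_code[tid] = attrs["class_code"][0]
        if feat.featuretype != "exon":
            continue
        if tid not in exons:
            exons[tid] = []
            order.append(tid)
        gene_of.setdefault(tid, attrs.get("gene_id", [""])[0])
        exons[tid].append(
            GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand or ".")
        )

    records = []
    for tid in order:
        ex = sorted(exons[tid], key=lambda e: e.start)
        locus = GenomicInterval(ex[0].chrom, ex[0].start, ex[-1].end, ex[0].strand)
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gene_of.get(tid, ""),
                locus=locus,
                exons=ex,
                class_code=class_code.get(tid, ""),
            )
        )
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: sequence}; sequences upper-cased, U→T, id is the
    first whitespace-delimited header token."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        if not seq:
            raise ValueError(f"{path}: empty sequence for {rec.id!r}")
        out[rec.id] = seq
    return out


def read_matrix(
    path: str | Path,
    condition_map: Mapping[str, str],
    unit: str = "count",
) -> ExpressionMatrix:
    """Read a features×samples TSV (first column = feature id, header row =
    sample ids) into an ExpressionMatrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing values")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), unit, dict(condition_map))


def read_verdict_table(path: str | Path, tool_name: str) -> CodingVerdictTable:
    """One transcript id per line (first tab-separated token kept)."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split("\t")[0])
    return CodingVerdictTable(tool_name=tool_name, noncoding_ids=ids)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.sort_index().to_csv(
        path, sep="\t", float_format=MATRIX_FLOAT_FORMAT, lineterminator="\n"
    )


def write_table(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write any tabular result to TSV deterministically: header always
    present, rows sorted by the first column.

    ``columns`` supplies the header when ``records`` is an empty list.
    """
    if records is None:
        raise ValueError("records must not be None")
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            if dataclasses.is_dataclass(r):
                d = dataclasses.asdict(r)
            elif isinstance(r, Mapping):
                d = dict(r)
            else:
                raise TypeError(f"cannot tabulate {type(r)}")
            rows.append(
                {
                    k: (";".join(sorted(map(str, v))) if isinstance(v, (set, frozenset)) else v)
                    for k, v in d.items()
                }
            )
        if rows:
            df = pd.DataFrame(rows)
        else:
            df = pd.DataFrame(columns=list(columns or []))
    if len(df.columns):
        df = df.sort_values(by=list(df.columns[:2]), kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=MATRIX_FLOAT_FORMAT,
              lineterminator="\n")
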