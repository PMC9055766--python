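"""Self-contained synthetic data with the statistical structure the analysis
assumes, plus ground truth for recovery testing.

The generator emulates a two-condition RNA-seq design (control vs drought,
three replicates each): negative-binomial counts with multiplicative library
sizes, planted differential effects per RNA class, toy genome annotation with
assembler class codes and coding-potential verdict tables, a miRNA→target map,
and planted ceRNA modules in which one lncRNA and several mRNAs share a set of
miRNAs, the miRNAs are up-regulated and anti-correlated with both targets, and
the lncRNA–mRNA pair is positively correlated through a shared latent factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    CodingVerdictTable,
    ExpressionMatrix,
    GenomicInterval,
    TranscriptRecord,
)
from .lncrna_screen import STOP_CODONS, find_longest_orf
from .target_pred import TargetMap, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-design parameters of the simulation.

    Defaults mirror the emulated experiment: 3 replicates per condition,
    negative-binomial dispersion 0.1, planted |log2FC| = 3, five ceRNA
    modules of one lncRNA × four mRNAs sharing four miRNAs against a sparse
    random target background.
    """

    seed: int = 0
    n_lncrna: int = 50
    n_mirna: int = 30
    n_mrna: int = 200
    # non-targeting, non-differential small RNAs co-sequenced in the miRNA
    # library; they anchor the TPM denominator the way the stable majority of
    # a real small-RNA population does
    n_filler_mirna: int = 420
    n_reps_per_condition: int = 3
    nb_dispersion: float = 0.1
    base_mean_log2_range: tuple[float, float] = (5.0, 9.0)
    planted_de_fraction: float = 0.3
    planted_log2fc: float = 3.0
    n_cerna_modules: int = 5
    module_shared_mirnas: int = 4
    module_mrnas_per_lnc: int = 4
    background_target_prob: float = 0.03
    latent_sd: float = 0.5
    chrom_count: int = 12
    chrom_length_bp: int = 2_000_000
    # lincRNA / intronic / sense / antisense proportions of lncRNA candidates
    category_fractions: tuple[float, float, float, float] = (0.827, 0.039, 0.08, 0.054)
    consensus_fraction: float = 0.9
    n_trt_specific: int = 2
    n_ctrl_specific: int = 1
    ctrl_label: str = "CK"
    trt_label: str = "D"
    library_jitter: float = 0.2
    mirna_length_nt: int = 21
    novel_min_orf_aa: int = 50

    def __post_init__(self) -> None:
        for name in ("n_lncrna", "n_mirna", "n_mrna", "n_reps_per_condition",
                     "n_cerna_modules", "module_shared_mirnas",
                     "module_mrnas_per_lnc", "chrom_count", "chrom_length_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("planted_de_fraction", "background_target_prob",
                     "consensus_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_cerna_modules > 0:
            if self.n_cerna_modules > self.n_lncrna:
                raise ValueError("more ceRNA modules than lncRNAs")
            if self.n_cerna_modules * self.module_mrnas_per_lnc > self.n_mrna:
                raise ValueError("module mRNAs exceed mRNA universe")
            if self.module_shared_mirnas > self.n_mirna:
                raise ValueError("module miRNAs exceed miRNA universe")


@dataclass(frozen=True)
class PlantedModule:
    lnc_id: str
    mirna_ids: tuple[str, ...]
    mrna_ids: tuple[str, ...]

    def pairs(self) -> list[tuple[str, str]]:
        return [(self.lnc_id, m) for m in self.mrna_ids]


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    lnc_ids: list[str]
    mirna_ids: list[str]
    mrna_ids: list[str]
    filler_mirna_ids: list[str]
    de_effects: dict[str, float]  # signed log2 effect; absent/0 = null
    modules: list[PlantedModule]
    trt_specific: set[str]
    ctrl_specific: set[str]
    planted_sites: list[tuple[str, str, int, float]]  # (miRNA, target, pos, penalty)

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {pr for mod in self.modules for pr in mod.pairs()}


@dataclass
class SimulatedAnnotation:
    transcripts: list[TranscriptRecord]
    sequences: dict[str, str]
    mirna_sequences: dict[str, str]  # analysed miRNAs plus filler small RNAs
    verdicts: list[CodingVerdictTable]
    lnc_ids: list[str]
    mrna_ids: list[str]
    mirna_ids: list[str]
    filler_mirna_ids: list[str] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    config: SimConfig
    annotation: SimulatedAnnotation
    counts_long: ExpressionMatrix  # lncRNA + mRNA counts
    counts_mirna: ExpressionMatrix
    target_map: TargetMap
    truth: GroundTruth

    @property
    def lengths(self) -> dict[str, int]:
        out = {t.transcript_id: t.length for t in self.annotation.transcripts}
        out.update({m: len(s) for m, s in self.annotation.mirna_sequences.items()})
        return out

    def write(self, out_dir: str | Path) -> None:
        write_dataset(self, out_dir)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _break_long_orfs(seq: str, max_aa: int, rng: np.random.Generator) -> str:
    """Disrupt reading frames until no ORF reaches max_aa residues.

    Writing a stop into one frame can erase an overlapping stop of another
    frame and resurrect a long ORF there, so the iteration is capped; on the
    rare pathological sequence the whole sequence is redrawn instead.
    """
    s = list(seq)
    for _ in range(64):
        orf = find_longest_orf("".join(s))
        if orf.length_aa < max_aa:
            return "".join(s)
        mid_codon = orf.start_nt - 1 + 3 * (orf.length_aa // 2)
        s[mid_codon : mid_codon + 3] = list(STOP_CODONS[0])
    return _break_long_orfs(_random_seq(rng, len(seq)), max_aa, rng)


def _embed_orf(seq: str, rng: np.random.Generator, aa_len: int) -> str:
    codons = []
    for _ in range(aa_len):
        c = _random_seq(rng, 3)
        codons.append("CTG" if c in STOP_CODONS or c == "ATG" else c)
    orf = "ATG" + "".join(codons) + STOP_CODONS[0]
    if len(orf) >= len(seq):
        return orf[: len(seq)]
    off = int(rng.integers(0, len(seq) - len(orf) + 1))
    return seq[:off] + orf + seq[off + len(orf) :]


def _exon_model(
    rng: np.random.Generator,
    cfg: SimConfig,
    total_len: int,
    n_exons: int,
    strand: str,
) -> tuple[GenomicInterval, list[GenomicInterval]]:
    cuts = np.sort(rng.choice(np.arange(1, total_len), size=n_exons - 1, replace=False)) \
        if n_exons > 1 else np.array([], dtype=int)
    pieces = np.diff(np.concatenate([[0], cuts, [total_len]])).astype(int)
    introns = rng.integers(60, 2000, size=n_exons - 1)
    span = total_len + int(introns.sum())
    chrom = f"chr{int(rng.integers(1, cfg.chrom_count + 1))}"
    start = int(rng.integers(1, max(2, cfg.chrom_length_bp - span - 1)))
    exons = []
    pos = start
    for i, ln in enumerate(pieces):
        exons.append(GenomicInterval(chrom, pos, pos + ln - 1, strand))
        pos += ln + (int(introns[i]) if i < n_exons - 1 else 0)
    locus = GenomicInterval(chrom, start, exons[-1].end, strand)
    return locus, exons


def simulate_annotation(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimulatedAnnotation:
    """Toy multi-exon transcripts: lncRNA candidates with class codes drawn
    from the configured category proportions and only short ORFs; mRNAs with
    embedded ORFs of at least the novel-transcript cutoff; four verdict
    tables in which a configurable fraction of candidates is four-way
    consensus."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lnc_ids = [f"LNC{i:04d}" for i in range(1, cfg.n_lncrna + 1)]
    mrna_ids = [f"OSG{i:04d}" for i in range(1, cfg.n_mrna + 1)]
    mirna_ids = [f"miR{i:03d}" for i in range(1, cfg.n_mirna + 1)]

    f_lin, f_int, f_sen, f_anti = cfg.category_fractions
    sense_codes = ["o", "e"]
    transcripts: list[TranscriptRecord] = []
    sequences: dict[str, str] = {}

    for i, lid in enumerate(lnc_ids):
        total = int(rng.integers(250, 801))
        n_ex = 2 if rng.random() < 0.85 else 3
        strand = "+" if rng.random() < 0.5 else "-"
        locus, exons = _exon_model(rng, cfg, total, n_ex, strand)
        u = rng.random()
        if u < f_lin:
            code = "u"
        elif u < f_lin + f_int:
            code = "i"
        elif u < f_lin + f_int + f_sen:
            code = sense_codes[int(rng.integers(0, 2))]
        else:
            code = "x"
        seq = _break_long_orfs(_random_seq(rng, total), cfg.novel_min_orf_aa, rng)
        transcripts.append(
            TranscriptRecord(lid, f"gene_{lid}", locus, exons, code, seq,
                             "lncRNA_candidate")
        )
        sequences[lid] = seq

    for gid in mrna_ids:
        total = int(rng.integers(900, 2401))
        n_ex = int(rng.integers(2, 8))
        strand = "+" if rng.random() < 0.5 else "-"
        locus, exons = _exon_model(rng, cfg, total, n_ex, strand)
        aa = int(rng.integers(cfg.novel_min_orf_aa + 10, 260))
        seq = _embed_orf(_random_seq(rng, total), rng, aa)
        transcripts.append(
            TranscriptRecord(gid, f"gene_{gid}", locus, exons, "=", seq, "mRNA")
        )
        sequences[gid] = seq

    mirna_sequences = {m: _random_seq(rng, cfg.mirna_length_nt) for m in mirna_ids}
    # co-sequenced stable small RNAs (21/24-nt size classes)
    filler_ids = [f"sRNA{i:04d}" for i in range(1, cfg.n_filler_mirna + 1)]
    for fid in filler_ids:
        mirna_sequences[fid] = _random_seq(
            rng, int(rng.choice([21, 24], p=[0.45, 0.55]))
        )

    tools = list(CodingVerdictTable.TOOLS)
    tool_sets: dict[str, set[str]] = {t: set() for t in tools}
    # module lncRNAs (the first n_cerna_modules ids by construction, see
    # plant_cerna_modules) are genuine lncRNAs: always four-way consensus
    protected = set(lnc_ids[: cfg.n_cerna_modules])
    for lid in lnc_ids:
        if lid in protected or rng.random() < cfg.consensus_fraction:
            for t in tools:
                tool_sets[t].add(lid)
        else:
            skip = tools[int(rng.integers(0, len(tools)))]
            for t in tools:
                if t != skip:
                    tool_sets[t].add(lid)
    verdicts = [CodingVerdictTable(t, tool_sets[t]) for t in tools]
    return SimulatedAnnotation(
        transcripts, sequences, mirna_sequences, verdicts,
        lnc_ids, mrna_ids, mirna_ids, filler_ids,
    )


# ---------------------------------------------------------------------------
# ceRNA modules and target map
# ---------------------------------------------------------------------------

def plant_cerna_modules(
    cfg: SimConfig,
    ann: SimulatedAnnotation,
    rng: np.random.Generator | None = None,
) -> tuple[TargetMap, list[PlantedModule], list[tuple[str, str, int, float]]]:
    """Build the miRNA→target map with planted ceRNA modules plus sparse
    background edges, and embed a perfect-complement binding site (penalty
    0) for every planted module edge into the target's sequence."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    tmap = TargetMap()
    modules: list[PlantedModule] = []
    sites: list[tuple[str, str, int, float]] = []

    n_mod = cfg.n_cerna_modules
    module_lncs = ann.lnc_ids[:n_mod]
    mrna_pool = list(ann.mrna_ids)
    mirna_pool = list(ann.mirna_ids)
    for mi in range(n_mod):
        lnc = module_lncs[mi]
        if len(mirna_pool) >= cfg.module_shared_mirnas:
            mirs = tuple(mirna_pool[: cfg.module_shared_mirnas])
            mirna_pool = mirna_pool[cfg.module_shared_mirnas :]
        else:  # re-use miRNAs when the universe is small
            mirs = tuple(
                rng.choice(ann.mirna_ids, cfg.module_shared_mirnas, replace=False)
            )
        mrnas = tuple(mrna_pool[: cfg.module_mrnas_per_lnc])
        mrna_pool = mrna_pool[cfg.module_mrnas_per_lnc :]
        modules.append(PlantedModule(lnc, mirs, mrnas))
        for m in mirs:
            tmap.add(m, lnc, "lncRNA")
            sites.append(_embed_site(ann, rng, m, lnc))
            for g in mrnas:
                tmap.add(m, g, "mRNA")
                sites.append(_embed_site(ann, rng, m, g))

    if cfg.background_target_prob > 0:
        for m in ann.mirna_ids:
            for lid in ann.lnc_ids:
                if rng.random() < cfg.background_target_prob:
                    tmap.add(m, lid, "lncRNA")
            for gid in ann.mrna_ids:
                if rng.random() < cfg.background_target_prob:
                    tmap.add(m, gid, "mRNA")
    return tmap, modules, sites


def _embed_site(
    ann: SimulatedAnnotation, rng: np.random.Generator, mirna_id: str, target_id: str
) -> tuple[str, str, int, float]:
    site = revcomp(ann.mirna_sequences[mirna_id])
    seq = ann.sequences[target_id]
    off = int(rng.integers(0, len(seq) - len(site) + 1))
    ann.sequences[target_id] = seq[:off] + site + seq[off + len(site) :]
    for t in ann.transcripts:
        if t.transcript_id == target_id:
            t.sequence = ann.sequences[target_id]
    return (mirna_id, target_id, off + 1, 0.0)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def plan_effects(
    cfg: SimConfig,
    ann: SimulatedAnnotation,
    modules: Sequence[PlantedModule],
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Assign signed log2 effects: random ± planted_log2fc for a fraction of
    background features, module miRNAs up / module lncRNA+mRNAs down, plus
    condition-specific lncRNAs."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    module_members = {m.lnc_id for m in modules}
    module_members |= {x for m in modules for x in m.mirna_ids + m.mrna_ids}
    effects: dict[str, float] = {}
    for fid in ann.lnc_ids + ann.mrna_ids + ann.mirna_ids:
        if fid in module_members:
            continue
        if rng.random() < cfg.planted_de_fraction:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects[fid] = sign * cfg.planted_log2fc
    for m in modules:
        effects[m.lnc_id] = -cfg.planted_log2fc
        for g in m.mrna_ids:
            effects[g] = -cfg.planted_log2fc
        for mir in m.mirna_ids:
            effects[mir] = cfg.planted_log2fc

    free = [l for l in ann.lnc_ids if l not in module_members and l not in effects]
    trt_specific = set(free[: cfg.n_trt_specific])
    ctrl_specific = set(free[cfg.n_trt_specific : cfg.n_trt_specific + cfg.n_ctrl_specific])
    return GroundTruth(
        lnc_ids=list(ann.lnc_ids),
        mirna_ids=list(ann.mirna_ids),
        mrna_ids=list(ann.mrna_ids),
        filler_mirna_ids=list(ann.filler_mirna_ids),
        de_effects=effects,
        modules=list(modules),
        trt_specific=trt_specific,
        ctrl_specific=ctrl_specific,
        planted_sites=[],
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = np.where(mean > 0, r / (r + mean), 1.0)
    return rng.negative_binomial(r, p)


def simulate_counts(
    cfg: SimConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Draw NB counts (var = μ + dispersion·μ²) for the long-RNA and miRNA
    matrices: per-feature base means log-uniform over
    base_mean_log2_range, condition effects 2^effect, module latent factors
    inducing the planted correlations, library sizes jittered ±20%, and
    zeroed counts for condition-specific features."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    reps = cfg.n_reps_per_condition
    samples = [f"{cfg.ctrl_label}{i+1}" for i in range(reps)] + [
        f"{cfg.trt_label}{i+1}" for i in range(reps)
    ]
    condition_of = {
        s: (cfg.ctrl_label if i < reps else cfg.trt_label)
        for i, s in enumerate(samples)
    }
    is_trt = np.array([0.0] * reps + [1.0] * reps)

    lo, hi = cfg.base_mean_log2_range
    module_sign: dict[str, float] = {}
    module_idx: dict[str, int] = {}
    for j, mod in enumerate(truth.modules):
        module_idx[mod.lnc_id] = j
        module_sign[mod.lnc_id] = 1.0
        for g in mod.mrna_ids:
            module_idx[g], module_sign[g] = j, 1.0
        for m in mod.mirna_ids:
            module_idx[m], module_sign[m] = j, -1.0
    latent = rng.normal(0.0, cfg.latent_sd, size=(max(len(truth.modules), 1), 2 * reps))

    def _matrix(feature_ids: list[str]) -> pd.DataFrame:
        base = 2.0 ** rng.uniform(lo, hi, size=len(feature_ids))
        lib = rng.uniform(1 - cfg.library_jitter, 1 + cfg.library_jitter, size=2 * reps)
        means = np.empty((len(feature_ids), 2 * reps))
        for i, fid in enumerate(feature_ids):
            eff = truth.de_effects.get(fid, 0.0)
            mu = base[i] * 2.0 ** (eff * is_trt)
            if fid in module_idx:
                mu = mu * 2.0 ** (module_sign[fid] * latent[module_idx[fid]])
            if fid in truth.trt_specific:
                mu = np.where(is_trt > 0, base[i] * 2.0 ** cfg.planted_log2fc, 0.0)
            if fid in truth.ctrl_specific:
                mu = np.where(is_trt > 0, 0.0, base[i])
            means[i] = mu * lib
        counts = _nb_draw(rng, means, cfg.nb_dispersion)
        return pd.DataFrame(counts.astype(float), index=feature_ids, columns=samples)

    long_df = _matrix(truth.lnc_ids + truth.mrna_ids)
    mir_df = _matrix(truth.mirna_ids + truth.filler_mirna_ids)
    return (
        ExpressionMatrix(long_df, "count", condition_of),
        ExpressionMatrix(mir_df, "count", condition_of),
    )


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Full generator: annotation → planted modules/target map → counts.
    A fixed seed yields byte-identical outputs."""
    rng = np.random.default_rng(cfg.seed)
    ann = simulate_annotation(cfg, rng)
    tmap, modules, sites = plant_cerna_modules(cfg, ann, rng)
    truth = plan_effects(cfg, ann, modules, rng)
    truth.planted_sites = sites
    counts_long, counts_mirna = simulate_counts(cfg, truth, rng)
    return SimulatedDataset(cfg, ann, counts_long, counts_mirna, tmap, truth)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_gtf(transcripts: Sequence[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.class_code:
                attrs += f' class_code "{t.class_code}";'
            loc = t.locus
            fh.write(
                f"{loc.chrom}\tsim\ttranscript\t{loc.start}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{e.chrom}\tsim\texon\t{e.start}\t{e.end}\t.\t{e.strand}\t.\t"
                    f"{attrs}\n"
                )


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid in seqs:
            fh.write(f">{sid}\n")
            s = seqs[sid]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gtf"] = out / "annotation.gtf"
    write_gtf(ds.annotation.transcripts, paths["gtf"])
    paths["fasta"] = out / "transcripts.fa"
    write_fasta(ds.annotation.sequences, paths["fasta"])
    paths["mirna_fasta"] = out / "mirnas.fa"
    write_fasta(ds.annotation.mirna_sequences, paths["mirna_fasta"])
    for v in ds.annotation.verdicts:
        p = out / f"verdict_{v.tool_name.lower()}.tsv"
        p.write_text("".join(f"{i}\n" for i in sorted(v.noncoding_ids)))
        paths[f"verdict_{v.tool_name}"] = p

    for name, em in (("counts_long", ds.counts_long), ("counts_mirna", ds.counts_mirna)):
        p = out / f"{name}.tsv"
        em.values.to_csv(p, sep="\t", float_format="%g", lineterminator="\n")
        paths[name] = p
    p = out / "conditions.tsv"
    with open(p, "w") as fh:
        fh.write("sample\tcondition\n")
        for s in ds.counts_long.sample_ids:
            fh.write(f"{s}\t{ds.counts_long.condition_of[s]}\n")
    paths["conditions"] = p

    p = out / "targets.tsv"
    with open(p, "w") as fh:
        fh.write("mirna_id\ttarget_id\ttarget_class\n")
        for row in ds.target_map.to_rows():
            fh.write("\t".join(row) + "\n")
    paths["targets"] = p

    p = out / "lengths.tsv"
    with open(p, "w") as fh:
        fh.write("feature_id\tlength_nt\n")
        for fid, ln in sorted(ds.lengths.items()):
            fh.write(f"{fid}\t{ln}\n")
    paths["lengths"] = p

    p = out / "truth_effects.tsv"
    with open(p, "w") as fh:
        fh.write("feature_id\tlog2_effect\n")
        for fid, eff in sorted(ds.truth.de_effects.items()):
            fh.write(f"{fid}\t{eff}\n")
    paths["truth_effects"] = p
    p = out / "truth_modules.tsv"
    with open(p, "w") as fh:
        fh.write("module\tlnc_id\tmirna_ids\tmrna_ids\n")
        for i, m in enumerate(ds.truth.modules):
            fh.write(
                f"{i}\t{m.lnc_id}\t{';'.join(m.mirna_ids)}\t{';'.join(m.mrna_ids)}\n"
            )
    paths["truth_modules"] = p
    p = out / "truth_specific.tsv"
    with open(p, "w") as fh:
        fh.write("feature_id\tkind\n")
        for fid in sorted(ds.truth.trt_specific):
            fh.write(f"{fid}\ttrt_specific\n")
        for fid in sorted(ds.truth.ctrl_specific):
            fh.write(f"{fid}\tctrl_specific\n")
    paths["truth_specific"] = p
    p = out / "truth_sites.tsv"
    with open(p, "w") as fh:
        fh.write("mirna_id\ttarget_id\tsite_start\tpenalty\n")
        for m, t, pos, pen in sorted(ds.truth.planted_sites):
            fh.write(f"{m}\t{t}\t{pos}\t{pen}\n")
    paths["truth_sites"] = p
    return paths
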