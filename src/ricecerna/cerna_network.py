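"""ceRNA screening and network assembly.

Two transcripts that share many miRNA response elements can buffer each
other's miRNA repression; the screen therefore tests, for every
lncRNA–mRNA pair, whether the number of miRNAs targeting both is larger than
expected by chance. With M miRNAs in the background universe, K targeting
the lncRNA, n targeting the mRNA and k shared, the p-value is the
hypergeometric upper tail P(X ≥ k). Pairs pass with k ≥ 3 shared miRNAs,
p < 0.05 and BH-FDR < 0.1, are intersected with the differential-expression
calls of all three RNA classes, and must satisfy the ceRNA sign pattern:
miRNA anti-correlated with both targets, lncRNA and mRNA positively
correlated. Surviving pairs are assembled into a typed network exportable to
Cytoscape formats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation_io import ExpressionMatrix
from .diff_expr import bh_fdr
from .target_pred import TargetMap


def hypergeom_shared_p(k: int, K: int, n: int, M: int) -> float:
    """Upper-tail hypergeometric probability P(X ≥ k) for X ~ HG(M, K, n),
    computed exactly from binomial coefficients."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if not (0 <= K <= M and 0 <= n <= M):
        raise ValueError("require 0 <= K, n <= M")
    if not 0 <= k <= min(K, n):
        raise ValueError("require 0 <= k <= min(K, n)")
    denom = math.comb(M, n)
    total = sum(
        math.comb(K, x) * math.comb(M - K, n - x) for x in range(k, min(K, n) + 1)
    )
    return total / denom


@dataclass(frozen=True)
class CeRNAPair:
    """One candidate lncRNA–mRNA pair with its shared-miRNA statistics."""

    lnc_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    k: int
    K: int
    n: int
    M: int
    p_hyper: float
    fdr: float = float("nan")
    corr_lnc_mrna: float = float("nan")
    de_shared_mirnas: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ScreenThresholds:
    min_shared: int = 3
    max_p: float = 0.05
    max_fdr: float = 0.1


def screen_pairs(
    targets: TargetMap,
    thresholds: ScreenThresholds | None = None,
    universe_size: int | None = None,
    return_all: bool = False,
) -> list[CeRNAPair]:
    """Enumerate all lncRNA–mRNA pairs sharing at least one miRNA, compute
    the hypergeometric p and BH-FDR across the enumerated set, and keep
    pairs with k ≥ min_shared, p < max_p and fdr < max_fdr.

    The miRNA universe M defaults to the miRNAs with at least one target in
    the analysed set. ``return_all`` skips the final threshold filter (the
    FDR is still computed over all enumerated pairs).
    """
    th = thresholds or ScreenThresholds()
    if not targets.mirna_ids:
        raise ValueError("empty TargetMap")
    M = universe_size if universe_size is not None else targets.universe_size()

    lnc_of: dict[str, set[str]] = {}  # lnc id -> miRNAs targeting it
    mrna_of: dict[str, set[str]] = {}
    for m, ts in targets.lnc_targets.items():
        for t in ts:
            lnc_of.setdefault(t, set()).add(m)
    for m, ts in targets.mrna_targets.items():
        for t in ts:
            mrna_of.setdefault(t, set()).add(m)

    # pairs with k >= 1, via the shared-miRNA inverted index
    pair_ids = set()
    for m in targets.mirna_ids:
        for l in targets.lnc_targets.get(m, ()):
            for r in targets.mrna_targets.get(m, ()):
                pair_ids.add((l, r))

    pairs: list[CeRNAPair] = []
    for l, r in sorted(pair_ids):
        shared = lnc_of[l] & mrna_of[r]
        K, n, k = len(lnc_of[l]), len(mrna_of[r]), len(shared)
        pairs.append(
            CeRNAPair(
                lnc_id=l,
                mrna_id=r,
                shared_mirnas=frozenset(shared),
                k=k,
                K=K,
                n=n,
                M=M,
                p_hyper=hypergeom_shared_p(k, K, n, M),
            )
        )
    if pairs:
        fdrs = bh_fdr([p.p_hyper for p in pairs])
        pairs = [replace(p, fdr=float(f)) for p, f in zip(pairs, fdrs)]
    if not return_all:
        pairs = [
            p
            for p in pairs
            if p.k >= th.min_shared and p.p_hyper < th.max_p and p.fdr < th.max_fdr
        ]
    pairs.sort(key=lambda p: (p.p_hyper, p.lnc_id, p.mrna_id))
    return pairs


Edge = tuple[str, str, str]  # (source, edge_type, target)


def intersect_de(
    pairs: Sequence[CeRNAPair],
    de_lnc: Mapping[str, str],
    de_mir: Mapping[str, str],
    de_mrna: Mapping[str, str],
) -> tuple[list[CeRNAPair], list[Edge]]:
    """Keep pairs whose lncRNA, mRNA and at least one shared miRNA are all
    differentially expressed; emit the surviving miRNA-centric edges.

    The de_* maps give feature → direction ('up'/'down'); features absent or
    'ns' are not DE.
    """

    def _is_de(d: Mapping[str, str], fid: str) -> bool:
        return d.get(fid, "ns") in ("up", "down")

    kept: list[CeRNAPair] = []
    edges: list[Edge] = []
    for p in pairs:
        if not (_is_de(de_lnc, p.lnc_id) and _is_de(de_mrna, p.mrna_id)):
            continue
        de_shared = frozenset(m for m in p.shared_mirnas if _is_de(de_mir, m))
        if not de_shared:
            continue
        kept.append(replace(p, de_shared_mirnas=de_shared))
        for m in sorted(de_shared):
            edges.append((p.lnc_id, "mir-target", m))
            edges.append((m, "mir-target", p.mrna_id))
    return kept, sorted(set(edges))


def _log_expr(expr: ExpressionMatrix, fid: str, samples: Sequence[str]) -> np.ndarray:
    return np.log2(expr.values.loc[fid, list(samples)].to_numpy(dtype=float) + 1.0)


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")  # undefined for constant vectors
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def sign_filter(
    pairs: Sequence[CeRNAPair],
    expr_lnc: ExpressionMatrix,
    expr_mir: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    de_lnc: Mapping[str, str] | None = None,
    de_mir: Mapping[str, str] | None = None,
    de_mrna: Mapping[str, str] | None = None,
    method: str = "pearson",
    min_abs_corr: float = 0.0,
) -> tuple[list[CeRNAPair], list[Edge]]:
    """Enforce the ceRNA sign pattern on log2(normalized + 1) expression:
    corr(miRNA, lncRNA) < 0, corr(miRNA, mRNA) < 0 and corr(lncRNA, mRNA)
    > 0, each with |corr| ≥ min_abs_corr.

    When fewer than 3 replicates per condition are available, or a vector is
    constant, the filter falls back to the DE-direction rule: the miRNA
    direction must oppose both targets and the targets must agree.
    """
    import warnings

    samples = [s for s in expr_lnc.sample_ids if s in expr_mir.sample_ids]
    n_per_group: dict[str, int] = {}
    for s in samples:
        c = expr_lnc.condition_of[s]
        n_per_group[c] = n_per_group.get(c, 0) + 1
    corr_mode = bool(n_per_group) and min(n_per_group.values()) >= 3

    def _direction_ok(p: CeRNAPair, mirna: str) -> bool:
        if de_lnc is None or de_mir is None or de_mrna is None:
            return False
        dl, dm, dr = de_lnc.get(p.lnc_id), de_mir.get(mirna), de_mrna.get(p.mrna_id)
        if "ns" in (dl, dm, dr) or None in (dl, dm, dr):
            return False
        return dl == dr and dm != dl

    kept: list[CeRNAPair] = []
    edges: list[Edge] = []
    for p in pairs:
        candidate_mirnas = sorted(p.de_shared_mirnas or p.shared_mirnas)
        if corr_mode:
            xl = _log_expr(expr_lnc, p.lnc_id, samples)
            xr = _log_expr(expr_mrna, p.mrna_id, samples)
            c_lr = _corr(xl, xr, method)
            if math.isnan(c_lr):
                warnings.warn(
                    f"constant expression for pair {p.lnc_id}-{p.mrna_id}; "
                    "falling back to DE directions"
                )
                passing = [m for m in candidate_mirnas if _direction_ok(p, m)]
                c_lr = float("nan")
            else:
                if not (c_lr > 0 and abs(c_lr) >= min_abs_corr):
                    continue
                passing = []
                for m in candidate_mirnas:
                    xm = _log_expr(expr_mir, m, samples)
                    c_ml = _corr(xm, xl, method)
                    c_mr = _corr(xm, xr, method)
                    if math.isnan(c_ml) or math.isnan(c_mr):
                        if _direction_ok(p, m):
                            passing.append(m)
                        continue
                    if (
                        c_ml < 0
                        and c_mr < 0
                        and abs(c_ml) >= min_abs_corr
                        and abs(c_mr) >= min_abs_corr
                    ):
                        passing.append(m)
        else:
            c_lr = float("nan")
            passing = [m for m in candidate_mirnas if _direction_ok(p, m)]
        if not passing:
            continue
        kept.append(
            replace(p, corr_lnc_mrna=c_lr, de_shared_mirnas=frozenset(passing))
        )
        for m in passing:
            edges.append((p.lnc_id, "mir-target", m))
            edges.append((m, "mir-target", p.mrna_id))
    kept.sort(key=lambda p: (p.p_hyper, p.lnc_id, p.mrna_id))
    return kept, sorted(set(edges))


@dataclass
class CeRNANetwork:
    """Typed lncRNA/miRNA/mRNA graph assembled from surviving pairs."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def node_counts(self) -> dict[str, int]:
        counts = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
        for _, d in self.graph.nodes(data=True):
            counts[d["node_type"]] = counts.get(d["node_type"], 0) + 1
        return counts

    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)


def build_network(
    pairs: Sequence[CeRNAPair],
    edges: Sequence[Edge],
    node_class: Mapping[str, str] | None = None,
    de_direction: Mapping[str, str] | None = None,
) -> CeRNANetwork:
    """Assemble the typed network: lncRNA–mRNA 'ceRNA' edges carry the pair
    statistics, miRNA edges are typed 'mir-target'; nodes carry class and DE
    direction. Duplicate edges collapse; ordering is deterministic."""
    de_direction = de_direction or {}
    g = nx.Graph()

    classes: dict[str, str] = dict(node_class or {})
    for p in pairs:
        classes.setdefault(p.lnc_id, "lncRNA")
        classes.setdefault(p.mrna_id, "mRNA")
        for m in p.shared_mirnas:
            classes.setdefault(m, "miRNA")
    for s, _, t in edges:
        classes.setdefault(s, "miRNA")
        classes.setdefault(t, "miRNA")

    node_ids = sorted(
        {p.lnc_id for p in pairs}
        | {p.mrna_id for p in pairs}
        | {m for p in pairs for m in p.de_shared_mirnas}
        | {s for s, _, t in edges}
        | {t for s, _, t in edges}
    )
    for nid in node_ids:
        g.add_node(
            nid,
            node_type=classes.get(nid, "unknown"),
            direction=de_direction.get(nid, "ns"),
        )
    for p in sorted(pairs, key=lambda p: (p.lnc_id, p.mrna_id)):
        g.add_edge(
            p.lnc_id,
            p.mrna_id,
            edge_type="ceRNA",
            shared_mirnas=";".join(sorted(p.shared_mirnas)),
            k=p.k,
            p_hyper=p.p_hyper,
            fdr=p.fdr,
            corr_lnc_mrna=p.corr_lnc_mrna,
        )
    for s, etype, t in sorted(set(edges)):
        if not g.has_edge(s, t):
            g.add_edge(s, t, edge_type=etype)
    return CeRNANetwork(g)


def export_network(
    net: CeRNANetwork, out_dir: str | Path, formats: Sequence[str] = ("SIF", "GraphML", "TSV")
) -> list[Path]:
    """Write Cytoscape-importable files (byte-deterministic).

    SIF rows are ``source<TAB>interaction<TAB>target``; TSV exports are a
    node-attribute and an edge-attribute table; GraphML via networkx.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = net.graph
    written: list[Path] = []
    edge_rows = sorted(
        (min(u, v), max(u, v), d) for u, v, d in g.edges(data=True)
    )
    for fmt in formats:
        if fmt == "SIF":
            path = out_dir / "network.sif"
            with open(path, "w") as fh:
                for u, v, d in edge_rows:
                    fh.write(f"{u}\t{d['edge_type']}\t{v}\n")
            written.append(path)
        elif fmt == "GraphML":
            path = out_dir / "network.graphml"
            nx.write_graphml(g, path, named_key_ids=True)
            written.append(path)
        elif fmt == "TSV":
            npath = out_dir / "nodes.tsv"
            rows = [
                {"id": n, "node_type": d["node_type"], "direction": d["direction"]}
                for n, d in sorted(g.nodes(data=True))
            ]
            pd.DataFrame(rows, columns=["id", "node_type", "direction"]).to_csv(
                npath, sep="\t", index=False, lineterminator="\n"
            )
            epath = out_dir / "edges.tsv"
            cols = ["source", "target", "edge_type", "shared_mirnas", "k",
                    "p_hyper", "fdr", "corr_lnc_mrna"]
            erows = [
                {"source": u, "target": v, **{c: d.get(c, "") for c in cols[2:]}}
                for u, v, d in edge_rows
            ]
            pd.DataFrame(erows, columns=cols).to_csv(
                epath, sep="\t", index=False, lineterminator="\n"
            )
            written.extend([npath, epath])
        else:
            raise ValueError(f"unknown export format {fmt!r}")
    return written


def import_network_tsv(node_path: str | Path, edge_path: str | Path) -> CeRNANetwork:
    """Round-trip reader for the TSV export."""
    nodes = pd.read_csv(node_path, sep="\t")
    edges = pd.read_csv(edge_path, sep="\t")
    g = nx.Graph()
    for _, r in nodes.iterrows():
        g.add_node(r["id"], node_type=r["node_type"], direction=r["direction"])
    for _, r in edges.iterrows():
        g.add_edge(r["source"], r["target"], edge_type=r["edge_type"])
    return CeRNANetwork(g)
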