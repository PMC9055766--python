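"""Normalization, fold change and per-class differential-expression screening.

Expression is normalized to FPKM (long RNAs) or TPM (miRNA); fold change is
the ratio of condition means on the normalized scale with a pseudocount; the
built-in p-value source is a Welch two-sample t-test on log2(normalized + 1),
and any external per-feature p table can be substituted. Screening thresholds
are per RNA class: |log2FC| ≥ 2 with P < 0.05 for lncRNA, |log2FC| ≥ 1 with
P < 0.05 for miRNA, and |log2FC| ≥ 2 with BH-FDR < 0.05 for mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotation_io import ExpressionMatrix

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DEThresholds:
    rna_class: str
    min_abs_log2fc: float
    alpha: float
    alpha_is_fdr: bool

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


#: published per-class screening thresholds
LNCRNA_THRESHOLDS = DEThresholds("lncRNA", 2.0, 0.05, False)
MIRNA_THRESHOLDS = DEThresholds("miRNA", 1.0, 0.05, False)
MRNA_THRESHOLDS = DEThresholds("mRNA", 2.0, 0.05, True)

CLASS_THRESHOLDS = {
    "lncRNA": LNCRNA_THRESHOLDS,
    "miRNA": MIRNA_THRESHOLDS,
    "mRNA": MRNA_THRESHOLDS,
}


def _require_lengths(expr: ExpressionMatrix, lengths: Mapping[str, int]) -> np.ndarray:
    missing = [f for f in expr.feature_ids if f not in lengths]
    if missing:
        raise KeyError(f"features without length: {missing[:5]}")
    arr = np.array([lengths[f] for f in expr.feature_ids], dtype=float)
    if (arr <= 0).any():
        raise ValueError("all feature lengths must be > 0")
    return arr


def fpkm(counts: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments:
    count · 1e9 / (length_nt · library_size)."""
    if counts.unit != "count":
        raise ValueError("fpkm expects raw counts")
    lens = _require_lengths(counts, lengths)
    lib = counts.values.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library size must be > 0 for every sample")
    vals = counts.values.mul(1e9).div(lib, axis=1).div(lens, axis=0)
    return counts.with_unit(vals, "FPKM")


def tpm(counts: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Transcripts per million: length-normalized rates rescaled so each
    sample sums to 1e6 (all-zero samples stay zero, with a warning)."""
    import warnings

    if counts.unit != "count":
        raise ValueError("tpm expects raw counts")
    lens = _require_lengths(counts, lengths)
    rates = counts.values.div(lens, axis=0)
    denom = rates.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(f"all-zero samples in TPM: {list(denom.index[zero])}")
        denom = denom.replace(0, np.nan)
    vals = rates.div(denom, axis=1).mul(1e6).fillna(0.0)
    return counts.with_unit(vals, "TPM")


def _group_means(
    expr: ExpressionMatrix, ctrl: str, trt: str
) -> tuple[pd.Series, pd.Series]:
    cs, ts = expr.samples_of(ctrl), expr.samples_of(trt)
    if not cs or not ts:
        raise ValueError(f"need >= 1 replicate per condition ({ctrl!r}, {trt!r})")
    return expr.values[cs].mean(axis=1), expr.values[ts].mean(axis=1)


def log2_fold_change(
    expr: ExpressionMatrix,
    ctrl: str,
    trt: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """log2((mean_trt + pseudocount) / (mean_ctrl + pseudocount))."""
    mc, mt = _group_means(expr, ctrl, trt)
    return np.log2((mt + pseudocount) / (mc + pseudocount))


def welch_log_p(expr: ExpressionMatrix, ctrl: str, trt: str) -> pd.Series:
    """Built-in p-value source: Welch two-sample t on log2(normalized + 1).

    Constant features (zero variance in both groups with equal means) get
    p = 1.
    """
    cs, ts = expr.samples_of(ctrl), expr.samples_of(trt)
    a = np.log2(expr.values[cs].to_numpy() + 1.0)
    b = np.log2(expr.values[ts].to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.Series(p, index=expr.values.index)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def specific_expression(
    expr: ExpressionMatrix, ctrl: str, trt: str, min_expr: float = 0.1
) -> dict[str, str]:
    """Condition-specific calls: a feature is treatment-specific when every
    treatment replicate is >= min_expr and every control replicate is below
    it (and symmetrically for control-specific)."""
    cs, ts = expr.samples_of(ctrl), expr.samples_of(trt)
    c = expr.values[cs].to_numpy()
    t = expr.values[ts].to_numpy()
    trt_spec = (t >= min_expr).all(axis=1) & (c < min_expr).all(axis=1)
    ctrl_spec = (c >= min_expr).all(axis=1) & (t < min_expr).all(axis=1)
    out = {}
    for fid, a, b in zip(expr.feature_ids, ctrl_spec, trt_spec):
        out[fid] = "ctrl_specific" if a else ("trt_specific" if b else "none")
    return out


def de_screen(stats: pd.DataFrame, th: DEThresholds) -> pd.DataFrame:
    """Assign DE direction from a per-feature stats table.

    ``stats`` must carry columns feature_id, log2fc and p (plus optional
    mean_ctrl/mean_trt/specific). BH-FDR is computed over the tested set;
    when th.alpha_is_fdr the FDR, not p, is compared to alpha.
    """
    req = {"feature_id", "log2fc", "p"}
    if not req.issubset(stats.columns):
        raise ValueError(f"stats table must have columns {sorted(req)}")
    p = stats["p"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = stats.copy()
    out["fdr"] = bh_fdr(p)
    crit = out["fdr"] if th.alpha_is_fdr else out["p"]
    passing = (out["log2fc"].abs() >= th.min_abs_log2fc) & (crit < th.alpha)
    out["direction"] = np.where(
        passing & (out["log2fc"] > 0), "up", np.where(passing, "down", "ns")
    )
    if "specific" not in out.columns:
        out["specific"] = "none"
    return out.reset_index(drop=True)


def de_stats_table(
    expr: ExpressionMatrix,
    ctrl: str,
    trt: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    external_p: Mapping[str, float] | None = None,
    specific_min_expr: float = 0.1,
) -> pd.DataFrame:
    """Assemble the per-feature stats table (means, log2fc, p, specific flag)
    from a normalized matrix, using the built-in Welch test unless an
    external p table is supplied."""
    mc, mt = _group_means(expr, ctrl, trt)
    lfc = log2_fold_change(expr, ctrl, trt, pseudocount)
    if external_p is not None:
        p = pd.Series(
            [external_p[f] for f in expr.feature_ids], index=expr.values.index
        )
    else:
        p = welch_log_p(expr, ctrl, trt)
    spec = specific_expression(expr, ctrl, trt, specific_min_expr)
    return pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "mean_ctrl": mc.to_numpy(),
            "mean_trt": mt.to_numpy(),
            "log2fc": lfc.to_numpy(),
            "p": p.to_numpy(),
            "specific": [spec[f] for f in expr.feature_ids],
        }
    )


def run_de(
    expr: ExpressionMatrix,
    rna_class: str,
    ctrl: str,
    trt: str,
    external_p: Mapping[str, float] | None = None,
    thresholds: DEThresholds | None = None,
    specific_min_expr: float | None = None,
) -> pd.DataFrame:
    """Normalized matrix → screened DE table for one RNA class."""
    th = thresholds or CLASS_THRESHOLDS[rna_class]
    # miRNA specificity is judged on TPM, long RNAs on FPKM
    min_expr = specific_min_expr if specific_min_expr is not None else (
        1.0 if rna_class == "miRNA" else 0.1
    )
    stats = de_stats_table(
        expr, ctrl, trt, external_p=external_p, specific_min_expr=min_expr
    )
    return de_screen(stats, th)


def de_summary(de_table: pd.DataFrame) -> dict[str, int]:
    """Bookkeeping totals of a screened DE table."""
    up = int((de_table["direction"] == "up").sum())
    down = int((de_table["direction"] == "down").sum())
    return {"up": up, "down": down, "total_de": up + down,
            "tested": int(len(de_table))}


def zscore_log_matrix(expr: ExpressionMatrix, feature_ids: Sequence[str]) -> pd.DataFrame:
    """Row-z-scored log2(normalized + 1) matrix of the DE features — the
    exportable substrate of the hierarchical-clustering heatmaps."""
    m = np.log2(expr.values.loc[list(feature_ids)].to_numpy() + 1.0)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame(
        (m - mu) / sd, index=list(feature_ids), columns=expr.sample_ids
    )
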