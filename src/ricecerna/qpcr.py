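"""Relative quantification of qPCR data by the 2^-ΔΔCt method.

Each replicate's target Ct is normalized against the internal reference gene
(ΔCt = Ct_target − Ct_reference; β-actin for long RNAs, U6 for miRNA is the
usual convention), ΔΔCt is the treatment-minus-control difference of mean
ΔCt, and the relative expression fold is 2^(−ΔΔCt). Group differences are
tested with a Welch two-sample t-test and annotated with significance stars
(* p < 0.05, ** p < 0.01).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

CT_COLUMNS = (
    "target_id",
    "sample_id",
    "condition",
    "replicate_index",
    "ct_target",
    "ct_reference",
    "reference_gene",
)


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    for col in ("ct_target", "ct_reference"):
        vals = df[col].to_numpy(dtype=float)
        if ((vals <= 0) | (vals >= 45)).any():
            raise ValueError(f"{col}: Ct values must lie in (0, 45) cycles")
    return df


def ddct_fold_change(
    ct: pd.DataFrame, target_id: str, ctrl_label: str, trt_label: str
) -> dict:
    """2^-ΔΔCt relative expression of one target between two conditions.

    Returns the fold, the reporting phrase ("x.x times up" for fold ≥ 1,
    reciprocal "times down" otherwise), the raw ΔΔCt, and the fold-scale
    standard deviation propagated from the replicate ΔCt spread by the delta
    method (sd ≈ fold · ln2 · se(ΔΔCt)).
    """
    ct = validate_ct_table(ct)
    sub = ct[ct["target_id"] == target_id]
    rows = {}
    for label in (ctrl_label, trt_label):
        grp = sub[sub["condition"] == label]
        if grp.empty:
            raise ValueError(f"condition {label!r} missing for target {target_id!r}")
        rows[label] = (
            grp["ct_target"].to_numpy(dtype=float)
            - grp["ct_reference"].to_numpy(dtype=float)
        )
    dct_c, dct_t = rows[ctrl_label], rows[trt_label]
    ddct = dct_t.mean() - dct_c.mean()
    fold = 2.0 ** (-ddct)
    se = math.sqrt(
        (dct_c.var(ddof=1) / len(dct_c) if len(dct_c) > 1 else 0.0)
        + (dct_t.var(ddof=1) / len(dct_t) if len(dct_t) > 1 else 0.0)
    )
    sd = fold * math.log(2.0) * se
    if fold >= 1:
        direction_text = f"{fold:.1f} times up"
    else:
        direction_text = f"{1.0 / fold:.1f} times down"
    return {
        "target_id": target_id,
        "fold": fold,
        "ddct": ddct,
        "direction_text": direction_text,
        "sd": sd,
    }


def significance_stars(
    ctrl_vals: Sequence[float], trt_vals: Sequence[float]
) -> dict:
    """Welch two-sided t-test with star annotation ('' / '*' / '**' at
    p < 0.05 / 0.01). Two identical constant groups give p = 1."""
    a = np.asarray(list(ctrl_vals), dtype=float)
    b = np.asarray(list(trt_vals), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    if math.isnan(p):  # zero variance in both groups
        p = 1.0 if a.mean() == b.mean() else 0.0
    stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
    return {"p": p, "stars": stars}


def qpcr_report(
    ct: pd.DataFrame, ctrl_label: str, trt_label: str
) -> pd.DataFrame:
    """Per-target fold change, reporting phrase and significance stars."""
    rows = []
    for target in sorted(ct["target_id"].unique()):
        fc = ddct_fold_change(ct, target, ctrl_label, trt_label)
        sub = ct[ct["target_id"] == target]
        dct = sub["ct_target"] - sub["ct_reference"]
        rel = 2.0 ** -(dct - dct[sub["condition"] == ctrl_label].mean())
        sig = significance_stars(
            rel[sub["condition"] == ctrl_label],
            rel[sub["condition"] == trt_label],
        )
        rows.append({**fc, **sig})
    return pd.DataFrame(
        rows,
        columns=["target_id", "fold", "ddct", "direction_text", "sd", "p", "stars"],
    )
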