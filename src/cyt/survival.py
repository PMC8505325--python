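"""Kaplan-Meier estimation, log-rank testing and the two-gene survival
synergy analysis (both-high / both-low vs the rest).

The product-limit estimator and the Mantel-Cox log-rank test are standard;
they are computed through lifelines, with the Greenwood variance reported
as a 95% confidence band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


def km_estimate(clinical: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Kaplan-Meier table(s): time, at-risk count, survival and Greenwood
    95% CI, one block per group when ``group`` names a column."""
    def one(sub: pd.DataFrame, label: str) -> pd.DataFrame:
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_days"], sub["event"], label="S")
        table = kmf.event_table
        sf = kmf.survival_function_["S"]
        ci = kmf.confidence_interval_
        out = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].reindex(sf.index).to_numpy(),
            "S": sf.to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
        })
        out["group"] = label
        return out

    if group is None:
        return one(clinical, "all")
    return pd.concat(
        [one(sub, str(label)) for label, sub in clinical.groupby(group)],
        ignore_index=True,
    )


def logrank_test(clinical: pd.DataFrame, group_col: str, group_a, group_b):
    """Two-group Mantel-Cox log-rank test; returns (chi2 statistic, p)."""
    a = clinical[clinical[group_col] == group_a]
    b = clinical[clinical[group_col] == group_b]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if a["event"].sum() + b["event"].sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")
    res = _ll_logrank(
        a["time_days"], b["time_days"], a["event"], b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def dichotomize(expr_row: pd.Series, cutpoint: str = "median") -> pd.Series:
    """High/low labels for one gene across samples at the median (default)
    or quartile cutpoints ('q25'/'q75')."""
    x = expr_row.astype(float)
    if cutpoint == "median":
        cut = float(x.median())
    elif cutpoint == "q25":
        cut = float(x.quantile(0.25))
    elif cutpoint == "q75":
        cut = float(x.quantile(0.75))
    else:
        raise ValueError(f"unknown cutpoint {cutpoint!r}")
    return pd.Series(np.where(x > cut, "high", "low"), index=x.index)


def synergy_analysis(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    gene_a: str = "GZMA",
    gene_b: str = "PRF1",
    cutpoint: str = "median",
) -> pd.DataFrame:
    """Four log-rank contrasts for the two-gene synergy question:
    A-high vs A-low, B-high vs B-low, both-high vs other, both-low vs other.

    P-values are reported raw (no multiplicity correction across the four
    contrasts by default).
    """
    for g in (gene_a, gene_b):
        if g not in expr.index:
            raise KeyError(f"gene {g!r} not in expression matrix")
    clin = clinical.set_index("sample")
    common = clin.index.intersection(expr.columns)
    clin = clin.loc[common].copy()
    ha = dichotomize(expr.loc[gene_a, common], cutpoint)
    hb = dichotomize(expr.loc[gene_b, common], cutpoint)

    contrasts = {
        f"{gene_a}_high_vs_low": pd.Series(
            np.where(ha == "high", "pos", "neg"), index=common),
        f"{gene_b}_high_vs_low": pd.Series(
            np.where(hb == "high", "pos", "neg"), index=common),
        "both_high_vs_other": pd.Series(
            np.where((ha == "high") & (hb == "high"), "pos", "neg"), index=common),
        "both_low_vs_other": pd.Series(
            np.where((ha == "low") & (hb == "low"), "pos", "neg"), index=common),
    }
    rows = []
    for name, labels in contrasts.items():
        clin["__grp"] = labels
        stat, p = logrank_test(clin.reset_index(), "__grp", "pos", "neg")
        rows.append({
            "contrast": name, "chi2": stat, "p": p,
            "n_pos": int((labels == "pos").sum()),
            "n_neg": int((labels == "neg").sum()),
        })
    return pd.DataFrame(rows)
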