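"""Shared statistical helpers: group comparison and multiplicity adjustment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    p_adjusted: float
    n_a: int
    n_b: int
    method: str = "mann-whitney"
    correction: str = "none"


def mann_whitney(a, b, alternative: str = "two-sided"):
    """Two-sided Mann-Whitney U with midrank tie handling.

    Uses the exact distribution for small tie-free samples, the normal
    approximation with tie correction otherwise (scipy's default policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(pvals, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg ('bh') or Bonferroni ('bonferroni') adjustment."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}[
        method.lower()
    ]
    return multipletests(pvals, method=key)[1]


def compare_groups(
    values,
    groups,
    group_a: str = "high",
    group_b: str = "low",
    correction: str = "none",
    m_tests: int = 1,
) -> GroupComparison:
    """Mann-Whitney U comparison of ``values`` between two group labels.

    ``m_tests`` sets the Bonferroni family size when this comparison is one
    of a family tested together; BH adjustment of a single p is the p
    itself, so families should prefer :func:`compare_groups_table`.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    a = values[groups == group_a]
    b = values[groups == group_b]
    if a.size == 0 or b.size == 0:
        raise ValueError(f"empty group: {group_a} n={a.size}, {group_b} n={b.size}")
    stat, p = mann_whitney(a, b)
    if correction.lower() in ("none",):
        p_adj = p
    elif correction.lower() == "bonferroni":
        p_adj = min(1.0, m_tests * p)
    else:
        p_adj = float(adjust_pvalues([p], correction)[0])
    return GroupComparison(stat, p, p_adj, a.size, b.size, correction=correction)


def compare_groups_table(
    df: pd.DataFrame,
    value_cols,
    group_col: str,
    group_a: str = "high",
    group_b: str = "low",
    correction: str = "bh",
) -> pd.DataFrame:
    """One Mann-Whitney test per column, jointly multiplicity-adjusted."""
    rows = []
    for col in value_cols:
        res = compare_groups(
            df[col].to_numpy(), df[group_col].to_numpy(), group_a, group_b
        )
        rows.append({"variable": col, "U": res.statistic, "p": res.p_value,
                     "n_a": res.n_a, "n_b": res.n_b})
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), correction)
    out["correction"] = correction
    return out
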