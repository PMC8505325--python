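"""Cytolytic-activity (CYT) scoring and quartile stratification.

CYT for a sample is the geometric mean of its GZMA and PRF1 expression in
TPM: ``CYT = sqrt((GZMA + eps)(PRF1 + eps))`` with a small pseudocount
``eps`` (default 0.01 TPM) so a zero does not annihilate the product.  The
cohort is split, within each tumor-type stratum, into the upper quartile
(CYT-high), the lower quartile (CYT-low) and the remainder (mid).

Percentiles use linear interpolation (numpy default, type 7); samples whose
CYT exactly equals a quartile boundary go to ``mid``, which keeps the
extreme groups conservative and makes the all-tied cohort degenerate to
all-mid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import compare_groups, compare_groups_table, adjust_pvalues  # noqa: F401
from .synthetic import IFNG_SIGNATURE, EXPANDED_IMMUNE_SIGNATURE  # noqa: F401

DEFAULT_PSEUDOCOUNT = 0.01


def compute_cyt(expr: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
    """Per-sample CYT (TPM-scale geometric mean of GZMA and PRF1)."""
    for gene in ("GZMA", "PRF1"):
        if gene not in expr.index:
            raise KeyError(f"expression matrix lacks required gene row {gene!r}")
    gz = expr.loc["GZMA"].astype(float)
    pr = expr.loc["PRF1"].astype(float)
    if (gz < 0).any() or (pr < 0).any():
        raise ValueError("negative TPM values for GZMA/PRF1")
    cyt = np.sqrt((gz + pseudocount) * (pr + pseudocount))
    cyt.name = "CYT"
    return cyt


def stratify_quartiles(
    cyt: pd.Series,
    strata: pd.Series | None = None,
    min_stratum_size: int = 4,
) -> pd.DataFrame:
    """Quartile groups per stratum: high (> 75th pct), low (< 25th pct), mid.

    ``strata`` maps sample -> tumor type; ``None`` pools the cohort.  Strata
    with fewer than ``min_stratum_size`` samples are skipped (all mid) with
    a warning.  Boundary ties go to mid, so an all-tied stratum is all mid.
    """
    if strata is None:
        strata = pd.Series("all", index=cyt.index)
    strata = strata.reindex(cyt.index)
    group = pd.Series("mid", index=cyt.index, dtype=object)
    for label, idx in cyt.groupby(strata).groups.items():
        values = cyt.loc[idx]
        if len(values) < min_stratum_size:
            warnings.warn(
                f"stratum {label!r} has {len(values)} < {min_stratum_size} samples; "
                "skipped (assigned mid)", stacklevel=2,
            )
            continue
        q25, q75 = np.quantile(values.to_numpy(), [0.25, 0.75])
        group.loc[values.index[values > q75]] = "high"
        group.loc[values.index[values < q25]] = "low"
    out = pd.DataFrame({
        "CYT": cyt,
        "cyt_log2": np.log2(cyt),
        "group": group,
        "tumor_type": strata,
    })
    out.index.name = "sample"
    return out


def coexpression_rho(expr: pd.DataFrame, gene_a: str, gene_b: str):
    """Spearman rank correlation (midrank ties) between two gene rows."""
    for g in (gene_a, gene_b):
        if g not in expr.index:
            raise KeyError(f"gene {g!r} not in expression matrix")
    res = sps.spearmanr(expr.loc[gene_a], expr.loc[gene_b])
    return float(res.statistic), float(res.pvalue)


def signature_score(expr: pd.DataFrame, gene_set, ddof: int = 1) -> pd.Series:
    """Mean per-gene z-score (z across samples) over the set's genes present
    in the matrix.  The number of genes used is in ``.attrs['n_genes_used']``."""
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    sub = expr.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=ddof)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    z[sd == 0] = 0.0
    score = z.mean(axis=0)
    score.name = "score"
    score.attrs["n_genes_used"] = len(present)
    return score
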