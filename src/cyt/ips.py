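"""Immunophenoscore (IPS): sample-wise z-scores, the four immunophenogram
categories (MHC molecules, immunomodulators/checkpoints CP, effector cells
EC, suppressor cells SC), and the 0-10 aggregate score.

Scores follow the published immunophenogram construction: per-gene z-scores
across samples, factor scores as weighted means of member-gene z-scores,
category scores as plain means of their factor scores, and the aggregate
``AZ`` as the sum of the four category scores (checkpoint and suppressor
weights are negative, so immunosuppressive expression lowers AZ).  IPS is
0 for AZ <= 0, 10 for AZ >= 3, and ``round(AZ * 10/3)`` in between
(numpy half-to-even rounding).

The bundled weight table is a synthetic fixture (the gene/weight
assignments of the original immunophenogram are not reproduced here); it
ships as an editable TSV so a user can substitute the published table.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .stats import compare_groups, GroupComparison

IPS_CATEGORIES = ("MHC", "CP", "EC", "SC")

WEIGHT_TABLE_RESOURCE = "ips_weights_synthetic.tsv"


def default_weight_table() -> pd.DataFrame:
    """The bundled synthetic weight table (gene, factor, category, weight)."""
    ref = resources.files("cyt.data").joinpath(WEIGHT_TABLE_RESOURCE)
    with ref.open() as fh:
        return read_weight_table(fh)


def read_weight_table(path_or_buf) -> pd.DataFrame:
    wt = pd.read_csv(path_or_buf, sep="\t")
    required = {"gene", "factor", "category", "weight"}
    if not required <= set(wt.columns):
        raise ValueError(f"weight table needs columns {sorted(required)}")
    bad = set(wt["category"].unique()) - set(IPS_CATEGORIES)
    if bad:
        raise ValueError(f"unknown IPS categories {sorted(bad)}")
    return wt


def samplewise_zscores(expr: pd.DataFrame, genes=None, ddof: int = 1) -> pd.DataFrame:
    """Per-gene z-score across samples: (x - mean) / sd per row.

    ``ddof=1`` (sample sd) by default.  Zero-variance genes get z = 0 with
    a warning rather than NaN.
    """
    sub = expr if genes is None else expr.loc[[g for g in genes if g in expr.index]]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=ddof)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s) set to z=0", stacklevel=2
        )
    z = sub.sub(mean, axis=0).div(sd.where(~flat, 1.0), axis=0)
    z[flat] = 0.0
    return z


def category_scores(
    expr: pd.DataFrame, weights: pd.DataFrame | None = None, ddof: int = 1
) -> pd.DataFrame:
    """Per-sample scores for MHC, CP, EC and SC.

    Factor score = weighted mean of member-gene z-scores; category score =
    unweighted mean of its factor scores.  Genes absent from the matrix are
    dropped (a factor losing all its genes is dropped with a warning).
    """
    if weights is None:
        weights = default_weight_table()
    present = weights[weights["gene"].isin(expr.index)]
    lost = set(weights["gene"]) - set(present["gene"])
    if lost:
        warnings.warn(f"{len(lost)} weight-table gene(s) absent from matrix",
                      stacklevel=2)
    z = samplewise_zscores(expr, genes=list(dict.fromkeys(present["gene"])), ddof=ddof)
    out = {}
    for cat in IPS_CATEGORIES:
        wcat = present[present["category"] == cat]
        factor_scores = []
        for _, wfac in wcat.groupby("factor", sort=True):
            w = wfac["weight"].to_numpy(dtype=float)
            zg = z.loc[wfac["gene"]].to_numpy()
            denom = np.abs(w).sum()
            if denom == 0:
                continue
            factor_scores.append((w[:, None] * zg).sum(axis=0) / denom)
        if not factor_scores:
            warnings.warn(f"category {cat} has no usable factors", stacklevel=2)
            out[cat] = np.zeros(expr.shape[1])
        else:
            out[cat] = np.mean(factor_scores, axis=0)
    return pd.DataFrame(out, index=expr.columns)


def ips_score(cat_scores: pd.DataFrame) -> pd.DataFrame:
    """Aggregate AZ and the integer IPS in [0, 10].

    AZ = MHC + CP + EC + SC (negative CP/SC weights are already encoded in
    the weight table).  IPS saturates at 0 for AZ <= 0 and 10 for AZ >= 3,
    linear (x 10/3, rounded half-to-even) in between.
    """
    az = cat_scores[list(IPS_CATEGORIES)].sum(axis=1)
    ips = np.rint(np.clip(az, 0.0, 3.0) * (10.0 / 3.0)).astype(int)
    out = cat_scores.copy()
    out["AZ"] = az
    out["IPS"] = ips
    return out


def compute_ips(
    expr: pd.DataFrame, weights: pd.DataFrame | None = None, ddof: int = 1
) -> pd.DataFrame:
    """Full IPS table: per-sample MHC, CP, EC, SC, AZ and IPS."""
    return ips_score(category_scores(expr, weights, ddof=ddof))


def compare_ips(ips_table: pd.DataFrame, groups: pd.Series) -> GroupComparison:
    """Mann-Whitney comparison of IPS between CYT-high and CYT-low samples."""
    common = ips_table.index.intersection(groups.index)
    res = compare_groups(
        ips_table.loc[common, "IPS"].to_numpy(), groups.loc[common].to_numpy()
    )
    return res


def wheel_table(
    expr: pd.DataFrame, weights: pd.DataFrame | None = None, ddof: int = 1
) -> pd.DataFrame:
    """Long-format immunophenogram data (sample, category, factor, gene, z,
    weight) for plotting the wheel."""
    if weights is None:
        weights = default_weight_table()
    present = weights[weights["gene"].isin(expr.index)]
    z = samplewise_zscores(expr, genes=list(dict.fromkeys(present["gene"])), ddof=ddof)
    rows = []
    for _, w in present.iterrows():
        for sample in expr.columns:
            rows.append({
                "sample": sample, "category": w["category"], "factor": w["factor"],
                "gene": w["gene"], "z": z.loc[w["gene"], sample],
                "weight": w["weight"],
            })
    return pd.DataFrame(rows)
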