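"""Intra-tumor heterogeneity: variant allele fractions, the MATH score and
VAF-distribution clustering.

MATH (mutant-allele tumor heterogeneity) is the percent-scale ratio of the
Gaussian-consistent scaled median absolute deviation to the median of a
sample's VAF distribution:

    MATH = 100 * 1.4826 * median(|VAF - median(VAF)|) / median(VAF)

Clustering fits 1-D Gaussian mixtures for k = 1..max_clusters and selects
k by BIC, with quantile-placed initial means so the fit is deterministic
for a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

MAD_CONSTANT = 1.4826


def compute_vaf(muts: pd.DataFrame) -> pd.DataFrame:
    """Add a ``vaf`` column (alt/(alt+ref)); records without usable counts
    are dropped, their number recorded in ``.attrs['n_excluded']``."""
    out = muts.copy()
    alt = pd.to_numeric(out.get("alt_count"), errors="coerce")
    ref = pd.to_numeric(out.get("ref_count"), errors="coerce")
    depth = alt + ref
    ok = depth.notna() & (depth > 0)
    out = out[ok].copy()
    out["vaf"] = (alt[ok] / depth[ok]).astype(float)
    out.attrs["n_excluded"] = int((~ok).sum())
    return out


def math_score(vafs) -> float:
    """Percent-scale MATH score of a VAF vector."""
    v = np.asarray(vafs, dtype=float)
    if v.size < 2:
        raise ValueError("MATH needs >= 2 VAF values")
    med = float(np.median(v))
    if med == 0:
        raise ValueError("MATH undefined: median VAF is 0")
    mad = float(np.median(np.abs(v - med)))
    return 100.0 * MAD_CONSTANT * mad / med


def cluster_vaf(vafs, max_clusters: int = 4, seed: int = 0) -> dict:
    """BIC-selected 1-D Gaussian-mixture clustering of a VAF vector.

    Fewer than 5 mutations forces k = 1 and flags the result low
    confidence.  Initial means are placed at quantiles, so the fit is
    deterministic for a fixed seed.
    """
    v = np.asarray(vafs, dtype=float).reshape(-1, 1)
    if v.shape[0] < 5:
        return {"n_clusters": 1, "means": [float(np.mean(v))] if v.size else [],
                "weights": [1.0] if v.size else [], "low_confidence": True,
                "bic": {}}
    best = None
    bics = {}
    for k in range(1, max_clusters + 1):
        means_init = np.quantile(v, np.linspace(0.1, 0.9, k)).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=k, covariance_type="full", random_state=seed,
            means_init=means_init, n_init=1, reg_covar=1e-4,
        ).fit(v)
        bic = gm.bic(v)
        bics[k] = float(bic)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, k, gm)
    _, k, gm = best
    order = np.argsort(gm.means_.ravel())
    return {
        "n_clusters": k,
        "means": gm.means_.ravel()[order].tolist(),
        "weights": gm.weights_[order].tolist(),
        "low_confidence": False,
        "bic": bics,
    }


def vaf_profiles(
    muts: pd.DataFrame, max_clusters: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Per-sample heterogeneity table: n_mutations, MATH, n_clusters and
    cluster means.  Samples whose MATH is undefined get NaN."""
    withv = compute_vaf(muts)
    rows = []
    for sample, grp in withv.groupby("Tumor_Sample_Barcode", sort=True):
        v = grp["vaf"].to_numpy()
        try:
            m = math_score(v)
        except ValueError:
            m = np.nan
        cl = cluster_vaf(v, max_clusters=max_clusters, seed=seed)
        rows.append({
            "sample": sample, "n_mutations": int(len(v)), "MATH": m,
            "n_clusters": cl["n_clusters"],
            "cluster_means": ",".join(f"{x:.4f}" for x in cl["means"]),
            "low_confidence": cl["low_confidence"],
        })
    return pd.DataFrame(rows, columns=["sample", "n_mutations", "MATH",
                                       "n_clusters", "cluster_means",
                                       "low_confidence"])
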