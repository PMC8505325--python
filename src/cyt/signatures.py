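"""De novo mutational-signature extraction (KL-NMF), cosine matching to a
reference catalog, per-sample exposure attribution and subgroup tests.

Extraction is a desk-scale re-implementation of the SigProfiler recipe:
for each candidate rank, many NMF restarts under the Kullback-Leibler
objective are clustered; stability is the weakest signature's cluster
cohesion (minimum per-cluster mean silhouette, cosine distance) and the
selected rank is the largest one whose stability clears a threshold
(default 0.8).  Consensus signatures are
cluster centroids, L1-normalized; exposures are per-sample non-negative
least-squares fits rescaled to mutation counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_samples

from .stats import adjust_pvalues, mann_whitney


def cosine_similarity(u, v) -> float:
    """u.v / (|u||v|); in [0, 1] for non-negative inputs."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class ExtractionResult:
    signatures: pd.DataFrame          # channels x signatures, columns sum to 1
    exposures: pd.DataFrame           # samples x signatures, count scale
    selected_rank: int
    diagnostics: pd.DataFrame         # per rank: stability, reconstruction error
    params: dict = field(default_factory=dict)

    @property
    def relative_exposures(self) -> pd.DataFrame:
        totals = self.exposures.sum(axis=1)
        return self.exposures.div(totals.where(totals > 0, 1.0), axis=0)


def _kl_divergence(X, WH) -> float:
    mask = X > 0
    wh = np.maximum(WH, 1e-12)
    return float((X[mask] * np.log(X[mask] / wh[mask])).sum() - X.sum() + WH.sum())


def extract_signatures_nmf(
    matrix: pd.DataFrame,
    rank_range=(2, 5),
    n_restarts: int = 20,
    seed: int = 0,
    stability_threshold: float = 0.8,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ExtractionResult:
    """De novo extraction from a channels x samples count matrix."""
    X = matrix.to_numpy(dtype=float)
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples for extraction")
    if X.sum() <= 0:
        raise ValueError("matrix has no counts")
    lo, hi = int(rank_range[0]), int(rank_range[-1])
    if hi > min(X.shape):
        raise ValueError(f"max rank {hi} exceeds min(matrix dims) {min(X.shape)}")

    rng = np.random.default_rng(seed)
    diag_rows = []
    per_rank: dict[int, tuple[np.ndarray, float]] = {}
    for rank in range(lo, hi + 1):
        sigs_all = []
        best_err = np.inf
        for _ in range(n_restarts):
            rs = int(rng.integers(0, 2**31 - 1))
            model = NMF(
                n_components=rank, solver="mu", beta_loss="kullback-leibler",
                init="random", max_iter=max_iter, tol=tol, random_state=rs,
            )
            with warnings.catch_warnings():
                # KL multiplicative updates routinely stop at max_iter;
                # restart clustering absorbs the residual wobble
                from sklearn.exceptions import ConvergenceWarning

                warnings.simplefilter("ignore", ConvergenceWarning)
                W = model.fit_transform(X)
            H = model.components_
            err = _kl_divergence(X, W @ H)
            best_err = min(best_err, err)
            colsum = W.sum(axis=0)
            W = W / np.where(colsum > 0, colsum, 1.0)
            sigs_all.append(W.T)  # rank x channels
        stacked = np.vstack(sigs_all)
        if rank == 1:
            stability = 1.0
            centroids = stacked.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=rank, n_init=10, random_state=seed)
            labels = km.fit_predict(stacked)
            if len(np.unique(labels)) < 2:
                stability = 0.0
            else:
                # weakest-signature stability: the minimum over clusters of
                # the mean silhouette of that cluster's members, so one
                # scattered (spurious) signature sinks the whole rank
                sil = silhouette_samples(stacked, labels, metric="cosine")
                stability = float(min(
                    sil[labels == k].mean() for k in range(rank)
                ))
            centroids = np.vstack([
                stacked[labels == k].mean(axis=0) for k in range(rank)
            ])
        per_rank[rank] = (centroids, stability)
        diag_rows.append({"rank": rank, "stability": stability,
                          "kl_reconstruction_error": best_err})
    diagnostics = pd.DataFrame(diag_rows)

    stable = diagnostics[diagnostics["stability"] >= stability_threshold]
    if len(stable):
        selected = int(stable["rank"].max())
    else:  # no stable rank: fall back to the most stable one
        selected = int(diagnostics.loc[diagnostics["stability"].idxmax(), "rank"])
    centroids, _ = per_rank[selected]
    centroids = centroids / centroids.sum(axis=1, keepdims=True)
    signatures = pd.DataFrame(
        centroids.T, index=matrix.index,
        columns=[f"DN{k + 1}" for k in range(selected)],
    )
    exposures = attribute_exposure_matrix(matrix, signatures)
    return ExtractionResult(
        signatures=signatures, exposures=exposures, selected_rank=selected,
        diagnostics=diagnostics,
        params={"rank_range": (lo, hi), "n_restarts": n_restarts, "seed": seed,
                "stability_threshold": stability_threshold, "max_iter": max_iter,
                "tol": tol, "objective": "kullback-leibler"},
    )


def attribute_exposures_nnls(sample_vector, signatures: pd.DataFrame):
    """Non-negative least-squares exposures of one sample vector.

    Returns (exposures Series, reconstruction cosine); exposures are
    rescaled so they sum to the vector's total count.
    """
    y = np.asarray(sample_vector, dtype=float)
    A = signatures.to_numpy(dtype=float)
    coef, _ = optimize.nnls(A, y)
    recon = A @ coef
    total = y.sum()
    if coef.sum() > 0 and total > 0:
        coef = coef * (total / (recon.sum() if recon.sum() > 0 else 1.0))
    cos = 0.0
    if np.linalg.norm(recon) > 0 and np.linalg.norm(y) > 0:
        cos = cosine_similarity(y, recon)
    return pd.Series(coef, index=signatures.columns), cos


def attribute_exposure_matrix(matrix: pd.DataFrame, signatures: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for sample in matrix.columns:
        rows[sample], _ = attribute_exposures_nnls(matrix[sample].to_numpy(), signatures)
    out = pd.DataFrame(rows).T
    out.index.name = "sample"
    return out


def match_to_reference(
    denovo: pd.DataFrame, reference: pd.DataFrame, min_cosine: float = 0.8
) -> pd.DataFrame:
    """Greedy one-to-one best-cosine assignment of de novo signatures to a
    reference catalog; channel labels must align exactly."""
    if list(denovo.index) != list(reference.index):
        raise ValueError(
            "channel labels of de novo and reference catalogs do not align; "
            "reorder the reference to the conventional channel order first"
        )
    sims = []
    for d in denovo.columns:
        for r in reference.columns:
            sims.append((cosine_similarity(denovo[d], reference[r]), d, r))
    sims.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_d, used_r, rows = set(), set(), []
    for s, d, r in sims:
        if d in used_d or r in used_r:
            continue
        used_d.add(d)
        if s >= min_cosine:
            used_r.add(r)
            rows.append({"denovo": d, "reference": r, "cosine": s, "assigned": True})
        else:
            rows.append({"denovo": d, "reference": None, "cosine": s,
                         "assigned": False})
    return pd.DataFrame(rows).sort_values("denovo").reset_index(drop=True)


def compare_signature_contributions(
    exposures: pd.DataFrame, groups: pd.Series, sum_signatures: dict | None = None
) -> pd.DataFrame:
    """Per-signature Mann-Whitney test of relative contributions between
    CYT-high and CYT-low, Bonferroni-adjusted (adjusted p = min(1, m p)).

    ``sum_signatures`` optionally maps a new name to a list of signature
    columns summed before testing (e.g. SBS7a/b jointly).
    """
    totals = exposures.sum(axis=1)
    rel = exposures.div(totals.where(totals > 0, 1.0), axis=0)
    if sum_signatures:
        for name, cols in sum_signatures.items():
            rel[name] = rel[list(cols)].sum(axis=1)
            rel = rel.drop(columns=list(cols))
    g = groups.reindex(rel.index)
    rows = []
    m = rel.shape[1]
    for sig in rel.columns:
        a = rel.loc[g == "high", sig].to_numpy()
        b = rel.loc[g == "low", sig].to_numpy()
        stat, p = mann_whitney(a, b)
        rows.append({"signature": sig, "U": stat, "p": p,
                     "p_bonferroni": min(1.0, m * p), "n_high": a.size,
                     "n_low": b.size})
    return pd.DataFrame(rows)


def exposure_cooccurrence(
    exposures: pd.DataFrame, sig_a: str, sig_b: str, threshold: float = 0.05
) -> dict:
    """Presence/absence association of two signatures (2x2 Fisher exact).

    Presence = relative contribution > threshold.  A zero cell triggers the
    Haldane 0.5 correction for the odds ratio (flagged degenerate).
    """
    totals = exposures.sum(axis=1)
    rel = exposures.div(totals.where(totals > 0, 1.0), axis=0)
    pa = rel[sig_a] > threshold
    pb = rel[sig_b] > threshold
    a = int((pa & pb).sum())
    b = int((pa & ~pb).sum())
    c = int((~pa & pb).sum())
    d = int((~pa & ~pb).sum())
    table = np.array([[a, b], [c, d]], dtype=float)
    _, p = sps.fisher_exact(table, alternative="two-sided")
    degenerate = (table == 0).any()
    if degenerate:
        table = table + 0.5
    odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    return {"odds_ratio": odds, "p": float(p), "table": [[a, b], [c, d]],
            "degenerate": bool(degenerate), "threshold": threshold}
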