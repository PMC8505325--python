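"""Cosine similarity, NMF extraction, reference matching, NNLS attribution
and exposure association tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cyt.channels import SBS96_LABELS
from cyt.signatures import (
    attribute_exposures_nnls,
    compare_signature_contributions,
    cosine_similarity,
    exposure_cooccurrence,
    extract_signatures_nmf,
    match_to_reference,
)


class TestCosine:
    def test_identical_is_one(self):
        v = np.arange(1.0, 97.0)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        u = np.zeros(96); u[:48] = 1.0
        v = np.zeros(96); v[48:] = 1.0
        assert cosine_similarity(u, v) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_similarity(np.zeros(3), np.ones(3))

    @given(st.lists(st.floats(0.0, 10.0), min_size=4, max_size=4),
           st.floats(0.1, 50.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetric_and_scale_invariant(self, u, c):
        u = np.asarray(u) + 0.01
        v = u[::-1].copy()
        assert cosine_similarity(u, v) == pytest.approx(cosine_similarity(v, u))
        assert cosine_similarity(c * u, v) == pytest.approx(
            cosine_similarity(u, v), rel=1e-9
        )


class TestExtraction:
    def test_rank_one_analytic_fixed_point(self):
        """Rank-1 KL-NMF: signature is the normalized row-sum profile and
        exposures are the column sums."""
        rng = np.random.default_rng(0)
        profile = rng.dirichlet(np.ones(96))
        totals = np.array([200.0, 350.0, 500.0, 120.0])
        X = pd.DataFrame(
            rng.poisson(np.outer(profile, totals)),
            index=SBS96_LABELS, columns=[f"S{i}" for i in range(4)],
        )
        res = extract_signatures_nmf(X, rank_range=(1, 1), n_restarts=4, seed=0)
        assert res.selected_rank == 1
        rowsum = X.sum(axis=1) / X.to_numpy().sum()
        assert cosine_similarity(res.signatures.iloc[:, 0], rowsum) > 0.9999
        assert np.allclose(res.exposures.iloc[:, 0], X.sum(axis=0), rtol=0.02)

    def test_rank_exceeding_dims_rejected(self):
        X = pd.DataFrame(np.ones((96, 3)), index=SBS96_LABELS)
        with pytest.raises(ValueError, match="rank"):
            extract_signatures_nmf(X, rank_range=(2, 5))

    def test_duplicating_samples_preserves_result(self, catalog):
        """Column duplication leaves the selected rank and the signatures
        (up to permutation) unchanged."""
        rng = np.random.default_rng(3)
        sigs = catalog[["UV-like", "deamination"]].to_numpy()
        mix = rng.dirichlet([1.0, 1.0], size=12)
        X = pd.DataFrame(
            rng.poisson(sigs @ (mix.T * 400)),
            index=SBS96_LABELS, columns=[f"S{i}" for i in range(12)],
        )
        X2 = pd.concat([X, X.add_suffix("_dup")], axis=1)
        a = extract_signatures_nmf(X, rank_range=(1, 3), n_restarts=6, seed=1)
        b = extract_signatures_nmf(X2, rank_range=(1, 3), n_restarts=6, seed=1)
        assert a.selected_rank == b.selected_rank
        for col in a.signatures.columns:
            best = max(
                cosine_similarity(a.signatures[col], b.signatures[c])
                for c in b.signatures.columns
            )
            assert best > 0.98


class TestAttribution:
    def test_pure_signature_recovered(self, catalog):
        sigs = catalog[["UV-like", "flat-clock", "deamination"]]
        vec = sigs["UV-like"].to_numpy() * 100.0
        expo, cos = attribute_exposures_nnls(vec, sigs)
        assert expo["UV-like"] == pytest.approx(100.0, rel=1e-6)
        assert expo.drop("UV-like").abs().max() < 1e-6
        assert cos == pytest.approx(1.0)

    def test_orthogonal_vector_zero_exposure(self):
        sigs = pd.DataFrame({"A": [1.0, 0.0, 0.0]}, index=["c1", "c2", "c3"])
        expo, cos = attribute_exposures_nnls(np.array([0.0, 1.0, 1.0]), sigs)
        assert expo["A"] == 0.0
        assert cos == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_mixture_recovered_within_5pct(self, catalog, seed):
        rng = np.random.default_rng(seed)
        sigs = catalog[["UV-like", "flat-clock", "deamination"]]
        weights = rng.dirichlet([2.0, 2.0, 2.0]) * 10_000
        vec = rng.poisson(sigs.to_numpy() @ weights)
        expo, _ = attribute_exposures_nnls(vec, sigs)
        l1 = np.abs(expo.to_numpy() - weights).sum() / weights.sum()
        assert l1 < 0.05


class TestMatching:
    def test_identity_mapping(self, catalog):
        m = match_to_reference(catalog, catalog)
        assert (m["assigned"]).all()
        assert (m["denovo"] == m["reference"]).all()
        assert np.allclose(m["cosine"], 1.0)

    def test_misaligned_channels_fail_loudly(self, catalog):
        shuffled = catalog.iloc[::-1]
        with pytest.raises(ValueError, match="do not align"):
            match_to_reference(catalog, shuffled)

    def test_below_threshold_unassigned(self, catalog):
        denovo = catalog[["UV-like"]].rename(columns={"UV-like": "DN1"})
        ref = catalog[["deamination"]]
        m = match_to_reference(denovo, ref, min_cosine=0.8)
        assert not m["assigned"].iloc[0]


class TestGroupTests:
    def _exposures(self, shift=0.0, seed=0, n=30):
        rng = np.random.default_rng(seed)
        idx = [f"S{i}" for i in range(2 * n)]
        expo = pd.DataFrame({
            "sigA": rng.gamma(5.0, 20.0, 2 * n),
            "sigB": rng.gamma(5.0, 20.0, 2 * n),
        }, index=idx)
        expo.loc[idx[:n], "sigA"] *= np.exp(shift)
        groups = pd.Series(["high"] * n + ["low"] * n, index=idx)
        return expo, groups

    def test_identical_groups_adjusted_p_one(self):
        rng = np.random.default_rng(1)
        half = pd.DataFrame({"sigA": rng.gamma(5, 20, 20),
                             "sigB": rng.gamma(5, 20, 20)},
                            index=[f"S{i}" for i in range(20)])
        expo = pd.concat([half, half.set_index(half.index + "_b")])
        groups = pd.Series(["high"] * 20 + ["low"] * 20, index=expo.index)
        res = compare_signature_contributions(expo, groups)
        assert (res["p_bonferroni"] > 0.99).all()

    def test_shifted_signature_flagged(self):
        """One strongly shifted minor signature is flagged; the small
        compensating dilution of the other five is not (relative
        contributions must sum to 1, so the others cannot be perfectly
        untouched — the design keeps their change well below detection)."""
        rng = np.random.default_rng(2)
        n = 12
        idx = [f"S{i}" for i in range(2 * n)]
        expo = pd.DataFrame(
            {f"sig{j}": rng.gamma(5.0, 20.0 if j else 4.0, 2 * n)
             for j in range(6)},
            index=idx,
        )
        expo.loc[idx[:n], "sig0"] *= 4.0
        groups = pd.Series(["high"] * n + ["low"] * n, index=idx)
        res = compare_signature_contributions(expo, groups).set_index("signature")
        assert res.loc["sig0", "p_bonferroni"] < 0.05
        assert (res.drop("sig0")["p_bonferroni"] > 0.05).all()

    def test_bonferroni_never_below_raw(self):
        expo, groups = self._exposures(seed=3)
        res = compare_signature_contributions(expo, groups)
        assert (res["p_bonferroni"] >= res["p"] - 1e-12).all()

    def test_summed_signatures_mode(self):
        expo, groups = self._exposures(seed=4)
        res = compare_signature_contributions(
            expo, groups, sum_signatures={"sigAB": ["sigA", "sigB"]}
        )
        assert list(res["signature"]) == ["sigAB"]


class TestCooccurrence:
    def test_perfect_exclusivity(self):
        idx = [f"S{i}" for i in range(20)]
        expo = pd.DataFrame({
            "A": [100.0] * 10 + [0.0] * 10,
            "B": [0.0] * 10 + [100.0] * 10,
        }, index=idx)
        res = exposure_cooccurrence(expo, "A", "B")
        assert res["odds_ratio"] < 1.0
        # hypergeometric enumeration oracle for the 2x2 table [[0,10],[10,0]]:
        # margins (10,10)/(10,10), two-sided p = sum of pmf(k) over tables
        # no more likely than the observed one
        from scipy.stats import hypergeom
        pmf = [hypergeom.pmf(k, 20, 10, 10) for k in range(11)]
        oracle_p = sum(p for p in pmf if p <= pmf[0] * (1 + 1e-9))
        assert res["p"] == pytest.approx(oracle_p)

    def test_all_positive_degenerate_flagged(self):
        idx = [f"S{i}" for i in range(10)]
        expo = pd.DataFrame({"A": 50.0, "B": 60.0}, index=idx)
        res = exposure_cooccurrence(expo, "A", "B")
        assert res["degenerate"]
        assert np.isfinite(res["odds_ratio"])

    def test_independent_presence_null_calibration(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            idx = [f"S{i}" for i in range(40)]
            expo = pd.DataFrame({
                "A": np.where(rng.random(40) < 0.5, 100.0, 0.0),
                "B": np.where(rng.random(40) < 0.5, 100.0, 0.0),
            }, index=idx)
            pvals.append(exposure_cooccurrence(expo, "A", "B")["p"])
        # Fisher p-values are conservative; demand no excess of small ones
        assert np.mean(np.array(pvals) < 0.05) <= 0.07
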