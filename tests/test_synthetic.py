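"""Generator contracts: copula correlation, mutation placement, planted
events, survival draws and byte-level determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cyt.catalogs import fixture_catalog
from cyt.synthetic import (
    ChromothripsisSpec,
    CohortConfig,
    KataegisSpec,
    default_exposures,
    generate_cohort,
    generate_expression,
    generate_mutations,
    generate_segments,
    generate_survival,
    sample_annotations,
)


class TestExpression:
    def test_perfect_dependence_gives_identical_ranks(self):
        cfg = CohortConfig(n_samples=50, cyt_rho=1.0, seed=3)
        expr = generate_expression(cfg)
        ranks_gz = stats.rankdata(expr.loc["GZMA"])
        ranks_pr = stats.rankdata(expr.loc["PRF1"])
        assert (ranks_gz == ranks_pr).all()
        rho = stats.spearmanr(expr.loc["GZMA"], expr.loc["PRF1"]).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_target_rho_recovered(self):
        cfg = CohortConfig(n_samples=200, cyt_rho=0.9, seed=1)
        expr = generate_expression(cfg)
        rho = stats.spearmanr(expr.loc["GZMA"], expr.loc["PRF1"]).statistic
        assert 0.85 <= rho <= 0.95

    def test_rho_across_seeds(self):
        rhos = []
        for seed in range(15):
            cfg = CohortConfig(n_samples=200, cyt_rho=0.9, seed=seed)
            expr = generate_expression(cfg)
            rhos.append(
                stats.spearmanr(expr.loc["GZMA"], expr.loc["PRF1"]).statistic
            )
        assert abs(np.mean(rhos) - 0.9) < 0.03
        assert all(0.8 <= r <= 0.97 for r in rhos)

    def test_minimum_cohort_size(self):
        expr = generate_expression(CohortConfig(n_samples=4, seed=0))
        assert expr.shape[1] == 4
        with pytest.raises(ValueError):
            generate_expression(CohortConfig(n_samples=3, seed=0))

    def test_panel_genes_present(self):
        expr = generate_expression(CohortConfig(n_samples=6, seed=0))
        for gene in ("GZMA", "PRF1", "IFNG", "HLA-DRA", "FOXP3", "TAP1"):
            assert gene in expr.index
        assert (expr.to_numpy() >= 0).all()


class TestMutations:
    def test_pure_signature_concentration(self, catalog):
        """Pure-signature samples reproduce the planted channel profile.

        The multinomial concentration oracle gives expected L1 error
        sum_c sqrt(2 p_c (1 - p_c) / (pi n)) per signature: ~0.02-0.04 for
        the peaked vectors and ~0.078 for the near-flat clock-like vector
        at n = 10,000.  Each sample is checked against 1.5x its own
        analytic expectation (0.05 for the peaked ones)."""
        cfg = CohortConfig(n_samples=4, seed=5)
        expo = pd.DataFrame(
            {"UV-like": [10_000, 0, 0, 0],
             "flat-clock": [0, 10_000, 0, 0],
             "deamination": [0, 0, 10_000, 10_000]},
            index=cfg.sample_names,
        )
        muts = generate_mutations(cfg, catalog, expo)
        from cyt.spectra import build_sbs96_matrix

        mat = build_sbs96_matrix(muts)
        for sample, sig in zip(cfg.sample_names[:3],
                               ["UV-like", "flat-clock", "deamination"]):
            n = mat[sample].sum()
            freq = mat[sample] / n
            l1 = float(np.abs(freq - catalog[sig]).sum())
            p = catalog[sig].to_numpy()
            expected_l1 = float(np.sqrt(2.0 * p * (1 - p) / (np.pi * n)).sum())
            assert l1 < max(0.05, 1.5 * expected_l1)

    def test_kataegis_planted_exactly(self, catalog):
        cfg = CohortConfig(
            n_samples=4, seed=2,
            kataegis_spec=[KataegisSpec("S0001", "chr1", 1_000_000, 8, 500)],
        )
        muts = generate_mutations(cfg, catalog)
        cluster = muts[
            (muts["Tumor_Sample_Barcode"] == "S0001")
            & (muts["Chromosome"] == "chr1")
            & (muts["Start_Position"] >= 1_000_000)
            & (muts["Start_Position"] < 1_000_000 + 8 * 500)
        ]
        assert list(cluster["Start_Position"]) == [
            1_000_000 + i * 500 for i in range(8)
        ]
        assert (cluster["Reference_Allele"] == "C").all()
        assert (cluster["Tumor_Seq_Allele2"] == "T").all()

    def test_background_isolation(self, catalog):
        cfg = CohortConfig(n_samples=6, seed=4)
        muts = generate_mutations(cfg, catalog)
        for (_s, _c), grp in muts.groupby(
            ["Tumor_Sample_Barcode", "Chromosome"]
        ):
            gaps = np.diff(np.sort(grp["Start_Position"]))
            assert (gaps > 10_000).all()

    def test_zero_exposure_row_rejected(self, catalog):
        cfg = CohortConfig(n_samples=4, seed=0)
        expo = default_exposures(cfg)
        expo.iloc[0] = 0
        with pytest.raises(ValueError, match="sums to 0"):
            generate_mutations(cfg, catalog, expo)

    def test_kataegis_spec_validation(self):
        with pytest.raises(ValueError, match="n_mutations >= 6"):
            CohortConfig(kataegis_spec=[KataegisSpec("S0001", "chr1", 1, 5, 100)])


class TestSegments:
    def test_planted_oscillations(self):
        cfg = CohortConfig(
            n_samples=4, seed=8,
            chromothripsis_spec=[ChromothripsisSpec("S0002", "chr9", 25, 0.5)],
        )
        seg = generate_segments(cfg)
        prof = seg[(seg["ID"] == "S0002") & (seg["chrom"] == "chr9")]
        prof = prof.sort_values("loc.start")
        deltas = np.abs(np.diff(prof["seg.mean"].to_numpy()))
        assert (deltas >= 0.5 - 1e-9).sum() >= 25
        lengths = prof["loc.end"] - prof["loc.start"] + 1
        block = prof[np.abs(prof["seg.mean"]) == 0.5]
        assert len(block) == 26
        assert (lengths[block.index] >= 10_000).all()

    def test_background_is_quiet(self):
        seg = generate_segments(CohortConfig(n_samples=6, seed=9))
        assert (seg["seg.mean"].abs() < 0.3).all()
        per_chrom = seg.groupby(["ID", "chrom"]).size()
        assert per_chrom.max() <= 4  # <= 3 change points

    def test_amplitude_floor_enforced(self):
        with pytest.raises(ValueError, match="amplitude"):
            CohortConfig(
                chromothripsis_spec=[ChromothripsisSpec("S0001", "chr1", 20, 0.2)]
            )


class TestSurvival:
    def test_reproducible_and_valid(self):
        cfg = CohortConfig(n_samples=40, seed=6)
        groups = pd.Series(
            ["high", "low"] * 20, index=cfg.sample_names, name="group"
        )
        a = generate_survival(cfg, groups)
        b = generate_survival(cfg, groups)
        pd.testing.assert_frame_equal(a, b)
        assert (a["time_days"] >= 0).all()
        assert set(a["event"].unique()) <= {0, 1}

    def test_hazard_ratio_power(self):
        """Hazard ratio ~3 is detected by the log-rank test in most seeds."""
        from cyt.survival import logrank_test

        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = CohortConfig(
                n_samples=200, seed=seed,
                survival_hazards={"high": 1 / 3000.0, "low": 1 / 1000.0},
                censoring_hazard=1 / 4000.0,
            )
            groups = pd.Series(["high", "low"] * 100, index=cfg.sample_names)
            surv = generate_survival(cfg, groups)
            _, p = logrank_test(surv, "group", "high", "low")
            hits += p < 0.05
        assert hits >= 0.8 * n_seeds

    def test_all_censored_breaks_logrank(self):
        from cyt.survival import logrank_test

        cfg = CohortConfig(n_samples=10, seed=0, censoring_hazard=1e9)
        groups = pd.Series(["high", "low"] * 5, index=cfg.sample_names)
        surv = generate_survival(cfg, groups)
        assert surv["event"].sum() == 0
        with pytest.raises(ValueError, match="no events"):
            logrank_test(surv, "group", "high", "low")

    def test_unknown_group_rejected(self):
        cfg = CohortConfig(n_samples=4, seed=0)
        groups = pd.Series(["weird"] * 4, index=cfg.sample_names)
        with pytest.raises(ValueError, match="weird"):
            generate_survival(cfg, groups)


def test_fixed_seed_byte_identical(catalog):
    cfg = CohortConfig(n_samples=10, seed=42)
    a = generate_cohort(cfg, catalog)
    b = generate_cohort(CohortConfig(n_samples=10, seed=42), catalog)
    for key in ("expression", "mutations", "segments", "clinical"):
        assert a[key].to_csv() == b[key].to_csv()


def test_tumor_type_admixture():
    annot = sample_annotations(CohortConfig(n_samples=100, frac_metastatic=0.78,
                                            seed=1))
    assert (annot["tumor_type"] == "metastatic").sum() == 78
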