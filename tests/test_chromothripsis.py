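"""Profile simplification, switch counting, the Poisson LR statistic and
end-to-end chromothripsis-like calling."""

import numpy as np
import pandas as pd
import pytest

from cyt.catalogs import fixture_catalog
from cyt.chromothripsis import (
    ChromothripsisParams,
    call_chromothripsis,
    chromothripsis_group_summary,
    chromothripsis_lr,
    count_cn_switches,
    merge_segments,
)
from cyt.synthetic import ChromothripsisSpec, CohortConfig, generate_segments


def seg_table(rows, sample="S1", chrom="chr1"):
    return pd.DataFrame(
        [(sample, chrom, s, e, 10, m) for s, e, m in rows],
        columns=["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"],
    )


class TestMerge:
    def test_small_difference_merged(self):
        seg = seg_table([(1, 100_000, 0.1), (100_001, 300_000, 0.3)])
        merged = merge_segments(seg)
        assert len(merged) == 1
        # length-weighted mean: (0.1 * 1e5 + 0.3 * 2e5) / 3e5
        assert merged["seg.mean"].iloc[0] == pytest.approx(0.23333, abs=1e-4)

    def test_short_segment_dropped(self):
        seg = seg_table([(1, 5_000, 2.0), (5_001, 100_000, 0.0)])
        merged = merge_segments(seg)
        assert len(merged) == 1
        assert merged["seg.mean"].iloc[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        bounds = np.sort(rng.choice(np.arange(1, 2_000), 30, replace=False))
        rows = []
        start = 1
        for b in bounds:
            rows.append((start * 10_000, b * 10_000 + 9_999,
                         float(rng.normal(0, 0.4))))
            start = b + 1
        seg = seg_table(rows)
        once = merge_segments(seg)
        twice = merge_segments(once.assign(**{"num.mark": 10}))
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_all_boundaries_exceed_signal_distance(self):
        rng = np.random.default_rng(7)
        rows = [(i * 50_000 + 1, (i + 1) * 50_000, float(rng.normal(0, 0.5)))
                for i in range(40)]
        merged = merge_segments(seg_table(rows))
        deltas = np.abs(np.diff(merged["seg.mean"].to_numpy()))
        assert (deltas >= 0.3).all()


class TestSwitchCount:
    def test_flat_profile_zero(self):
        merged = merge_segments(seg_table([(1, 1_000_000, 0.0)]))
        n, _ = count_cn_switches(merged, "S1", "chr1")
        assert n == 0

    def test_alternating_21_segments_20_switches(self):
        rows = [(i * 50_000 + 1, (i + 1) * 50_000, 0.5 * (-1) ** i)
                for i in range(21)]
        merged = merge_segments(seg_table(rows))
        n, bps = count_cn_switches(merged, "S1", "chr1")
        assert n == 20
        assert len(bps) == 20

    @pytest.mark.parametrize("seed", range(5))
    def test_random_profile_matches_brute_recount(self, seed):
        rng = np.random.default_rng(seed)
        rows = [(i * 50_000 + 1, (i + 1) * 50_000, float(rng.normal(0, 0.4)))
                for i in range(50)]
        merged = merge_segments(seg_table(rows))
        n, _ = count_cn_switches(merged, "S1", "chr1")
        # independent recount on the merged profile
        means = merged.sort_values("loc.start")["seg.mean"].to_numpy()
        brute = sum(1 for a, b in zip(means, means[1:]) if abs(b - a) >= 0.3)
        assert n == brute == len(means) - 1


class TestLikelihoodRatio:
    def test_background_rate_gives_zero(self):
        # k/W exactly equals K/G
        assert chromothripsis_lr(5, 50e6, 300, 3e9) == pytest.approx(0.0)

    def test_arithmetic_oracle(self):
        # [25 ln((25/50e6)/(30/3e9)) - 50e6 (25/50e6 - 30/3e9)] / ln 10
        assert chromothripsis_lr(25, 50e6, 30, 3e9) == pytest.approx(
            31.834035301770797, rel=1e-12
        )

    def test_monotone_in_local_count(self):
        vals = [chromothripsis_lr(k, 50e6, 30, 3e9) for k in range(1, 40)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_zero_background_sentinel(self):
        assert chromothripsis_lr(5, 1e6, 0, 3e9) == float("inf")
        assert chromothripsis_lr(0, 1e6, 0, 3e9) == 0.0


class TestCalls:
    def test_planted_oscillating_chromosome_called(self):
        cfg = CohortConfig(
            n_samples=6, seed=21,
            chromothripsis_spec=[ChromothripsisSpec("S0003", "chr2", 25, 0.5)],
        )
        seg = generate_segments(cfg)
        calls = call_chromothripsis(seg, cfg.chrom_sizes)
        assert len(calls) == 1
        call = calls.iloc[0]
        assert call["sample"] == "S0003" and call["chrom"] == "chr2"
        assert call["n_switches"] >= 20
        assert call["log10_lr"] >= 8.0
        assert len(call["gains"]) > 0 and len(call["losses"]) > 0

    def test_two_planted_chromosomes_two_calls(self):
        cfg = CohortConfig(
            n_samples=6, seed=22,
            chromothripsis_spec=[
                ChromothripsisSpec("S0001", "chr1", 25, 0.5),
                ChromothripsisSpec("S0001", "chr5", 30, 0.6),
            ],
        )
        calls = call_chromothripsis(generate_segments(cfg), cfg.chrom_sizes)
        assert len(calls) == 2
        assert set(calls["chrom"]) == {"chr1", "chr5"}

    def test_background_only_no_calls(self):
        cfg = CohortConfig(n_samples=10, seed=23)
        calls = call_chromothripsis(generate_segments(cfg), cfg.chrom_sizes)
        assert len(calls) == 0

    def test_record_order_invariance(self):
        cfg = CohortConfig(
            n_samples=4, seed=24,
            chromothripsis_spec=[ChromothripsisSpec("S0002", "chr3", 25, 0.5)],
        )
        seg = generate_segments(cfg)
        shuffled = seg.sample(frac=1.0, random_state=0)
        a = call_chromothripsis(seg, cfg.chrom_sizes)
        b = call_chromothripsis(shuffled, cfg.chrom_sizes)
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )

    def test_gene_annotation(self):
        cfg = CohortConfig(
            n_samples=4, seed=25,
            chromothripsis_spec=[ChromothripsisSpec("S0001", "chr1", 25, 0.5)],
        )
        genes = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [5_100_000, 5_300_000, 1],
            "end": [5_150_000, 5_350_000, 100],
            "gene_name": ["ONC1", "TSG1", "ELSEWHERE"],
            "role": ["", "", ""],
        })
        calls = call_chromothripsis(generate_segments(cfg), cfg.chrom_sizes,
                                    gene_table=genes)
        call = calls.iloc[0]
        named = set(call["genes_gained"]) | set(call["genes_lost"])
        assert "ELSEWHERE" not in named
        assert {"ONC1", "TSG1"} <= named


def test_group_summary_arithmetic():
    calls = pd.DataFrame({
        "sample": ["A", "B"], "chrom": ["chr1", "chr2"],
        "start": [1, 1], "end": [2, 2],
        "n_switches": [20, 30], "log10_lr": [10.0, 12.0],
        "gains": [[], []], "losses": [[], []],
        "genes_gained": [["X"], []], "genes_lost": [[], ["Y", "Z"]],
    })
    groups = pd.Series({"A": "low", "B": "low"})
    out = chromothripsis_group_summary(calls, groups)
    row = out.iloc[0]
    assert row["n_calls"] == 2
    assert row["mean_switches"] == pytest.approx(25.0)
    assert row["sd_switches"] == pytest.approx(7.0710678, abs=1e-6)
    assert row["n_gene_gains"] == 1 and row["n_gene_losses"] == 2
    assert chromothripsis_group_summary(calls.iloc[:0]).empty
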