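"""Somatic copy-number aberration (SCNA) thresholding, per-sample burden
and a simplified ("gistic-like") recurrence G-score with a circular-
permutation FDR.

Thresholds follow the study convention for segment log-ratios: seg_mean
>= 0.6 is an amplification and <= -0.4 a deletion.  The recurrence score
for a genomic bin sums |seg_mean| x overlap fraction over all samples'
aberrant segments of one sign; its null distribution comes from within-
sample circular shifts of segment placements along the concatenated
genome, which preserve each sample's segment-length and amplitude
multiset.  This is a deliberately simplified stand-in for GISTIC2's
peak model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import adjust_pvalues, compare_groups

AMP_CUT = 0.6
DEL_CUT = -0.4


def threshold_scna(
    segments: pd.DataFrame, amp_cut: float = AMP_CUT, del_cut: float = DEL_CUT
) -> pd.DataFrame:
    """Label each segment amplification / deletion / neutral by seg.mean."""
    if amp_cut <= 0 or del_cut >= 0:
        raise ValueError("amp_cut must be positive and del_cut negative")
    out = segments.copy()
    mean = out["seg.mean"].to_numpy(dtype=float)
    label = np.where(mean >= amp_cut, "amplification",
                     np.where(mean <= del_cut, "deletion", "neutral"))
    out["scna"] = label
    return out


def scna_burden(
    labeled: pd.DataFrame, groups: pd.Series | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-sample amplification/deletion segment counts, with an optional
    Mann-Whitney comparison of total burden between CYT groups."""
    counts = (
        labeled.pivot_table(index="ID", columns="scna", aggfunc="size", fill_value=0)
        .reindex(columns=["amplification", "deletion", "neutral"], fill_value=0)
    )
    samples = labeled["ID"].unique()
    counts = counts.reindex(samples, fill_value=0)
    counts.index.name = "sample"
    burden = pd.DataFrame({
        "n_amplifications": counts["amplification"],
        "n_deletions": counts["deletion"],
        "n_scna": counts["amplification"] + counts["deletion"],
    })
    summary: dict = {
        "total_amplifications": int(burden["n_amplifications"].sum()),
        "total_deletions": int(burden["n_deletions"].sum()),
    }
    if groups is not None:
        g = groups.reindex(burden.index)
        summary["per_group_totals"] = (
            burden["n_scna"].groupby(g).sum().to_dict()
        )
        mask = g.isin(["high", "low"])
        if mask.any():
            res = compare_groups(
                burden.loc[mask, "n_scna"].to_numpy(), g[mask].to_numpy()
            )
            summary["comparison"] = {
                "U": res.statistic, "p": res.p_value,
                "n_high": res.n_a, "n_low": res.n_b,
            }
    return burden, summary


def _genome_offsets(chrom_sizes: dict[str, int]) -> tuple[dict[str, int], int]:
    offsets, total = {}, 0
    for chrom, size in chrom_sizes.items():
        offsets[chrom] = total
        total += size
    return offsets, total


def _bin_scores(starts, ends, weights, n_bins, bin_size) -> np.ndarray:
    """Sum weight x overlap-fraction into fixed-width bins (absolute coords)."""
    G = np.zeros(n_bins)
    for s, e, w in zip(starts, ends, weights):
        b0 = int(s // bin_size)
        b1 = int(e // bin_size)
        for b in range(b0, min(b1, n_bins - 1) + 1):
            lo = max(s, b * bin_size)
            hi = min(e, (b + 1) * bin_size - 1)
            G[b] += w * (hi - lo + 1) / bin_size
    return G


def recurrence_gscore(
    labeled: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_size: int = 1_000_000,
    n_permutations: int = 200,
    seed: int = 0,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-bin G-scores with empirical permutation q-values.

    Output is BED-like: chrom, start, end, G_amp, p_amp, q_amp, G_del,
    p_del, q_del, with ``significant_*`` flags at ``q_threshold``.
    Empirical p has floor 1/(n_permutations + 1).
    """
    offsets, genome_len = _genome_offsets(chrom_sizes)
    n_bins = int(np.ceil(genome_len / bin_size))
    rng = np.random.default_rng(seed)

    aberrant = labeled[labeled["scna"] != "neutral"].copy()
    aberrant["__abs_start"] = (
        aberrant["chrom"].map(offsets) + aberrant["loc.start"] - 1
    )
    aberrant["__abs_end"] = aberrant["chrom"].map(offsets) + aberrant["loc.end"] - 1

    obs = {}
    for sign, lab in (("amp", "amplification"), ("del", "deletion")):
        sub = aberrant[aberrant["scna"] == lab]
        obs[sign] = _bin_scores(
            sub["__abs_start"].to_numpy(), sub["__abs_end"].to_numpy(),
            np.abs(sub["seg.mean"].to_numpy(dtype=float)), n_bins, bin_size,
        )

    exceed = {"amp": np.zeros(n_bins), "del": np.zeros(n_bins)}
    samples = list(aberrant["ID"].unique())
    by_sample = {s: aberrant[aberrant["ID"] == s] for s in samples}
    for _ in range(n_permutations):
        perm = {"amp": np.zeros(n_bins), "del": np.zeros(n_bins)}
        for s in samples:
            sub = by_sample[s]
            shift = int(rng.integers(0, genome_len))
            starts = (sub["__abs_start"].to_numpy() + shift) % genome_len
            lengths = (sub["__abs_end"] - sub["__abs_start"]).to_numpy()
            weights = np.abs(sub["seg.mean"].to_numpy(dtype=float))
            labs = sub["scna"].to_numpy()
            for st, ln, w, lab in zip(starts, lengths, weights, labs):
                sign = "amp" if lab == "amplification" else "del"
                en = st + ln
                if en < genome_len:
                    perm[sign] += _bin_scores([st], [en], [w], n_bins, bin_size)
                else:  # wrap around the concatenated genome
                    perm[sign] += _bin_scores([st], [genome_len - 1], [w], n_bins,
                                              bin_size)
                    perm[sign] += _bin_scores([0], [en - genome_len], [w], n_bins,
                                              bin_size)
        for sign in ("amp", "del"):
            exceed[sign] += perm[sign] >= obs[sign] - 1e-12

    rows = []
    chroms = list(chrom_sizes)
    for b in range(n_bins):
        abs_start = b * bin_size
        chrom = None
        for c in chroms:
            if offsets[c] <= abs_start < offsets[c] + chrom_sizes[c]:
                chrom = c
                break
        start = abs_start - offsets[chrom] + 1
        end = min(start + bin_size - 1, chrom_sizes[chrom])
        rows.append({"chrom": chrom, "start": start, "end": end})
    out = pd.DataFrame(rows)
    for sign in ("amp", "del"):
        p = (1.0 + exceed[sign]) / (n_permutations + 1.0)
        out[f"G_{sign}"] = obs[sign]
        out[f"p_{sign}"] = p
        out[f"q_{sign}"] = adjust_pvalues(p, "bh")
        out[f"significant_{sign}"] = out[f"q_{sign}"] < q_threshold
    return out
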