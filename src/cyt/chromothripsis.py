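"""Chromothripsis-like region detection from segmented copy-number
profiles (CTLPScanner-style oscillation counting).

Per sample chromosome the segment profile is first simplified: segments
shorter than ``min_segment_size`` (default 10 kb) are dropped and adjacent
segments whose seg_mean difference is below ``signal_distance`` (default
0.3) are merged (length-weighted mean), so every remaining boundary is a
copy-number status change of at least the signal distance.  A sliding
window (default 50 Mb, step 10 Mb) then looks for windows with at least
``min_switches`` (default 20) such changes and a Poisson likelihood-ratio
statistic of locally elevated breakpoint rate of at least ``min_lr``
(default 8, log10 scale); qualifying windows are merged into maximal
regions.  Sub-regions with signal >= 0.15 / <= -0.15 are annotated as
gains / losses, and genes from a user-supplied BED-like table by interval
overlap.

The likelihood-ratio form (local rate k/W against the genome-wide
breakpoint rate K/G, log10 scale) is this package's concrete choice of
statistic for "clustered breakpoints"; it is closed-form and oracle-
checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_SWITCHES = 20
MIN_LOG10_LR = 8.0
MIN_SEGMENT_SIZE = 10_000
SIGNAL_DISTANCE = 0.3
GAIN_CUT = 0.15
LOSS_CUT = -0.15
WINDOW = 50_000_000
STEP = 10_000_000


@dataclass
class ChromothripsisParams:
    min_switches: int = MIN_SWITCHES
    min_lr: float = MIN_LOG10_LR
    min_segment_size: int = MIN_SEGMENT_SIZE
    signal_distance: float = SIGNAL_DISTANCE
    gain_cut: float = GAIN_CUT
    loss_cut: float = LOSS_CUT
    window: int = WINDOW
    step: int = STEP


def merge_segments(
    segments: pd.DataFrame,
    signal_distance: float = SIGNAL_DISTANCE,
    min_segment_size: int = MIN_SEGMENT_SIZE,
) -> pd.DataFrame:
    """Simplified profile per sample chromosome.

    Drops sub-minimum segments, then repeatedly merges adjacent segments
    with |delta seg_mean| < signal_distance using a length-weighted mean
    until no such pair remains (idempotent by construction).
    """
    out = []
    for (sample, chrom), grp in segments.groupby(["ID", "chrom"], sort=True):
        grp = grp.sort_values("loc.start", kind="mergesort")
        segs = [
            [int(s), int(e), float(m)]
            for s, e, m in zip(grp["loc.start"], grp["loc.end"], grp["seg.mean"])
            if (e - s + 1) >= min_segment_size
        ]
        changed = True
        while changed:
            changed = False
            merged = []
            for seg in segs:
                if merged and abs(merged[-1][2] - seg[2]) < signal_distance:
                    prev = merged[-1]
                    l1 = prev[1] - prev[0] + 1
                    l2 = seg[1] - seg[0] + 1
                    prev[2] = (prev[2] * l1 + seg[2] * l2) / (l1 + l2)
                    prev[1] = seg[1]
                    changed = True
                else:
                    merged.append(list(seg))
            segs = merged
        for s, e, m in segs:
            out.append({"ID": sample, "chrom": chrom, "loc.start": s, "loc.end": e,
                        "seg.mean": m})
    return pd.DataFrame(out, columns=["ID", "chrom", "loc.start", "loc.end",
                                      "seg.mean"])


def count_cn_switches(
    profile: pd.DataFrame, sample: str, chrom: str
) -> tuple[int, np.ndarray]:
    """Switch count and breakpoint positions of one merged sample-chromosome
    profile (every boundary in the merged profile is a status change)."""
    grp = profile[(profile["ID"] == sample) & (profile["chrom"] == chrom)]
    grp = grp.sort_values("loc.start", kind="mergesort")
    if len(grp) < 2:
        return 0, np.array([], dtype=int)
    breakpoints = grp["loc.start"].to_numpy()[1:]
    return len(breakpoints), breakpoints


def chromothripsis_lr(k: int, window: float, k_genome: int, genome_len: float) -> float:
    """Poisson log10 likelihood ratio of local breakpoint rate vs background.

    lambda1 = k/W locally, lambda0 = K/G genome-wide;
    log10 LR = [k ln(lambda1/lambda0) - W (lambda1 - lambda0)] / ln 10.
    Returns +inf (flag it) when the background rate is zero with local
    breakpoints present; 0 when the local rate equals the background.
    """
    if window <= 0 or genome_len <= 0:
        raise ValueError("window and genome length must be positive")
    lam1 = k / window
    lam0 = k_genome / genome_len
    if lam0 == 0:
        return float("inf") if k > 0 else 0.0
    if k == 0:
        return (window * lam0) / np.log(10.0)
    return float((k * np.log(lam1 / lam0) - window * (lam1 - lam0)) / np.log(10.0))


def call_chromothripsis(
    segments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    params: ChromothripsisParams | None = None,
    gene_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Chromothripsis-like region calls for a whole SEG table.

    One row per call: sample, chrom, region start/end, n_switches,
    log10_lr, gain/loss sub-regions (as lists of (start, end, seg_mean))
    and overlapping annotated genes.
    """
    if params is None:
        params = ChromothripsisParams()
    genome_len = float(sum(chrom_sizes.values()))
    merged = merge_segments(segments, params.signal_distance, params.min_segment_size)
    calls = []
    for sample, sgrp in merged.groupby("ID", sort=True):
        bp_by_chrom = {}
        for chrom in sgrp["chrom"].unique():
            _, bps = count_cn_switches(merged, sample, chrom)
            bp_by_chrom[chrom] = bps
        k_genome = int(sum(len(b) for b in bp_by_chrom.values()))
        for chrom, bps in bp_by_chrom.items():
            if len(bps) < params.min_switches:
                continue
            length = chrom_sizes.get(chrom)
            if length is None:
                raise KeyError(f"no size for chromosome {chrom!r}")
            qualifying = []
            start = 1
            while start <= max(1, length - params.step + 1):
                end = min(start + params.window - 1, length)
                k = int(((bps >= start) & (bps <= end)).sum())
                if k >= params.min_switches:
                    lr = chromothripsis_lr(k, end - start + 1, k_genome, genome_len)
                    if lr >= params.min_lr:
                        qualifying.append((start, end))
                if end == length:
                    break
                start += params.step
            if not qualifying:
                continue
            # merge overlapping qualifying windows into maximal regions
            regions = []
            cur = list(qualifying[0])
            for s, e in qualifying[1:]:
                if s <= cur[1] + 1:
                    cur[1] = max(cur[1], e)
                else:
                    regions.append(tuple(cur))
                    cur = [s, e]
            regions.append(tuple(cur))
            for s, e in regions:
                k = int(((bps >= s) & (bps <= e)).sum())
                lr = chromothripsis_lr(k, e - s + 1, k_genome, genome_len)
                if k < params.min_switches or lr < params.min_lr:
                    # fall back to the best single qualifying window inside
                    best = max(
                        (w for w in qualifying if w[0] >= s and w[1] <= e),
                        key=lambda w: chromothripsis_lr(
                            int(((bps >= w[0]) & (bps <= w[1])).sum()),
                            w[1] - w[0] + 1, k_genome, genome_len,
                        ),
                    )
                    s, e = best
                    k = int(((bps >= s) & (bps <= e)).sum())
                    lr = chromothripsis_lr(k, e - s + 1, k_genome, genome_len)
                prof = merged[
                    (merged["ID"] == sample) & (merged["chrom"] == chrom)
                    & (merged["loc.end"] >= s) & (merged["loc.start"] <= e)
                ]
                gains = [
                    (int(r["loc.start"]), int(r["loc.end"]), float(r["seg.mean"]))
                    for _, r in prof.iterrows() if r["seg.mean"] >= params.gain_cut
                ]
                losses = [
                    (int(r["loc.start"]), int(r["loc.end"]), float(r["seg.mean"]))
                    for _, r in prof.iterrows() if r["seg.mean"] <= params.loss_cut
                ]
                genes_gain, genes_loss = [], []
                if gene_table is not None:
                    gt = gene_table[gene_table["chrom"] == chrom]
                    for sub, names in ((gains, genes_gain), (losses, genes_loss)):
                        for gs, ge, _m in sub:
                            hit = gt[(gt["end"] >= gs) & (gt["start"] <= ge)]
                            names.extend(hit["gene_name"].tolist())
                calls.append({
                    "sample": sample, "chrom": chrom, "start": int(s), "end": int(e),
                    "n_switches": k, "log10_lr": lr,
                    "gains": gains, "losses": losses,
                    "genes_gained": sorted(set(genes_gain)),
                    "genes_lost": sorted(set(genes_loss)),
                })
    cols = ["sample", "chrom", "start", "end", "n_switches", "log10_lr",
            "gains", "losses", "genes_gained", "genes_lost"]
    return pd.DataFrame(calls, columns=cols)


def chromothripsis_group_summary(
    calls: pd.DataFrame, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Per-group call counts, affected chromosomes and mean +/- SD of switch
    counts (SD with n-1 denominator), plus gene gain/loss tallies."""
    if len(calls) == 0:
        return pd.DataFrame(columns=["group", "n_calls", "n_samples",
                                     "chromosomes", "mean_switches", "sd_switches",
                                     "n_gene_gains", "n_gene_losses"])
    g = calls["sample"].map(groups) if groups is not None else pd.Series(
        "all", index=calls.index
    )
    rows = []
    for label, sub in calls.groupby(g):
        switches = sub["n_switches"].to_numpy(dtype=float)
        rows.append({
            "group": label,
            "n_calls": int(len(sub)),
            "n_samples": int(sub["sample"].nunique()),
            "chromosomes": sorted(sub["chrom"].unique()),
            "mean_switches": float(switches.mean()),
            "sd_switches": float(switches.std(ddof=1)) if len(switches) > 1 else 0.0,
            "n_gene_gains": int(sub["genes_gained"].map(len).sum()),
            "n_gene_losses": int(sub["genes_lost"].map(len).sum()),
        })
    return pd.DataFrame(rows)
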