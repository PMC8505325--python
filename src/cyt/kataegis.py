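"""Kataegis (localized hypermutation) calling from inter-mutation distances.

A kataegis event is a run of at least ``min_mutations`` (default 6)
consecutive mutations on one sample chromosome whose mean successive
inter-mutation distance is at most ``max_mean_imd`` (default 1000 bp).
Events are maximal: scanning left to right, the caller takes the longest
qualifying window starting at the current mutation, emits it, and resumes
after it, so reported events never overlap and each satisfies both
thresholds exactly.  Chromosome boundaries always break runs; samples
never pool.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .channels import SBS6_CLASSES, sbs6_class

MIN_MUTATIONS = 6
MAX_MEAN_IMD = 1000.0


def intermutation_distances(
    muts: pd.DataFrame, sample: str, chrom: str
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted positions and successive distances for one sample chromosome."""
    sel = muts[
        (muts["Tumor_Sample_Barcode"] == sample) & (muts["Chromosome"] == chrom)
    ]
    pos = np.sort(sel["Start_Position"].to_numpy())
    return pos, np.diff(pos)


def _scan_positions(pos: np.ndarray, min_mutations: int, max_mean_imd: float):
    """Greedy maximal scan: yields (i, j) index windows, leftmost-longest."""
    n = len(pos)
    i = 0
    min_span = min_mutations - 1
    while i + min_span < n:
        best_j = -1
        for j in range(i + min_span, n):
            if (pos[j] - pos[i]) <= max_mean_imd * (j - i):
                best_j = j
        if best_j >= 0:
            yield i, best_j
            i = best_j + 1
        else:
            i += 1


def call_kataegis(
    muts: pd.DataFrame,
    min_mutations: int = MIN_MUTATIONS,
    max_mean_imd: float = MAX_MEAN_IMD,
) -> pd.DataFrame:
    """All kataegis events in a mutation table.

    Returns one row per event: sample, chrom, start, end, n_mutations,
    mean_imd and the 6-class substitution composition of the event.
    """
    events = []
    if len(muts) == 0:
        return _events_frame(events)
    for (sample, chrom), grp in muts.groupby(
        ["Tumor_Sample_Barcode", "Chromosome"], sort=True
    ):
        grp = grp.sort_values("Start_Position", kind="mergesort")
        pos = grp["Start_Position"].to_numpy()
        for i, j in _scan_positions(pos, min_mutations, max_mean_imd):
            rows = grp.iloc[i: j + 1]
            classes = [
                sbs6_class(r, a)
                for r, a in zip(rows["Reference_Allele"], rows["Tumor_Seq_Allele2"])
                if len(r) == 1 and len(a) == 1 and r != "-" and a != "-"
            ]
            comp = {c: classes.count(c) for c in SBS6_CLASSES}
            events.append({
                "sample": sample, "chrom": chrom,
                "start": int(pos[i]), "end": int(pos[j]),
                "n_mutations": int(j - i + 1),
                "mean_imd": float((pos[j] - pos[i]) / (j - i)),
                **comp,
            })
    return _events_frame(events)


def _events_frame(events) -> pd.DataFrame:
    cols = ["sample", "chrom", "start", "end", "n_mutations", "mean_imd",
            *SBS6_CLASSES]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(events, columns=cols)


def kataegis_summary(
    events: pd.DataFrame, groups: pd.Series | None = None
) -> dict:
    """Cohort tallies: events, involved tumors, involved mutations, C>T
    fraction of event mutations, and per-CYT-group event counts."""
    if len(events) == 0:
        out = {"n_events": 0, "n_tumors": 0, "n_mutations": 0, "c_to_t_fraction": 0.0}
        if groups is not None:
            out["per_group"] = {}
        return out
    n_mut = int(events["n_mutations"].sum())
    ct = int(events["C>T"].sum())
    out = {
        "n_events": int(len(events)),
        "n_tumors": int(events["sample"].nunique()),
        "n_mutations": n_mut,
        "c_to_t_fraction": ct / n_mut if n_mut else 0.0,
    }
    if groups is not None:
        g = events["sample"].map(groups)
        out["per_group"] = g.value_counts().to_dict()
    return out


def rainfall_table(muts: pd.DataFrame) -> pd.DataFrame:
    """Rainfall-plot data: per mutation, log10 distance to the previous
    mutation on the same sample chromosome, plus its substitution class."""
    rows = []
    for (sample, chrom), grp in muts.groupby(
        ["Tumor_Sample_Barcode", "Chromosome"], sort=True
    ):
        grp = grp.sort_values("Start_Position", kind="mergesort")
        pos = grp["Start_Position"].to_numpy()
        imd = np.concatenate([[np.nan], np.diff(pos).astype(float)])
        for k, (_, r) in enumerate(grp.iterrows()):
            ref, alt = r["Reference_Allele"], r["Tumor_Seq_Allele2"]
            cls = (
                sbs6_class(ref, alt)
                if len(ref) == 1 and len(alt) == 1 and ref != "-" and alt != "-"
                else "other"
            )
            rows.append({
                "sample": sample, "chrom": chrom, "pos": int(pos[k]),
                "log10_imd": float(np.log10(imd[k])) if imd[k] and imd[k] > 0
                else np.nan,
                "class": cls,
            })
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "log10_imd",
                                       "class"])
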