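"""SBS-96 / DBS-78 mutation-context matrices, 6-class substitution spectra
and a simplified recurrently-mutated-gene frequency test.

Doublet handling follows the SigProfiler convention: two same-sample SNVs
at adjacent positions form one doublet base substitution and are removed
from the SBS matrix; runs of three or more adjacent substitutions are
excluded from both matrices (and tallied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .channels import (
    AmbiguousBaseError,
    DBS78_LABELS,
    SBS6_CLASSES,
    SBS96_LABELS,
    classify_dbs,
    classify_sbs96,
    sbs6_class,
)
from .stats import adjust_pvalues, compare_groups_table


@dataclass
class MatrixBuildInfo:
    n_records: int = 0
    n_snv: int = 0
    n_dbs: int = 0
    n_excluded_ambiguous: int = 0
    n_excluded_multiplet: int = 0
    n_excluded_no_context: int = 0
    notes: list[str] = field(default_factory=list)


def _context_lookup(fasta_path: str):
    from pyfaidx import Fasta  # optional dependency, only for FASTA input

    fa = Fasta(fasta_path)

    def lookup(chrom: str, pos: int) -> str:
        # MAF coordinates are 1-based inclusive; pyfaidx slices are 0-based
        return str(fa[chrom][pos - 2: pos + 1]).upper()

    return lookup


def _iter_contexts(muts: pd.DataFrame, fasta: str | None):
    if "trinucleotide_context" in muts.columns and muts["trinucleotide_context"].notna().all():
        return muts["trinucleotide_context"].astype(str).tolist()
    if fasta is None:
        raise ValueError(
            "mutation table lacks a complete trinucleotide_context column and "
            "no reference FASTA was given"
        )
    look = _context_lookup(fasta)
    return [
        look(c, p)
        for c, p in zip(muts["Chromosome"], muts["Start_Position"])
    ]


def _snv_mask(muts: pd.DataFrame) -> pd.Series:
    return (
        muts["Reference_Allele"].str.len().eq(1)
        & muts["Tumor_Seq_Allele2"].str.len().eq(1)
        & muts["Reference_Allele"].ne("-")
        & muts["Tumor_Seq_Allele2"].ne("-")
    )


def build_matrices(
    muts: pd.DataFrame, fasta: str | None = None, samples=None
) -> tuple[pd.DataFrame, pd.DataFrame, MatrixBuildInfo]:
    """SBS-96 and DBS-78 count matrices (channels x samples).

    Adjacent same-sample substitution pairs are extracted as doublets first
    and not double-counted as two SNVs; longer adjacent runs are excluded
    from both matrices.
    """
    info = MatrixBuildInfo(n_records=len(muts))
    if samples is None:
        samples = sorted(muts["Tumor_Sample_Barcode"].unique()) if len(muts) else []
    sbs = pd.DataFrame(0, index=pd.Index(SBS96_LABELS, name="Type"), columns=samples,
                       dtype=int)
    dbs = pd.DataFrame(0, index=pd.Index(DBS78_LABELS, name="Type"), columns=samples,
                       dtype=int)
    if len(muts) == 0:
        return sbs, dbs, info

    snv = muts[_snv_mask(muts)].copy()
    snv["__context"] = _iter_contexts(snv, fasta)
    snv = snv.sort_values(["Tumor_Sample_Barcode", "Chromosome", "Start_Position"],
                          kind="mergesort")

    for (sample, _chrom), grp in snv.groupby(
        ["Tumor_Sample_Barcode", "Chromosome"], sort=False
    ):
        pos = grp["Start_Position"].to_numpy()
        # group consecutive positions into runs of adjacency (diff == 1)
        run_id = np.concatenate([[0], np.cumsum(np.diff(pos) != 1)])
        for rid in np.unique(run_id):
            rows = grp.iloc[run_id == rid]
            if len(rows) == 1:
                r = rows.iloc[0]
                ctx = r["__context"]
                try:
                    label = classify_sbs96(
                        r["Reference_Allele"], r["Tumor_Seq_Allele2"], ctx[0], ctx[2]
                    )
                except AmbiguousBaseError:
                    info.n_excluded_ambiguous += 1
                    continue
                sbs.loc[label, sample] += 1
                info.n_snv += 1
            elif len(rows) == 2:
                ref2 = "".join(rows["Reference_Allele"])
                alt2 = "".join(rows["Tumor_Seq_Allele2"])
                try:
                    dbs.loc[classify_dbs(ref2, alt2), sample] += 1
                    info.n_dbs += 1
                except (AmbiguousBaseError, ValueError):
                    info.n_excluded_ambiguous += 2
            else:
                info.n_excluded_multiplet += len(rows)
    return sbs, dbs, info


def build_sbs96_matrix(muts: pd.DataFrame, fasta: str | None = None) -> pd.DataFrame:
    return build_matrices(muts, fasta)[0]


def substitution_spectrum(
    muts: pd.DataFrame, groups: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample fractions over the 6 pyrimidine-strand substitution
    classes, optionally compared between CYT groups (Mann-Whitney, BH)."""
    snv = muts[_snv_mask(muts)]
    classes = [
        sbs6_class(r, a)
        for r, a in zip(snv["Reference_Allele"], snv["Tumor_Seq_Allele2"])
    ]
    tab = pd.crosstab(snv["Tumor_Sample_Barcode"], pd.Series(classes, index=snv.index))
    tab = tab.reindex(columns=list(SBS6_CLASSES), fill_value=0)
    frac = tab.div(tab.sum(axis=1), axis=0).fillna(0.0)
    frac.index.name = "sample"
    comparison = None
    if groups is not None:
        df = frac.copy()
        df["group"] = groups.reindex(frac.index)
        df = df.dropna(subset=["group"])
        comparison = compare_groups_table(df, list(SBS6_CLASSES), "group")
    return frac, comparison


def smg_frequency_test(
    muts: pd.DataFrame,
    gene_lengths: pd.Series,
    genome_mb: float,
    n_samples: int | None = None,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Simplified recurrently-mutated-gene test (frequency only).

    For each gene, the number of samples carrying >= 1 mutation is tested
    against a background probability 1 - exp(-r * L), where r is the cohort
    median per-Mb mutation rate and L the gene length in Mb, with a
    one-sided binomial test and BH adjustment.  This is explicitly NOT a
    covariate-aware driver test; output metadata marks it "simplified".
    """
    if "Hugo_Symbol" not in muts.columns:
        raise ValueError("smg_frequency_test requires a Hugo_Symbol column")
    if n_samples is None:
        n_samples = muts["Tumor_Sample_Barcode"].nunique()
    per_sample = muts.groupby("Tumor_Sample_Barcode").size()
    median_rate = float(per_sample.median()) / genome_mb if len(per_sample) else 0.0
    rows = []
    mutated = muts.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].nunique()
    for gene, length in gene_lengths.items():
        x = int(mutated.get(gene, 0))
        lam = median_rate * (float(length) / 1e6)
        p_bg = 1.0 - np.exp(-lam)
        if x == 0:
            p = 1.0
        else:
            p = float(sps.binomtest(x, n_samples, p_bg, alternative="greater").pvalue)
        rows.append({"gene": gene, "n_mutated_samples": x, "p_background": p_bg,
                     "p": p})
    out = pd.DataFrame(rows)
    out["q"] = adjust_pvalues(out["p"].to_numpy(), "bh")
    out["significant"] = out["q"] < q_threshold
    out.attrs["method"] = "simplified frequency test (not MutSigCV)"
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
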