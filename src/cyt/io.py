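"""Readers and writers for the pipeline's tabular formats.

All formats are plain TSV:

* expression   — genes x samples matrix, gene symbols as the row index;
* mutations    — MAF-like table (``Tumor_Sample_Barcode``, ``Chromosome``,
                 ``Start_Position``, ``Reference_Allele``,
                 ``Tumor_Seq_Allele2``, ``ref_count``, ``alt_count``,
                 ``trinucleotide_context``);
* segments     — SEG (``ID``, ``chrom``, ``loc.start``, ``loc.end``,
                 ``num.mark``, ``seg.mean``), 1-based inclusive;
* clinical     — ``sample``, ``tumor_type``, ``time_days``, ``event``;
* chrom sizes  — ``chrom`` <tab> ``length``.
"""

from __future__ import annotations

import pandas as pd

MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "ref_count",
    "alt_count",
    "trinucleotide_context",
]

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def read_expression(path: str) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index.name = "gene"
    if (expr < 0).any().any():
        raise ValueError(f"negative expression values in {path}")
    return expr


def write_expression(expr: pd.DataFrame, path: str) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_mutations(path: str) -> pd.DataFrame:
    muts = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    missing = [c for c in MAF_COLUMNS[:5] if c not in muts.columns]
    if missing:
        raise ValueError(f"mutation table {path} lacks required columns {missing}")
    muts["Start_Position"] = muts["Start_Position"].astype(int)
    return muts


def write_mutations(muts: pd.DataFrame, path: str) -> None:
    muts.to_csv(path, sep="\t", index=False)


def read_segments(path: str) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in seg.columns]
    if missing:
        raise ValueError(f"segment table {path} lacks required columns {missing}")
    seg["loc.start"] = seg["loc.start"].astype(int)
    seg["loc.end"] = seg["loc.end"].astype(int)
    if (seg["loc.start"] > seg["loc.end"]).any():
        raise ValueError(f"segment with start > end in {path}")
    return seg


def write_segments(seg: pd.DataFrame, path: str) -> None:
    seg.to_csv(path, sep="\t", index=False)


def read_clinical(path: str) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t")
    for col in ("sample", "time_days", "event"):
        if col not in clin.columns:
            raise ValueError(f"clinical table {path} lacks column {col!r}")
    if not set(clin["event"].unique()) <= {0, 1}:
        raise ValueError("event column must be 0 (censored) / 1 (death)")
    if (clin["time_days"] < 0).any():
        raise ValueError("negative survival times")
    return clin


def write_clinical(clin: pd.DataFrame, path: str) -> None:
    clin.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split()[:2]
            sizes[chrom] = int(length)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_gene_bed(path: str) -> pd.DataFrame:
    """BED-like gene table: chrom, start, end, gene_name[, role]."""
    names = ["chrom", "start", "end", "gene_name", "role"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, : min(5, df.shape[1])]
    df.columns = names[: df.shape[1]]
    if "role" not in df.columns:
        df["role"] = ""
    return df
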