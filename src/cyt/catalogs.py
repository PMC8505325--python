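"""Signature catalogs: the bundled fixture catalog and COSMIC-layout IO.

A signature catalog is a DataFrame with the 96 SBS channel labels (or the
78 DBS labels) as the row index and one probability column per signature.
Files follow the COSMIC layout: first column ``Type`` holding labels such
as ``A[C>A]A``, one column per signature.

The bundled fixture catalog holds four synthetic signature-like vectors so
the whole pipeline is testable without any download:

* ``UV-like``       — dominant C>T at dipyrimidines (5' C or T), the
                      hallmark of UV damage (CPD photoproducts);
* ``flat-clock``    — a broad, nearly flat background with a mild T>C
                      tilt, emulating a clock-like process;
* ``deamination``   — N[C>T]G dominant, emulating 5-methylcytosine
                      deamination at CpG;
* ``uniform``       — 1/96 everywhere, a null control.

These are NOT COSMIC signatures; real COSMIC v3.1 files are an optional
drop-in via :func:`load_catalog`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .channels import SBS96_LABELS, parse_sbs96_label

#: Default location probed for a user-supplied COSMIC v3.1 SBS file.
COSMIC_DROPIN_PATH = os.path.join("data", "COSMIC_v3.1_SBS_GRCh37.txt")


def fixture_catalog() -> pd.DataFrame:
    """Four synthetic signature-like probability vectors over SBS-96."""
    n = len(SBS96_LABELS)
    uv = np.full(n, 0.15 / n)
    deam = np.full(n, 0.10 / n)
    flat = np.zeros(n)
    for i, label in enumerate(SBS96_LABELS):
        ref, alt, five, three = parse_sbs96_label(label)
        sub = f"{ref}>{alt}"
        if sub == "C>T" and five in ("C", "T"):
            # dipyrimidine C>T; weight tilted toward TpC and away from 3' G
            w = 2.0 if five == "T" else 1.0
            w *= 0.5 if three == "G" else 1.0
            uv[i] += 0.85 * w
        if sub == "C>T" and three == "G":
            deam[i] += 0.90
        # broad flat background with a mild T>C tilt and smooth context wobble
        base = 1.0 + (0.8 if sub == "T>C" else 0.0)
        wobble = 0.15 * ((i * 7919) % 13) / 13.0
        flat[i] = base + wobble
    cat = pd.DataFrame(
        {
            "UV-like": uv / uv.sum(),
            "flat-clock": flat / flat.sum(),
            "deamination": deam / deam.sum(),
            "uniform": np.full(n, 1.0 / n),
        },
        index=pd.Index(SBS96_LABELS, name="Type"),
    )
    return cat


def load_catalog(path: str) -> pd.DataFrame:
    """Read a COSMIC-layout signature TSV (``Type`` column + one per signature).

    Rows are reordered to the conventional 96-channel order; a file whose
    label set does not cover the expected channels raises ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t")
    label_col = df.columns[0]
    df = df.set_index(label_col)
    df.index.name = "Type"
    missing = set(SBS96_LABELS) - set(df.index)
    if missing:
        raise ValueError(
            f"catalog {path} is missing {len(missing)} SBS-96 channel labels "
            f"(e.g. {sorted(missing)[:3]})"
        )
    df = df.loc[list(SBS96_LABELS)].astype(float)
    bad = df.columns[(df < 0).any(axis=0)]
    if len(bad):
        raise ValueError(f"negative entries in signature(s) {list(bad)}")
    return df


def write_catalog(catalog: pd.DataFrame, path: str) -> None:
    catalog.to_csv(path, sep="\t", index_label="Type")


def normalize_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """L1-normalize each signature column to sum exactly 1."""
    sums = catalog.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("signature column with non-positive mass")
    return catalog / sums
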