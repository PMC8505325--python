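"""Mutation-channel definitions: SBS-96 and DBS-78 classification.

The SBS-96 scheme describes every single-base substitution by its
pyrimidine-strand substitution class (C>A, C>G, C>T, T>A, T>C, T>G) and the
bases immediately 5' and 3' of the mutated base, giving 6 x 4 x 4 = 96
channels labelled like ``A[C>T]G``.  Purine-reference records are
reverse-complemented onto the pyrimidine strand, so a G>A in a C_T context
is the same channel as a C>T in an A_G context.

The DBS-78 scheme collapses the 144 possible doublet substitutions (16 ref
doublets x 9 both-base-changed alts) onto 78 strand-collapsed channels, the
convention used by the COSMIC doublet catalogs.
"""

from __future__ import annotations

import itertools

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Pyrimidine-strand substitution classes, in conventional display order.
SBS6_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical reference doublets of the DBS-78 scheme.
DBS_CANONICAL_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (upper case, ACGT only)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _sbs96_labels() -> tuple[str, ...]:
    labels = []
    for sub in SBS6_CLASSES:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


#: The 96 channel labels, ordered by (6 substitution classes x 5' base x 3' base).
SBS96_LABELS: tuple[str, ...] = _sbs96_labels()
SBS96_INDEX = {label: i for i, label in enumerate(SBS96_LABELS)}


class AmbiguousBaseError(ValueError):
    """Raised when a mutation record carries a non-ACGT base (e.g. N)."""


def _check_base(b: str) -> str:
    b = b.upper()
    if b not in COMPLEMENT:
        raise AmbiguousBaseError(f"ambiguous or invalid base {b!r}")
    return b


def classify_sbs96(ref: str, alt: str, fiveprime: str, threeprime: str) -> str:
    """Map one SNV with its flanking bases onto its SBS-96 channel label.

    Purine-reference mutations are reverse-complemented so the reported
    reference base is a pyrimidine; the flanking bases swap and complement
    accordingly.
    """
    ref, alt = _check_base(ref), _check_base(alt)
    five, three = _check_base(fiveprime), _check_base(threeprime)
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref})")
    if ref in ("G", "A"):  # collapse to pyrimidine strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five, three = COMPLEMENT[three], COMPLEMENT[five]
    return f"{five}[{ref}>{alt}]{three}"


def parse_sbs96_label(label: str) -> tuple[str, str, str, str]:
    """Inverse of the label format: return (ref, alt, fiveprime, threeprime)."""
    five, rest = label[0], label[2:-2]
    three = label[-1]
    ref, alt = rest.split(">")
    return ref, alt, five, three


def _dbs78_channels() -> tuple[str, ...]:
    channels = []
    for ref in DBS_CANONICAL_REFS:
        seen = set()
        for alt in itertools.product(BASES, repeat=2):
            alt = "".join(alt)
            if alt[0] == ref[0] or alt[1] == ref[1]:
                continue
            canon = classify_dbs(ref, alt)
            if canon not in seen:
                seen.add(canon)
                channels.append(canon)
    return tuple(channels)


def classify_dbs(ref2: str, alt2: str) -> str:
    """Map a doublet substitution onto its canonical DBS-78 channel.

    Both bases must change.  Doublets whose reference is not one of the ten
    canonical refs are reverse-complemented; palindromic refs (AT, TA, CG,
    GC) additionally take the lexicographically smaller of the two
    equivalent alts.
    """
    ref2 = "".join(_check_base(b) for b in ref2)
    alt2 = "".join(_check_base(b) for b in alt2)
    if len(ref2) != 2 or len(alt2) != 2:
        raise ValueError("doublet substitution requires 2-base ref and alt")
    if ref2[0] == alt2[0] or ref2[1] == alt2[1]:
        raise ValueError(f"not a doublet substitution: {ref2}>{alt2}")
    rc_ref, rc_alt = revcomp(ref2), revcomp(alt2)
    if ref2 not in DBS_CANONICAL_REFS:
        ref2, alt2 = rc_ref, rc_alt
    elif rc_ref == ref2:  # palindromic ref: collapse equivalent alts
        alt2 = min(alt2, rc_alt)
    return f"{ref2}>{alt2}"


#: The 78 canonical doublet channel labels, grouped by reference doublet.
DBS78_LABELS: tuple[str, ...] = _dbs78_channels()
DBS78_INDEX = {label: i for i, label in enumerate(DBS78_LABELS)}


def sbs6_class(label_or_ref: str, alt: str | None = None) -> str:
    """Pyrimidine-strand 6-class of an SBS-96 label or of a (ref, alt) pair."""
    if alt is None:
        ref, a, _, _ = parse_sbs96_label(label_or_ref)
        return f"{ref}>{a}"
    ref, alt = _check_base(label_or_ref), _check_base(alt)
    if ref in ("G", "A"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"
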