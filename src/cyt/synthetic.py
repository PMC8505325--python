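"""Synthetic melanoma-like cohorts with the statistical structure the
pipeline's downstream stages assume.

The generator emulates, at desk scale, the structure of a skin-melanoma
cohort: tightly co-expressed GZMA/PRF1 (target Spearman rho 0.9, the
coupling observed between the two cytolytic toxins), UV-dominated C>T
mutational spectra drawn from signature mixtures, injected kataegis
showers, injected oscillating (chromothripsis-like) chromosomes, Beta-
mixture variant allele fractions, and group-dependent exponential
survival.  It makes no attempt at realistic gene models, germline
variation or read-level noise.

Determinism: every generator draws from ``numpy.random.Generator`` (PCG64)
seeded from ``CohortConfig.seed`` through a fixed per-stage
``SeedSequence`` spawn key, so a fixed seed yields byte-identical output
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import SBS96_LABELS, parse_sbs96_label, revcomp
from .ips import default_weight_table

#: Synthetic genome: 10 chromosomes, 800 Mb total.
DEFAULT_CHROM_SIZES: dict[str, int] = {
    "chr1": 120_000_000,
    "chr2": 110_000_000,
    "chr3": 100_000_000,
    "chr4": 90_000_000,
    "chr5": 85_000_000,
    "chr6": 80_000_000,
    "chr7": 70_000_000,
    "chr8": 60_000_000,
    "chr9": 50_000_000,
    "chr10": 35_000_000,
}

IFNG_SIGNATURE = ["IFNG", "IDO1", "CXCL9", "CXCL10", "HLA-DRA", "STAT1"]
EXPANDED_IMMUNE_SIGNATURE = [
    "CD30", "IDO1", "CIITA", "CD3E", "CCL5", "GZMK", "CD2", "HLA-DRA",
    "CXCL13", "IL2RG", "NKG7", "HLA-E", "CXCR6", "LAG3", "TAGAP", "CXCL10",
    "STAT1", "GZMB",
]


@dataclass
class KataegisSpec:
    """One planted mutation shower: ``n_mutations`` C>T substitutions at
    ``start``, ``start + spacing``, ... on one sample chromosome."""

    sample: str
    chrom: str
    start: int
    n_mutations: int
    spacing: int


@dataclass
class ChromothripsisSpec:
    """One planted oscillating chromosome: ``n_oscillations`` copy-number
    status switches between seg_mean levels +amplitude and -amplitude."""

    sample: str
    chrom: str
    n_oscillations: int
    amplitude: float
    start: int = 5_000_000
    segment_length: int = 200_000


@dataclass
class CohortConfig:
    n_samples: int = 200
    frac_metastatic: float = 0.78
    cyt_rho: float = 0.9
    exposure_matrix: pd.DataFrame | None = None
    kataegis_spec: list[KataegisSpec] = field(default_factory=list)
    chromothripsis_spec: list[ChromothripsisSpec] = field(default_factory=list)
    survival_hazards: dict[str, float] = field(
        default_factory=lambda: {"high": 1 / 2400.0, "mid": 1 / 1600.0,
                                 "low": 1 / 1000.0}
    )
    censoring_hazard: float = 1 / 2000.0
    #: Beta mixture for VAFs: (mean, concentration, weight) per component.
    vaf_clones: tuple = ((0.40, 40.0, 1.0),)
    mean_depth: float = 80.0
    immune_coupling: float = 0.6
    n_filler_genes: int = 120
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_SIZES)
    )
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frac_metastatic <= 1.0:
            raise ValueError("frac_metastatic must be in [0, 1]")
        if not -1.0 <= self.cyt_rho <= 1.0:
            raise ValueError("cyt_rho must be in [-1, 1]")
        if self.exposure_matrix is not None and (self.exposure_matrix.values < 0).any():
            raise ValueError("exposures must be non-negative")
        for ks in self.kataegis_spec:
            if ks.n_mutations < 6:
                raise ValueError("kataegis spec requires n_mutations >= 6")
        for cs in self.chromothripsis_spec:
            if cs.amplitude < 0.3:
                raise ValueError("chromothripsis amplitude must be >= 0.3")

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_samples)]


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,))
    )


def sample_annotations(config: CohortConfig) -> pd.DataFrame:
    """Per-sample tumor-type labels (deterministic count, seeded placement)."""
    rng = _rng(config, 0)
    n_met = int(round(config.frac_metastatic * config.n_samples))
    types = np.array(["primary"] * config.n_samples, dtype=object)
    met_idx = rng.permutation(config.n_samples)[:n_met]
    types[met_idx] = "metastatic"
    return pd.DataFrame(
        {"sample": config.sample_names, "tumor_type": types}
    ).set_index("sample")


def gene_universe(config: CohortConfig) -> list[str]:
    panel = ["GZMA", "PRF1"] + IFNG_SIGNATURE + EXPANDED_IMMUNE_SIGNATURE
    panel += list(default_weight_table()["gene"])
    seen, genes = set(), []
    for g in panel:
        if g not in seen:
            seen.add(g)
            genes.append(g)
    genes += [f"GENE{i:04d}" for i in range(config.n_filler_genes)]
    return genes


def generate_expression(config: CohortConfig) -> pd.DataFrame:
    """Log-normal TPM matrix (genes x samples) with a Gaussian copula tying
    GZMA and PRF1 at the target Spearman correlation.

    The bivariate-normal Pearson correlation is set to
    ``2 sin(pi * rho_s / 6)`` so the implied Spearman correlation equals
    ``cyt_rho``.  Immune-panel genes are mildly coupled (slope
    ``immune_coupling``) to the latent cytolytic factor; filler genes are
    independent log-normal.
    """
    if config.n_samples < 4:
        raise ValueError("need n_samples >= 4")
    rng = _rng(config, 1)
    n = config.n_samples
    genes = gene_universe(config)
    for required in ("GZMA", "PRF1"):
        if required not in genes:
            raise ValueError(f"gene universe lacks required panel gene {required}")

    rho_pearson = 2.0 * np.sin(np.pi * config.cyt_rho / 6.0)
    if abs(rho_pearson) > 1.0 - 1e-12:  # snap fp noise at perfect dependence
        rho_pearson = np.sign(rho_pearson)
    z1 = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    # explicit Cholesky construction: exact at rho = +/-1 (z2 == +/-z1)
    z2 = rho_pearson * z1 + np.sqrt(max(0.0, 1.0 - rho_pearson**2)) * eps
    z = np.column_stack([z1, z2])
    latent = z.mean(axis=1)  # shared cytolytic factor

    expr = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=config.sample_names,
                        dtype=float)
    expr.loc["GZMA"] = np.exp(3.0 + 1.0 * z[:, 0])
    expr.loc["PRF1"] = np.exp(3.0 + 1.0 * z[:, 1])

    immune = [g for g in genes if g not in ("GZMA", "PRF1") and not g.startswith("GENE")]
    for g in immune:
        base = rng.normal(2.0, 0.3)
        noise = rng.normal(0.0, 0.8, size=n)
        expr.loc[g] = np.exp(base + config.immune_coupling * latent + noise)
    for g in genes:
        if g.startswith("GENE"):
            base = rng.normal(2.0, 1.0)
            expr.loc[g] = np.exp(base + rng.normal(0.0, 0.8, size=n))
    return expr


def default_exposures(config: CohortConfig, signature_names=None) -> pd.DataFrame:
    """Per-sample signature exposures (mutation counts): UV-dominated
    mixtures of 200-500 mutations.

    The Dirichlet concentration is deliberately low so mixture fractions
    vary strongly across samples (many tumors nearly pure UV, others
    dominated by the clock-like or deamination process), emulating the
    near-mutual-exclusivity of UV and clock-like processes seen in
    melanoma cohorts.
    """
    if signature_names is None:
        signature_names = ["UV-like", "flat-clock", "deamination"]
    rng = _rng(config, 2)
    totals = rng.integers(200, 501, size=config.n_samples)
    base = np.array([0.55, 0.25, 0.20])[: len(signature_names)]
    base = base / base.sum()
    fracs = rng.dirichlet(base * 2.0, size=config.n_samples)
    counts = np.round(fracs * totals[:, None]).astype(int)
    return pd.DataFrame(counts, index=config.sample_names, columns=signature_names)


def _draw_vafs(rng, n, clones) -> np.ndarray:
    means = np.array([c[0] for c in clones])
    concs = np.array([c[1] for c in clones])
    weights = np.array([c[2] for c in clones], dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(clones), size=n, p=weights)
    a = means[comp] * concs[comp]
    b = (1.0 - means[comp]) * concs[comp]
    return rng.beta(a, b)


def _isolated_positions(rng, n, chrom_len, min_gap=12_000) -> np.ndarray:
    """n positions on [1, chrom_len] pairwise > 10 kb apart (uses a jittered
    grid; requires n * min_gap << chrom_len, true at desk scale)."""
    if n == 0:
        return np.array([], dtype=int)
    spacing = chrom_len // (n + 1)
    if spacing <= 2 * min_gap:
        raise ValueError(f"cannot place {n} isolated mutations on {chrom_len} bp")
    base = spacing * (np.arange(n) + 1)
    jitter = rng.integers(-(spacing // 2 - min_gap), spacing // 2 - min_gap, size=n)
    return (base + jitter).astype(int)


def generate_mutations(
    config: CohortConfig,
    catalog: pd.DataFrame,
    exposures: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """MAF-like mutation table drawn from exposure-weighted channel mixtures.

    Each sample's channel counts are multinomial in its exposure-weighted
    mixture of catalog signatures.  Background mutations land > 10 kb
    apart; kataegis showers from ``config.kataegis_spec`` are placed
    exactly as specified (C>T at ``T[C>T]A`` contexts).  Roughly half of
    the records are written on the purine strand (reverse-complemented
    ref/alt/context) to exercise strand collapse downstream.
    """
    if exposures is None:
        exposures = config.exposure_matrix
    if exposures is None:
        exposures = default_exposures(config)
    missing = [s for s in exposures.columns if s not in catalog.columns]
    if missing:
        raise ValueError(f"exposure columns not in catalog: {missing}")
    rng = _rng(config, 3)
    chroms = list(config.chrom_sizes)
    chrom_lens = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    sigs = catalog[list(exposures.columns)].to_numpy()  # 96 x k

    records: list[dict] = []
    kat_by_sample: dict[str, list[KataegisSpec]] = {}
    for ks in config.kataegis_spec:
        kat_by_sample.setdefault(ks.sample, []).append(ks)

    for sample in exposures.index:
        expo = exposures.loc[sample].to_numpy(dtype=float)
        total = int(expo.sum())
        if total <= 0:
            raise ValueError(f"exposure row for {sample} sums to 0")
        mixture = sigs @ (expo / expo.sum())
        channel_counts = rng.multinomial(total, mixture / mixture.sum())
        channel_idx = np.repeat(np.arange(96), channel_counts)
        rng.shuffle(channel_idx)
        # split mutations across chromosomes, then place isolated positions
        chrom_assign = rng.choice(len(chroms), size=total, p=chrom_p)
        vafs = _draw_vafs(rng, total, config.vaf_clones)
        depth = rng.poisson(config.mean_depth, size=total) + 10
        alt_counts = rng.binomial(depth, vafs)
        flip = rng.random(total) < 0.5
        pos_in_order = np.empty(total, dtype=int)
        for ci in range(len(chroms)):
            mask = chrom_assign == ci
            pos_in_order[mask] = _isolated_positions(
                rng, int(mask.sum()), config.chrom_sizes[chroms[ci]]
            )
        for i in range(total):
            ref, alt, five, three = parse_sbs96_label(SBS96_LABELS[channel_idx[i]])
            context = five + ref + three
            if flip[i]:
                ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
            records.append({
                "Tumor_Sample_Barcode": sample,
                "Chromosome": chroms[chrom_assign[i]],
                "Start_Position": int(pos_in_order[i]),
                "Reference_Allele": ref,
                "Tumor_Seq_Allele2": alt,
                "ref_count": int(depth[i] - alt_counts[i]),
                "alt_count": int(alt_counts[i]),
                "trinucleotide_context": context,
            })
        for ks in kat_by_sample.get(sample, []):
            kvafs = _draw_vafs(rng, ks.n_mutations, config.vaf_clones)
            kdepth = rng.poisson(config.mean_depth, size=ks.n_mutations) + 10
            kalt = rng.binomial(kdepth, kvafs)
            for j in range(ks.n_mutations):
                records.append({
                    "Tumor_Sample_Barcode": sample,
                    "Chromosome": ks.chrom,
                    "Start_Position": int(ks.start + j * ks.spacing),
                    "Reference_Allele": "C",
                    "Tumor_Seq_Allele2": "T",
                    "ref_count": int(kdepth[j] - kalt[j]),
                    "alt_count": int(kalt[j]),
                    "trinucleotide_context": "TCA",
                })
    muts = pd.DataFrame.from_records(records)
    return muts.sort_values(
        ["Tumor_Sample_Barcode", "Chromosome", "Start_Position"], kind="mergesort"
    ).reset_index(drop=True)


def generate_doublets(
    config: CohortConfig,
    dbs_catalog: pd.DataFrame,
    dbs_exposures: pd.DataFrame,
) -> pd.DataFrame:
    """Doublet base substitutions as adjacent-position record pairs.

    ``dbs_exposures`` (samples x DBS signature names) gives event counts;
    an all-zero row emits nothing for that sample.  Each event becomes two
    MAF rows at positions p and p+1 whose refs/alts concatenate to the
    sampled DBS channel.
    """
    rng = _rng(config, 6)
    chroms = list(config.chrom_sizes)
    sigs = dbs_catalog[list(dbs_exposures.columns)].to_numpy()
    records = []
    for sample in dbs_exposures.index:
        expo = dbs_exposures.loc[sample].to_numpy(dtype=float)
        total = int(expo.sum())
        if total == 0:
            continue
        mixture = sigs @ (expo / expo.sum())
        counts = rng.multinomial(total, mixture / mixture.sum())
        idx = np.repeat(np.arange(len(dbs_catalog)), counts)
        chrom_assign = rng.choice(len(chroms), size=total)
        for i, ch_i in enumerate(idx):
            ref2, alt2 = dbs_catalog.index[ch_i].split(">")
            chrom = chroms[chrom_assign[i]]
            pos = int(rng.integers(1_000_000, config.chrom_sizes[chrom] - 1_000_000))
            vaf = _draw_vafs(rng, 1, config.vaf_clones)[0]
            depth = int(rng.poisson(config.mean_depth)) + 10
            alt_n = int(rng.binomial(depth, vaf))
            for off in (0, 1):
                records.append({
                    "Tumor_Sample_Barcode": sample, "Chromosome": chrom,
                    "Start_Position": pos + off,
                    "Reference_Allele": ref2[off],
                    "Tumor_Seq_Allele2": alt2[off],
                    "ref_count": depth - alt_n, "alt_count": alt_n,
                    "trinucleotide_context": "N" + ref2[off] + "N",
                })
    cols = ["Tumor_Sample_Barcode", "Chromosome", "Start_Position",
            "Reference_Allele", "Tumor_Seq_Allele2", "ref_count", "alt_count",
            "trinucleotide_context"]
    return pd.DataFrame(records, columns=cols)


def generate_segments(config: CohortConfig) -> pd.DataFrame:
    """SEG table: quiet background profiles (<= 3 change points per
    chromosome, |seg_mean| < 0.3) plus planted oscillating chromothriptic
    blocks from ``config.chromothripsis_spec``."""
    rng = _rng(config, 4)
    ct_by_key = {(cs.sample, cs.chrom): cs for cs in config.chromothripsis_spec}
    rows = []
    for sample in config.sample_names:
        for chrom, length in config.chrom_sizes.items():
            n_break = int(rng.integers(0, 4))
            breaks = np.sort(rng.integers(2_000_000, length - 2_000_000,
                                          size=n_break)) if n_break else np.array([], int)
            bounds = np.concatenate([[1], breaks, [length]])
            means = np.clip(rng.normal(0.0, 0.08, size=len(bounds) - 1), -0.25, 0.25)
            segs = [
                (int(bounds[i] if i == 0 else bounds[i] + 1), int(bounds[i + 1]),
                 float(means[i]))
                for i in range(len(bounds) - 1)
            ]
            cs = ct_by_key.get((sample, chrom))
            if cs is not None:
                block_start = cs.start
                block_end = cs.start + (cs.n_oscillations + 1) * cs.segment_length - 1
                if block_end >= length:
                    raise ValueError("chromothripsis block exceeds chromosome")
                kept = []
                for s, e, m in segs:
                    if e < block_start or s > block_end:
                        kept.append((s, e, m))
                    else:
                        if s < block_start:
                            kept.append((s, block_start - 1, m))
                        if e > block_end:
                            kept.append((block_end + 1, e, m))
                # levels alternate between +amplitude and -amplitude so both
                # the intra-block steps (2 x amplitude) and the block edges
                # (amplitude >= 0.3) survive signal-distance merging
                osc = []
                for k in range(cs.n_oscillations + 1):
                    s = block_start + k * cs.segment_length
                    e = s + cs.segment_length - 1
                    m = cs.amplitude * (1 if k % 2 == 0 else -1)
                    osc.append((s, e, m))
                segs = sorted(kept + osc)
            for s, e, m in segs:
                if e <= s:
                    continue
                rows.append({
                    "ID": sample, "chrom": chrom, "loc.start": s, "loc.end": e,
                    "num.mark": max(2, (e - s + 1) // 10_000),
                    "seg.mean": round(m, 4),
                })
    return pd.DataFrame(rows, columns=["ID", "chrom", "loc.start", "loc.end",
                                       "num.mark", "seg.mean"])


def generate_survival(config: CohortConfig, groups: pd.Series) -> pd.DataFrame:
    """Exponential event times with per-CYT-group hazards and independent
    exponential censoring.  ``groups``: sample -> label in survival_hazards."""
    rng = _rng(config, 5)
    unknown = set(groups.unique()) - set(config.survival_hazards)
    if unknown:
        raise ValueError(f"no hazard configured for group(s) {sorted(unknown)}")
    hazards = groups.map(config.survival_hazards).to_numpy(dtype=float)
    t_event = rng.exponential(1.0 / hazards)
    if config.censoring_hazard > 0:
        t_cens = rng.exponential(1.0 / config.censoring_hazard, size=len(groups))
    else:
        t_cens = np.full(len(groups), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({
        "sample": groups.index, "time_days": np.round(time, 2), "event": event,
        "group": groups.to_numpy(),
    })


def generate_cohort(config: CohortConfig, catalog: pd.DataFrame) -> dict:
    """All four tables at once (expression, mutations, segments, clinical),
    with quartile CYT groups computed on the generated expression."""
    from .stratify import compute_cyt, stratify_quartiles

    annot = sample_annotations(config)
    expr = generate_expression(config)
    cyt = compute_cyt(expr)
    strat = stratify_quartiles(cyt, annot["tumor_type"])
    muts = generate_mutations(config, catalog)
    segments = generate_segments(config)
    survival = generate_survival(config, strat["group"])
    clinical = annot.reset_index().merge(survival, on="sample")
    return {
        "expression": expr,
        "mutations": muts,
        "segments": segments,
        "clinical": clinical,
        "stratification": strat,
    }
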