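"""End-to-end orchestration: one YAML config drives every stage, with a
deterministic manifest (stage parameters + SHA-256 of inputs/outputs) and
a JSON-lines log.

Stage order: stratify -> spectra -> signatures -> kataegis -> scna ->
chromothripsis -> heterogeneity -> survival -> ips.  The IPS stage is
optional (a missing/unusable weight table downgrades it to a warning);
every other stage aborts the run on failure.  Identical config + seed
yields a byte-identical result bundle.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
import warnings

import pandas as pd
import yaml

from . import io as cio
from .catalogs import fixture_catalog, load_catalog
from .chromothripsis import ChromothripsisParams, call_chromothripsis, \
    chromothripsis_group_summary
from .heterogeneity import vaf_profiles
from .ips import compute_ips, compare_ips, read_weight_table
from .kataegis import call_kataegis, kataegis_summary, rainfall_table
from .scna import recurrence_gscore, scna_burden, threshold_scna
from .signatures import compare_signature_contributions, extract_signatures_nmf, \
    match_to_reference
from .spectra import build_matrices, substitution_spectrum
from .stratify import compute_cyt, coexpression_rho, stratify_quartiles
from .survival import km_estimate, logrank_test, synergy_analysis
from .synthetic import DEFAULT_CHROM_SIZES

STAGES = ("stratify", "spectra", "signatures", "kataegis", "scna",
          "chromothripsis", "heterogeneity", "survival", "ips")
OPTIONAL_STAGES = {"ips"}

DEFAULT_STAGE_PARAMS: dict[str, dict] = {
    "stratify": {"pseudocount": 0.01, "pooled": False},
    "spectra": {},
    "signatures": {"rank_range": [2, 4], "n_restarts": 8, "min_cosine": 0.8,
                   "stability_threshold": 0.8},
    "kataegis": {"min_mutations": 6, "max_mean_imd": 1000.0},
    "scna": {"amp_cut": 0.6, "del_cut": -0.4, "bin_size": 1_000_000,
             "n_permutations": 100, "q_threshold": 0.1},
    "chromothripsis": {"min_switches": 20, "min_lr": 8.0,
                       "min_segment_size": 10_000, "signal_distance": 0.3,
                       "gain_cut": 0.15, "loss_cut": -0.15,
                       "window": 50_000_000, "step": 10_000_000},
    "heterogeneity": {"max_clusters": 4},
    "survival": {"gene_a": "GZMA", "gene_b": "PRF1", "cutpoint": "median"},
    "ips": {"ddof": 1},
}

INPUT_KEYS = ("expression", "mutations", "segments", "clinical", "chrom_sizes",
              "catalog", "ips_weights", "gene_bed")


class ConfigError(ValueError):
    pass


def load_config(path: str) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw, base_dir=os.path.dirname(os.path.abspath(path)))


def validate_config(raw: dict, base_dir: str = ".") -> dict:
    """Validate, reject unknown keys, and fill defaults."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known_top = {"seed", "output_dir", "inputs", "stages"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = {
        "seed": int(raw.get("seed", 0)),
        "output_dir": raw.get("output_dir", "cyt_out"),
        "inputs": {},
        "stages": copy.deepcopy(DEFAULT_STAGE_PARAMS),
    }
    inputs = raw.get("inputs", {}) or {}
    unknown = set(inputs) - set(INPUT_KEYS)
    if unknown:
        raise ConfigError(f"unknown input key(s): {sorted(unknown)}")
    for k, v in inputs.items():
        if v is not None and not os.path.isabs(v):
            v = os.path.join(base_dir, v)
        cfg["inputs"][k] = v
    for req in ("expression", "mutations", "segments", "clinical"):
        if not cfg["inputs"].get(req):
            raise ConfigError(f"missing required input {req!r}")
    stages = raw.get("stages", {}) or {}
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    for stage, params in stages.items():
        params = params or {}
        unknown = set(params) - set(DEFAULT_STAGE_PARAMS[stage])
        if unknown:
            raise ConfigError(
                f"unknown parameter(s) for stage {stage!r}: {sorted(unknown)}"
            )
        cfg["stages"][stage].update(params)
    if not os.path.isabs(cfg["output_dir"]):
        cfg["output_dir"] = os.path.join(base_dir, cfg["output_dir"])
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    def __init__(self, outdir: str):
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self.manifest: list[dict] = []
        self.log_path = os.path.join(outdir, "log.jsonl")
        self._log_fh = open(self.log_path, "w")

    def log(self, **payload):
        self._log_fh.write(json.dumps(payload, sort_keys=True, default=str) + "\n")
        self._log_fh.flush()

    def record(self, stage: str, params: dict, outputs: list[str],
               inputs: list[str] = (), status: str = "ok"):
        self.manifest.append({
            "stage": stage,
            "status": status,
            "parameters": params,
            "inputs": {os.path.basename(p): _sha256(p) for p in inputs},
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
        })

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def finish(self, config: dict) -> str:
        manifest_path = self.path("manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump({"config": _jsonable(config), "stages": self.manifest}, fh,
                      indent=2, sort_keys=True)
            fh.write("\n")
        self._log_fh.close()
        return manifest_path


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


def run_pipeline(config: dict) -> str:
    """Run every stage; returns the manifest path."""
    run = _Run(config["output_dir"])
    run.log(event="start", config=_jsonable(config))
    inputs = config["inputs"]

    expr = cio.read_expression(inputs["expression"])
    muts = cio.read_mutations(inputs["mutations"])
    segments = cio.read_segments(inputs["segments"])
    clinical = cio.read_clinical(inputs["clinical"])
    chrom_sizes = (cio.read_chrom_sizes(inputs["chrom_sizes"])
                   if inputs.get("chrom_sizes") else dict(DEFAULT_CHROM_SIZES))
    catalog = (load_catalog(inputs["catalog"]) if inputs.get("catalog")
               else fixture_catalog())
    gene_bed = cio.read_gene_bed(inputs["gene_bed"]) if inputs.get("gene_bed") else None

    # --- stratify ---------------------------------------------------------
    p = config["stages"]["stratify"]
    cyt = compute_cyt(expr, pseudocount=p["pseudocount"])
    tumor_type = clinical.set_index("sample").get("tumor_type")
    strata = None if p["pooled"] or tumor_type is None else tumor_type.reindex(cyt.index)
    strat = stratify_quartiles(cyt, strata)
    rho, rho_p = coexpression_rho(expr, "GZMA", "PRF1")
    out = run.path("cyt_stratification.tsv")
    strat.to_csv(out, sep="\t")
    with open(run.path("cyt_coexpression.json"), "w") as fh:
        json.dump({"spearman_rho": rho, "p": rho_p}, fh, indent=2)
        fh.write("\n")
    run.record("stratify", p, [out, run.path("cyt_coexpression.json")],
               [inputs["expression"], inputs["clinical"]])
    run.log(event="stage", stage="stratify", spearman_rho=rho)
    groups = strat["group"]

    # --- spectra ----------------------------------------------------------
    p = config["stages"]["spectra"]
    sbs96, dbs78, info = build_matrices(muts)
    frac, comparison = substitution_spectrum(muts, groups)
    outs = [run.path("sbs96_matrix.tsv"), run.path("dbs78_matrix.tsv"),
            run.path("substitution_spectrum.tsv")]
    sbs96.to_csv(outs[0], sep="\t")
    dbs78.to_csv(outs[1], sep="\t")
    frac.to_csv(outs[2], sep="\t")
    if comparison is not None:
        outs.append(run.path("spectrum_group_tests.tsv"))
        comparison.to_csv(outs[-1], sep="\t", index=False)
    run.record("spectra", p, outs, [inputs["mutations"]])
    run.log(event="stage", stage="spectra", n_snv=info.n_snv, n_dbs=info.n_dbs)

    # --- signatures -------------------------------------------------------
    p = config["stages"]["signatures"]
    res = extract_signatures_nmf(
        sbs96, rank_range=tuple(p["rank_range"]), n_restarts=p["n_restarts"],
        seed=config["seed"], stability_threshold=p["stability_threshold"],
    )
    matching = match_to_reference(res.signatures, catalog, min_cosine=p["min_cosine"])
    contrib = compare_signature_contributions(res.exposures, groups)
    outs = [run.path("denovo_signatures.tsv"), run.path("signature_exposures.tsv"),
            run.path("signature_matching.tsv"), run.path("signature_rank_diag.tsv"),
            run.path("signature_group_tests.tsv")]
    res.signatures.to_csv(outs[0], sep="\t")
    res.exposures.to_csv(outs[1], sep="\t")
    matching.to_csv(outs[2], sep="\t", index=False)
    res.diagnostics.to_csv(outs[3], sep="\t", index=False)
    contrib.to_csv(outs[4], sep="\t", index=False)
    run.record("signatures", p, outs)
    run.log(event="stage", stage="signatures", selected_rank=res.selected_rank)

    # --- kataegis ---------------------------------------------------------
    p = config["stages"]["kataegis"]
    events = call_kataegis(muts, min_mutations=p["min_mutations"],
                           max_mean_imd=p["max_mean_imd"])
    summary = kataegis_summary(events, groups)
    outs = [run.path("kataegis_events.tsv"), run.path("kataegis_summary.json"),
            run.path("rainfall.tsv")]
    events.to_csv(outs[0], sep="\t", index=False)
    with open(outs[1], "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    rainfall_table(muts).to_csv(outs[2], sep="\t", index=False)
    run.record("kataegis", p, outs, [inputs["mutations"]])
    run.log(event="stage", stage="kataegis", n_events=summary["n_events"])

    # --- scna -------------------------------------------------------------
    p = config["stages"]["scna"]
    labeled = threshold_scna(segments, p["amp_cut"], p["del_cut"])
    burden, bsummary = scna_burden(labeled, groups)
    gscore = recurrence_gscore(labeled, chrom_sizes, bin_size=p["bin_size"],
                               n_permutations=p["n_permutations"],
                               seed=config["seed"], q_threshold=p["q_threshold"])
    outs = [run.path("scna_burden.tsv"), run.path("scna_summary.json"),
            run.path("scna_gscore.tsv")]
    burden.to_csv(outs[0], sep="\t")
    with open(outs[1], "w") as fh:
        json.dump(_jsonable(bsummary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    gscore.to_csv(outs[2], sep="\t", index=False)
    run.record("scna", p, outs, [inputs["segments"]])
    run.log(event="stage", stage="scna", **{k: v for k, v in bsummary.items()
                                            if isinstance(v, int)})

    # --- chromothripsis ---------------------------------------------------
    p = config["stages"]["chromothripsis"]
    params = ChromothripsisParams(
        min_switches=p["min_switches"], min_lr=p["min_lr"],
        min_segment_size=p["min_segment_size"],
        signal_distance=p["signal_distance"], gain_cut=p["gain_cut"],
        loss_cut=p["loss_cut"], window=p["window"], step=p["step"],
    )
    calls = call_chromothripsis(segments, chrom_sizes, params, gene_bed)
    csummary = chromothripsis_group_summary(calls, groups)
    outs = [run.path("chromothripsis_calls.tsv"),
            run.path("chromothripsis_summary.tsv")]
    calls.to_csv(outs[0], sep="\t", index=False)
    csummary.to_csv(outs[1], sep="\t", index=False)
    run.record("chromothripsis", p, outs, [inputs["segments"]])
    run.log(event="stage", stage="chromothripsis", n_calls=int(len(calls)))

    # --- heterogeneity ----------------------------------------------------
    p = config["stages"]["heterogeneity"]
    het = vaf_profiles(muts, max_clusters=p["max_clusters"], seed=config["seed"])
    out = run.path("heterogeneity.tsv")
    het.to_csv(out, sep="\t", index=False)
    run.record("heterogeneity", p, [out], [inputs["mutations"]])
    run.log(event="stage", stage="heterogeneity", n_samples=int(len(het)))

    # --- survival ---------------------------------------------------------
    p = config["stages"]["survival"]
    clin_g = clinical.merge(groups.rename("cyt_group"), left_on="sample",
                            right_index=True, how="left")
    km = km_estimate(clin_g, "cyt_group")
    extremes = clin_g[clin_g["cyt_group"].isin(["high", "low"])]
    stat, pval = logrank_test(extremes, "cyt_group", "high", "low")
    synergy = synergy_analysis(expr, clinical, p["gene_a"], p["gene_b"],
                               p["cutpoint"])
    outs = [run.path("km_curves.tsv"), run.path("survival_tests.json"),
            run.path("synergy.tsv")]
    km.to_csv(outs[0], sep="\t", index=False)
    with open(outs[1], "w") as fh:
        json.dump({"logrank_high_vs_low": {"chi2": stat, "p": pval}}, fh,
                  indent=2, sort_keys=True)
        fh.write("\n")
    synergy.to_csv(outs[2], sep="\t", index=False)
    run.record("survival", p, outs, [inputs["clinical"]])
    run.log(event="stage", stage="survival", logrank_p=pval)

    # --- ips (optional) ---------------------------------------------------
    p = config["stages"]["ips"]
    try:
        weights = (read_weight_table(inputs["ips_weights"])
                   if inputs.get("ips_weights") else None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ips_table = compute_ips(expr, weights, ddof=p["ddof"])
            comp = compare_ips(ips_table, groups)
        outs = [run.path("ips.tsv"), run.path("ips_group_test.json")]
        ips_table.to_csv(outs[0], sep="\t", index_label="sample")
        with open(outs[1], "w") as fh:
            json.dump({"U": comp.statistic, "p": comp.p_value,
                       "n_high": comp.n_a, "n_low": comp.n_b}, fh, indent=2,
                      sort_keys=True)
            fh.write("\n")
        run.record("ips", p, outs, [inputs["expression"]])
        run.log(event="stage", stage="ips", p=comp.p_value)
    except Exception as exc:  # optional stage: warn and continue
        warnings.warn(f"IPS stage skipped: {exc}", stacklevel=2)
        run.record("ips", p, [], status=f"skipped: {exc}")
        run.log(event="stage", stage="ips", status="skipped", error=str(exc))

    return run.finish(config)
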