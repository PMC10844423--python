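"""End-to-end pipeline: simulate/ingest -> QC -> kinship -> fits ->
cross-validation scenarios -> genetic gains, with a run manifest.

All randomness flows from one master seed recorded in the manifest; the
run digest is a SHA-256 over the configuration snapshot, the seed and the
digests of every output file (timings are recorded but excluded), so two
runs with the same configuration and seed produce identical digests.

The flat key=value configuration schema (YAML mapping, all keys optional):

========================  =====================================================
key                       meaning (default)
========================  =====================================================
n_founders                founders in the clone bank (49)
n_families                maternal families (44)
n_sites                   trial sites (6)
site_totals               list of per-site tree counts (study defaults)
n_blocks_per_site         blocks per site (5)
n_markers                 SNP markers before QC (17074)
n_qtl                     markers with effects (2000)
h2                        scalar heritability target overriding the matrix
type_b_corr               cross-site additive correlation target (0.3)
site_effect_sd            latent-scale SD of site means (0.8)
selfing_rate              probability a seed is selfed (0.05)
missing_rate              mean missing-call rate (0.03)
preset                    marker-QC preset loose|moderate|strict (loose)
subsample_n               random marker subset after QC (none)
impute                    mean|hw (mean)
traits                    traits to evaluate (["height"])
k_folds                   CV folds (10)
models                    predictors to evaluate (["gblup", "ablup"])
proportions               selection proportions for gains ([0.05,0.1,0.2,0.5])
seed                      master seed (2024)
========================  =====================================================
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as pio
from .datatypes import ValidationError
from .evaluation import Dataset, ScenarioSpec, run_scenario, standardize
from .gains import compare_methods
from .kinship import build_grm, build_nrm
from .markerqc import qc_pipeline
from .mixedmodel import ModelSpec, family_anova, fit_reml, heritability_individual
from .simdata import SimConfig, config_to_dict, simulate_dataset

_SIM_KEYS = {
    "n_founders", "n_families", "n_sites", "site_totals", "n_per_family_site",
    "n_blocks_per_site", "n_markers", "n_qtl", "maf_min", "maf_max", "h2",
    "type_b_corr", "site_effect_sd", "block_sd", "residual_sd",
    "selfing_rate", "missing_rate", "seed",
}


@dataclass
class RunManifest:
    """Provenance record: config, seeds, digests, timings, outputs."""

    config: dict
    seed: int
    version: str
    outputs: dict = field(default_factory=dict)   # name -> {path, sha256}
    timings: dict = field(default_factory=dict)   # stage -> seconds
    stages: list = field(default_factory=list)

    def run_digest(self) -> str:
        payload = json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "outputs": {k: v["sha256"] for k, v in sorted(self.outputs.items())},
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "outputs": self.outputs,
            "timings": self.timings,
            "stages": self.stages,
            "run_digest": self.run_digest(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("configuration must be a flat key=value mapping")
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    kw = {k: v for k, v in cfg.items() if k in _SIM_KEYS}
    if "site_totals" in kw:
        kw["site_totals"] = tuple(kw["site_totals"])
        kw.setdefault("n_sites", len(kw["site_totals"]))
    sim = SimConfig(**kw)
    sim.validate()
    return sim


def run_pipeline(cfg: dict, outdir, resume: bool = False) -> RunManifest:
    """Run every stage in order, writing outputs and the manifest to outdir.

    With ``resume=True`` a stage whose output files already exist is loaded
    from disk instead of recomputed, so deleting an intermediate file
    regenerates only it and everything downstream.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 2024))
    sim_cfg = _sim_config({**cfg, "seed": seed})
    manifest = RunManifest(
        config={**config_to_dict(sim_cfg), **{k: cfg[k] for k in cfg if k not in _SIM_KEYS}},
        seed=seed,
        version=__version__,
    )

    def record(name, path):
        manifest.outputs[name] = {"path": str(path), "sha256": pio.file_digest(path)}

    def stage(name):
        manifest.stages.append(name)
        return time.perf_counter()

    # -- simulate ----------------------------------------------------------
    t0 = stage("simulate")
    geno_path = outdir / "genotypes.csv"
    ped_path = outdir / "pedigree.csv"
    pheno_path = outdir / "phenotypes.csv"
    placement_path = outdir / "placement.csv"
    if resume and all(p.exists() for p in (geno_path, ped_path, pheno_path, placement_path)):
        genotypes = pio.read_genotypes_csv(geno_path)
        phenotypes = pio.read_phenotypes_csv(pheno_path)
        pedigree = pio.read_pedigree_csv(ped_path)
        placement = pio.read_table_csv(placement_path)
        pedigree.table = pedigree.table.merge(placement, on="id", how="left").fillna(
            {"site": "", "block": 0, "family": ""}
        )
        genotypes.sample_qc = pio.read_table_csv(outdir / "sample_qc.csv", index_col=0)
        genotypes.marker_qc = pio.read_table_csv(outdir / "marker_qc.csv", index_col=0)
        truth = None
    else:
        sim = simulate_dataset(sim_cfg)
        genotypes, pedigree, phenotypes, truth = (
            sim.genotypes, sim.pedigree, sim.phenotypes, sim.truth,
        )
        pio.write_genotypes_csv(genotypes, geno_path, stage="simulate")
        pio.write_pedigree_csv(pedigree, ped_path, stage="simulate")
        pio.write_phenotypes_csv(phenotypes, pheno_path, stage="simulate")
        placed = pedigree.table[pedigree.table["site"] != ""]
        pio.write_table_csv(
            placed[["id", "site", "block", "family"]], placement_path, stage="simulate"
        )
        pio.write_table_csv(
            genotypes.sample_qc.reset_index(names="id"), outdir / "sample_qc.csv",
            stage="simulate",
        )
        pio.write_table_csv(
            genotypes.marker_qc.reset_index(names="marker"), outdir / "marker_qc.csv",
            stage="simulate",
        )
        truth_path = outdir / "truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "realized_h2": truth.realized_h2.round(6).to_dict(),
                    "variance_components": truth.variance_components.round(6).to_dict(
                        orient="records"
                    ),
                    "n_qtl": int(len(truth.qtl_markers)),
                },
                indent=2,
                sort_keys=True,
            )
        )
        record("truth", truth_path)
    for name, p in [
        ("genotypes", geno_path), ("pedigree", ped_path), ("phenotypes", pheno_path),
        ("placement", placement_path), ("sample_qc", outdir / "sample_qc.csv"),
        ("marker_qc", outdir / "marker_qc.csv"),
    ]:
        record(name, p)
    manifest.timings["simulate"] = time.perf_counter() - t0

    # -- QC (samples first, then markers), subsample, impute ---------------
    t0 = stage("qc")
    filtered, qc_report = qc_pipeline(
        genotypes,
        marker_thresholds=cfg.get("preset", "loose"),
        subsample_n=cfg.get("subsample_n"),
        impute_mode=cfg.get("impute", "mean"),
        seed=seed,
    )
    qc_path = outdir / "qc_report.json"
    qc_path.write_text(json.dumps(qc_report, indent=2, sort_keys=True, default=str))
    record("qc_report", qc_path)
    manifest.timings["qc"] = time.perf_counter() - t0

    # drop excluded samples from the phenotype table too
    kept = set(filtered.ids)
    phenotypes = phenotypes[phenotypes["id"].isin(kept)].reset_index(drop=True)

    # -- kinship -----------------------------------------------------------
    t0 = stage("kinship")
    grm = build_grm(filtered)
    nrm = build_nrm(pedigree)
    pio.write_relationship_csv(grm, outdir / "grm.csv", stage="kinship")
    pio.write_relationship_csv(nrm, outdir / "nrm.csv", stage="kinship")
    record("grm", outdir / "grm.csv")
    record("nrm", outdir / "nrm.csv")
    manifest.timings["kinship"] = time.perf_counter() - t0

    data = Dataset(
        genotypes=filtered, pedigree=pedigree, phenotypes=phenotypes,
        grm=grm, nrm=nrm, truth=truth,
    )

    traits = list(cfg.get("traits", ["height"]))
    models = list(cfg.get("models", ["gblup", "ablup"]))
    k_folds = int(cfg.get("k_folds", 10))
    sites = sorted(phenotypes["site"].unique())
    multi = len(sites) > 1

    # -- combined-analysis fits (h2 and variance components per trait) -----
    t0 = stage("fit")
    fits = {}
    fit_json = {}
    for trait in traits:
        fits[trait] = {}
        for model, kernel in (("gblup", grm), ("ablup", nrm)):
            fit = fit_reml(
                phenotypes,
                ModelSpec(
                    response=trait,
                    fixed_effects=["site"] if multi else ["block"],
                    random_kernel=kernel,
                ),
            )
            h2, h2_se = heritability_individual(fit.varcomps)
            fits[trait][model] = fit
            fit_json[f"{trait}.{model}"] = {
                "sigma2_additive": fit.varcomps.sigma2_additive,
                "sigma2_residual": fit.varcomps.sigma2_residual,
                "h2": h2,
                "h2_se": h2_se,
                "converged": bool(fit.varcomps.converged),
                "n_iter": fit.varcomps.n_iter,
            }
        try:
            fam = family_anova(phenotypes, trait, design="combined" if multi else "single_site")
            fit_json[f"{trait}.family_anova"] = {
                "h2_family": fam.h2_family,
                "sigma_family_mean": fam.sigma_family_mean,
                "components": {k: float(v) for k, v in fam.components_truncated.items()},
            }
        except ValidationError as exc:
            fit_json[f"{trait}.family_anova"] = {"error": str(exc)}
    fits_path = outdir / "fits.json"
    fits_path.write_text(json.dumps(fit_json, indent=2, sort_keys=True))
    record("fits", fits_path)
    manifest.timings["fit"] = time.perf_counter() - t0

    # -- scenarios ---------------------------------------------------------
    t0 = stage("evaluate")
    eval_rows = []
    reports = {}
    for trait in traits:
        for model in models:
            scen_list = [ScenarioSpec("combined_region", trait, model, k_folds, None, seed)]
            for region in sites if multi else []:
                scen_list.append(
                    ScenarioSpec("within_region", trait, model, k_folds, region, seed)
                )
                scen_list.append(
                    ScenarioSpec("between_region", trait, model, k_folds, region, seed)
                )
            for spec in scen_list:
                rep = run_scenario(data, spec)
                reports[(trait, model, spec.scenario, spec.region)] = rep
                eval_rows.append(
                    {
                        "trait": trait, "model": model, "scenario": spec.scenario,
                        "region": spec.region or "all",
                        "accuracy": rep.accuracy, "accuracy_se": rep.accuracy_se,
                        "predictive_ability": rep.predictive_ability,
                        "predictive_ability_se": rep.predictive_ability_se,
                        "true_accuracy": rep.true_accuracy,
                    }
                )
    # genomic-vs-pedigree standardization on the combined scenario
    for trait in traits:
        key_g = (trait, "gblup", "combined_region", None)
        key_a = (trait, "ablup", "combined_region", None)
        if key_g in reports and key_a in reports:
            h2 = fit_json[f"{trait}.gblup"]["h2"]
            g_over_a, g_over_h = standardize(reports[key_g], reports[key_a], h2)
            eval_rows.append(
                {
                    "trait": trait, "model": "gblup", "scenario": "standardized",
                    "region": "all", "accuracy": np.nan, "accuracy_se": np.nan,
                    "predictive_ability": g_over_a, "predictive_ability_se": np.nan,
                    "true_accuracy": g_over_h,
                }
            )
    eval_df = pd.DataFrame(eval_rows)
    pio.write_table_csv(eval_df.round(8), outdir / "evaluation.csv", stage="evaluate")
    record("evaluation", outdir / "evaluation.csv")
    manifest.timings["evaluate"] = time.perf_counter() - t0

    # -- gains -------------------------------------------------------------
    t0 = stage("gains")
    proportions = list(cfg.get("proportions", [0.05, 0.1, 0.2, 0.5]))
    estimates = {}
    for trait in traits:
        gfit = fits[trait]["gblup"]
        s2a = gfit.varcomps.sigma2_additive
        s2p = gfit.varcomps.sigma2_phenotypic
        h2_grm = fit_json[f"{trait}.gblup"]["h2"]
        r = reports.get((trait, "gblup", "combined_region", None))
        acc = r.accuracy if r is not None else np.nan
        entry = {
            "GS": {"r": acc, "sigma_a": float(np.sqrt(max(s2a, 0.0)))},
            "PS": {"h2": h2_grm, "sigma_p": float(np.sqrt(max(s2p, 0.0)))},
        }
        fam = fit_json.get(f"{trait}.family_anova", {})
        if "h2_family" in fam and np.isfinite(fam["h2_family"]):
            entry["FS"] = {"h2": fam["h2_family"], "sigma_p": fam["sigma_family_mean"]}
        estimates[trait] = entry
    gains_df = compare_methods(estimates, proportions)
    pio.write_table_csv(gains_df.round(8), outdir / "gains.csv", stage="gains")
    record("gains", outdir / "gains.csv")
    manifest.timings["gains"] = time.perf_counter() - t0

    manifest.save(outdir / "manifest.json")
    return manifest
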