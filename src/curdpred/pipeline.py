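"""End-to-end workflow orchestration from a single configuration.

A run config (YAML or JSON) names either input files (genotypes +
phenotypes) or a simulation block, toggles the stages to run, and carries a
global seed. Stage order follows the study workflow: filter -> impute ->
structure/LD -> association -> prediction. Every enabled stage writes its
tables plus an entry in a JSON manifest (artifact path, stage, parameters,
sub-seed, sha256), and sub-seeds are derived from the global seed by a fixed
counter scheme so any stage can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import genotypes as geno
from . import gpred, gwas, ld, simulate, structure
from .pheno import PhenotypeTable, fit_two_way_random, heritability

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "impute", "pheno", "structure", "ld", "gwas", "predict")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: global seed stretched by the stage's
    position in the canonical order (counter scheme, stays below 2^31)."""
    return (int(global_seed) * 100_003 + STAGES.index(stage) * 7_919 + 1) % (2**31 - 1)


@dataclasses.dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    stages: list[str] = dataclasses.field(default_factory=lambda: list(STAGES))
    simulation: dict[str, Any] | None = None
    genotype_path: Path | None = None
    genotype_format: str = "vcf"
    phenotype_path: Path | None = None
    params: dict[str, dict[str, Any]] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - {
            "out_dir", "seed", "stages", "simulation",
            "genotypes", "phenotypes", "params",
        }
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = raw.get("stages", list(STAGES))
        bad = set(stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        genotypes = raw.get("genotypes") or {}
        cfg = cls(
            out_dir=Path(raw.get("out_dir", "curdpred_run")),
            seed=int(raw.get("seed", 0)),
            stages=[s for s in STAGES if s in stages],
            simulation=raw.get("simulation"),
            genotype_path=Path(genotypes["path"]) if genotypes else None,
            genotype_format=genotypes.get("format", "vcf"),
            phenotype_path=Path(raw["phenotypes"]) if raw.get("phenotypes") else None,
            params={k: dict(v) for k, v in (raw.get("params") or {}).items()},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulation is None:
            if "simulate" in self.stages:
                self.stages.remove("simulate")
            if self.genotype_path is None:
                raise ValueError("config needs a simulation block or a genotype path")
            if not self.genotype_path.exists():
                raise FileNotFoundError(self.genotype_path)
            if self.phenotype_path is not None and not self.phenotype_path.exists():
                raise FileNotFoundError(self.phenotype_path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, seed: int):
        self.out_dir = out_dir
        self.entries: list[dict[str, Any]] = []
        self.seed = seed

    def add(self, stage: str, path: Path, params: dict[str, Any]) -> None:
        self.entries.append(
            {
                "stage": stage,
                "path": str(path.relative_to(self.out_dir)),
                "params": params,
                "seed": stage_seed(self.seed, stage),
                "sha256": _sha256(path),
            }
        )

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps({"seed": self.seed, "artifacts": self.entries}, indent=2))
        return path


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the enabled stages in order; returns the manifest dictionary.

    A stage failure aborts the run with the stage named; artifacts written by
    earlier stages are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config.seed)
    state: dict[str, Any] = {}
    for stage in config.stages:
        t0 = time.perf_counter()
        logger.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](config, state, manifest, out)
        except Exception as exc:
            manifest.write()
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
    path = manifest.write()
    result = json.loads(path.read_text())
    return result


def _load_inputs(config: RunConfig, state: dict) -> None:
    if "G" not in state:
        if config.genotype_path is None:
            raise ValueError("no genotypes available; enable the simulate stage")
        state["G"] = geno.read_genotypes(config.genotype_path, config.genotype_format)
    if "phenotypes" not in state and config.phenotype_path is not None:
        state["phenotypes"] = PhenotypeTable.read(config.phenotype_path)


def _stage_simulate(config, state, manifest, out: Path) -> None:
    sim_params = dict(config.simulation or {})
    traits = sim_params.pop("traits", None)
    if traits is not None:
        sim_params["traits"] = tuple(simulate.TraitSpec(**t) for t in traits)
    sim_cfg = simulate.SimConfig(**sim_params)
    seed = stage_seed(config.seed, "simulate")
    G, truth = simulate.simulate_population(sim_cfg, seed=seed)
    phe = simulate.simulate_phenotypes(G, truth, sim_cfg, seed=seed + 1)
    lo, hi = sim_cfg.missing_range
    if hi > 0:
        G = simulate.inject_missingness(G, sim_cfg.missing_range, seed=seed + 2)
    geno.write_vcf(G, out / "genotypes.vcf")
    phe.write(out / "phenotypes.tsv")
    truth.to_json(out / "truth.json")
    state.update(G=G, phenotypes=phe, truth=truth, sim_cfg=sim_cfg)
    params = {k: str(v) for k, v in (config.simulation or {}).items()}
    for name in ("genotypes.vcf", "phenotypes.tsv", "truth.json"):
        manifest.add("simulate", out / name, params)


def _stage_filter(config, state, manifest, out: Path) -> None:
    _load_inputs(config, state)
    p = {"maf_min": 0.05, "require_complete": True, **config.params.get("filter", {})}
    G_strict, report = geno.filter_markers(state["G"], **p)
    state["G_strict"] = G_strict
    report.to_json(out / "filter_report.json")
    geno.write_dosage(G_strict, out / "genotypes_strict.tsv")
    manifest.add("filter", out / "filter_report.json", p)
    manifest.add("filter", out / "genotypes_strict.tsv", p)


def _stage_impute(config, state, manifest, out: Path) -> None:
    _load_inputs(config, state)
    p = {"method": "knn_window", **config.params.get("impute", {})}
    G_imp = geno.impute_missing(
        state["G"], seed=stage_seed(config.seed, "impute"), **p
    )
    G_imp, _ = geno.filter_markers(G_imp, maf_min=0.05)
    state["G_imputed"] = G_imp
    geno.write_dosage(G_imp, out / "genotypes_imputed.tsv")
    manifest.add("impute", out / "genotypes_imputed.tsv", p)


def _analysis_matrix(state) -> geno.GenotypeMatrix:
    for key in ("G_imputed", "G_strict", "G"):
        if key in state:
            G = state[key]
            if not np.isnan(G.dosages).any():
                return G
    raise ValueError("no complete genotype matrix; run filter or impute first")


def _stage_pheno(config, state, manifest, out: Path) -> None:
    _load_inputs(config, state)
    phe: PhenotypeTable = state.get("phenotypes")
    if phe is None:
        raise ValueError("pheno stage needs phenotype records")
    rows = []
    blup_cols = {}
    for trait in phe.traits:
        vc, blups = fit_two_way_random(phe, trait)
        rows.append(
            (trait, vc.sigma_g2, vc.sigma_ge2, vc.sigma_e2, vc.e, vc.r, heritability(vc))
        )
        blup_cols[trait] = blups.blups
        state.setdefault("h2", {})[trait] = heritability(vc)
    import pandas as pd

    vc_tbl = pd.DataFrame(
        rows, columns=["trait", "sigma_g2", "sigma_ge2", "sigma_e2", "e", "r", "H2"]
    )
    vc_tbl.to_csv(out / "variance_components.tsv", sep="\t", index=False)
    blup_tbl = pd.DataFrame(blup_cols)
    blup_tbl.to_csv(out / "blups.tsv", sep="\t", index_label="genotype")
    phe.adjusted_means().to_csv(out / "adjusted_means.tsv", sep="\t")
    state["blups"] = blup_tbl
    for name in ("variance_components.tsv", "blups.tsv", "adjusted_means.tsv"):
        manifest.add("pheno", out / name, {})


def _stage_structure(config, state, manifest, out: Path) -> None:
    _load_inputs(config, state)
    G = _analysis_matrix(state)
    p = {"k_range": range(1, 9), **config.params.get("structure", {})}
    if isinstance(p["k_range"], (list, tuple)):
        p["k_range"] = range(p["k_range"][0], p["k_range"][1] + 1)
    sol = structure.find_clusters(
        G, k_range=p["k_range"], seed=stage_seed(config.seed, "structure")
    )
    state["clusters"] = sol
    import pandas as pd

    pd.DataFrame({"id": G.ids, "cluster": sol.labels}).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    if sol.K > 1:
        load = structure.dapc_loadings(G, sol.labels)
        load.loadings.to_csv(out / "dapc_loadings.tsv", sep="\t", index_label="marker")
        manifest.add("structure", out / "dapc_loadings.tsv", {})
    manifest.add("structure", out / "clusters.tsv", {"k_max": max(p["k_range"])})


def _stage_ld(config, state, manifest, out: Path) -> None:
    _load_inputs(config, state)
    G = _analysis_matrix(state)
    p = config.params.get("ld", {})
    seed = stage_seed(config.seed, "ld")
    bg = ld.background_ld(G, n_pairs=p.get("n_pairs", 2000), seed=seed)
    summary: dict[str, Any] = {"background_r2": bg, "chromosomes": {}}
    for chrom in dict.fromkeys(G.markers["chrom"]):
        try:
            curve = ld.ld_decay(G, chrom, bg, seed=seed)
        except (ValueError, RuntimeError) as exc:
            summary["chromosomes"][chrom] = {"error": str(exc)}
            continue
        summary["chromosomes"][chrom] = {
            "rho": curve.rho,
            "intersection_bp": curve.intersection_bp,
            "n_pairs": curve.n_pairs,
        }
    (out / "ld_summary.json").write_text(json.dumps(summary, indent=2))
    state["background_ld"] = bg
    manifest.add("ld", out / "ld_summary.json", dict(p))


def _trait_vector(state, G: geno.GenotypeMatrix, trait: str) -> np.ndarray:
    phe: PhenotypeTable = state.get("phenotypes")
    means = phe.adjusted_means()[trait]
    return means.reindex(G.ids).to_numpy(dtype=float)


def _stage_gwas(config, state, manifest, out: Path) -> None:
    _load_inputs(config, state)
    G = _analysis_matrix(state)
    p = {"fdr_q": 0.2, **config.params.get("gwas", {})}
    K = gwas.kinship(G)
    phe: PhenotypeTable = state.get("phenotypes")
    if phe is None:
        raise ValueError("gwas stage needs phenotypes")
    for trait in phe.traits:
        y = _trait_vector(state, G, trait)
        assoc = gwas.emmax_scan(y, G, K, fdr_q=p["fdr_q"])
        assoc.write(out / f"gwas_{trait}.tsv")
        manifest.add(
            "gwas", out / f"gwas_{trait}.tsv",
            {"trait": trait, "fdr_q": p["fdr_q"], "lambda": assoc.lambda_gc},
        )
    state["kinship"] = K


def _stage_predict(config, state, manifest, out: Path) -> None:
    _load_inputs(config, state)
    G = _analysis_matrix(state)
    p = {"models": ["gblup"], "folds": 5, "reps": 10, "corrected_kinship": False}
    p.update(config.params.get("predict", {}))
    phe: PhenotypeTable = state.get("phenotypes")
    if phe is None:
        raise ValueError("predict stage needs phenotypes")
    K = state.get("kinship") or gwas.kinship(G)
    if p["corrected_kinship"]:
        K = structure.pc_adjusted_kinship(G)
    seed = stage_seed(config.seed, "predict")
    rows = []
    for trait in phe.traits:
        y = _trait_vector(state, G, trait)
        for model in p["models"]:
            rep = gpred.cross_validate(
                model, y,
                X=G.dosages if model != "gblup" else None,
                K=K if model == "gblup" else None,
                folds=p["folds"], reps=p["reps"], seed=seed, trait=trait,
            )
            rows.append((trait, model, rep.mean_ability))
    import pandas as pd

    tbl = pd.DataFrame(rows, columns=["trait", "model", "prediction_ability"])
    tbl.to_csv(out / "prediction_ability.tsv", sep="\t", index=False)
    manifest.add("predict", out / "prediction_ability.tsv", {k: str(v) for k, v in p.items()})


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "impute": _stage_impute,
    "pheno": _stage_pheno,
    "structure": _stage_structure,
    "ld": _stage_ld,
    "gwas": _stage_gwas,
    "predict": _stage_predict,
}
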