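"""End-to-end pipeline: simulate -> QC -> matrices -> fit -> parameters ->
cross-validation -> LR validation, with deterministic JSON/CSV reports.

The pipeline is a thin orchestration of the library modules; every stage can
also be run on its own. Outputs are written with sorted keys and fixed
formatting so identical configurations and seeds yield byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InputError
from .simulate import (BreedingProgramConfig, GeneticArchitecture,
                       export_simulation, simulate_breeding_program)
from .relationships import (build_G_noia, build_H_noia, genotype_frequencies,
                            impute_missing_mean, noia_additive_coefficients,
                            qc_filter, read_genotypes, write_relationship_matrix)
from .mixed_model import (ModelSpec, VarianceComponents, ai_reml_estimate,
                          assemble_model, solve_mme, vc_nonorthogonality_report)
from .parameters import heritability_report, phenotypic_variance, narrow_sense_h2
from .crossval import (bootstrap_compare, corrected_line_means, max_potential_pa,
                       predictive_ability, relative_difference, run_loo_cv,
                       run_lso_cv)
from .validation import lr_statistics, prediction_agreement

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize_phenotypes"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    simulation: BreedingProgramConfig | None = None
    architecture: GeneticArchitecture | None = None
    genotypes_csv: str | None = None
    plots_csv: str | None = None
    models: list[str] = field(default_factory=lambda: ["I", "I+GA", "I+GA+GAA"])
    cv_schemes: list[str] = field(default_factory=list)
    n_boot: int = 10_000
    seed: int = 0
    vc_policy: str = "fixed"
    include_checks_in_genomic: bool = True
    reml_max_iter: int = 100
    reml_tol: float = 1e-8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        arch = raw.pop("architecture", None)
        cfg = cls(**raw)
        if sim is not None:
            if "founder_maf_distribution" in sim:
                sim["founder_maf_distribution"] = tuple(sim["founder_maf_distribution"])
            cfg.simulation = BreedingProgramConfig(**sim)
        if arch is not None:
            cfg.architecture = GeneticArchitecture(**arch)
        return cfg

    def validate(self) -> None:
        genomic = [m for m in self.models if m != "I"]
        if genomic and self.simulation is None and self.genotypes_csv is None:
            raise ConfigurationError(
                f"models {genomic} need genotypes: provide a simulation block "
                "or genotypes_csv")
        if self.simulation is None and self.plots_csv is None:
            raise ConfigurationError("provide a simulation block or plots_csv")
        for scheme in self.cv_schemes:
            if scheme not in ("loo", "lso"):
                raise ConfigurationError(f"unknown CV scheme {scheme!r}")
        for m in self.models:
            ModelSpec(model=m)  # raises on unknown names
        if self.vc_policy not in ("fixed", "per_fold"):
            raise ConfigurationError(f"unknown vc_policy {self.vc_policy!r}")


def summarize_phenotypes(plots: pd.DataFrame) -> pd.DataFrame:
    """Descriptive yield statistics per breeding cycle plus a Total row.

    SD is the sample standard deviation (n-1 divisor) of all plot
    observations; CV% = 100 * SD / mean. Line counts exclude checks.
    """
    if plots.empty:
        raise InputError("plot table is empty")

    def _row(sub: pd.DataFrame) -> dict:
        y = sub["yield_kg"].to_numpy(dtype=float)
        non_check = sub[~sub["is_check"].astype(bool)]
        sd = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
        mean = float(y.mean())
        return {
            "n_lines": int(non_check["line_id"].nunique()),
            "n_plots": int(len(sub)),
            "mean": mean,
            "sd": sd,
            "min": float(y.min()),
            "max": float(y.max()),
            "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
        }

    rows = {str(cycle): _row(sub) for cycle, sub in plots.groupby("cycle", sort=True)}
    rows["Total"] = _row(plots)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cycle"
    return out


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured stages, writing all reports under ``outdir``."""
    t0 = time.time()
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ------------------------------------------------ data
        stage = "data"
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(config.simulation, random_seed=config.seed)
            arch = config.architecture or GeneticArchitecture()
            result = simulate_breeding_program(sim_cfg, arch)
            export_simulation(result, outdir / "simulation")
            plots = result.plots
            genotypes_raw = result.genotypes_observed
        else:
            plots = pd.read_csv(config.plots_csv)
            genotypes_raw = read_genotypes(config.genotypes_csv) \
                if config.genotypes_csv else None

        summary = summarize_phenotypes(plots)
        summary.to_csv(outdir / "phenotype_summary.csv", float_format="%.6g")

        # ------------------------------------------------ relationship matrices
        G = H = None
        genomic_models = [m for m in config.models if m != "I"]
        if genomic_models:
            stage = "relationships"
            filtered, qc_report = qc_filter(genotypes_raw)
            imputed = impute_missing_mean(filtered)
            freqs = genotype_frequencies(filtered)
            coeffs = noia_additive_coefficients(imputed, freqs)
            G = build_G_noia(coeffs)
            write_relationship_matrix(G.round(10), outdir / "G_noia.tsv")
            if any(m == "I+GA+GAA" for m in config.models):
                H = build_H_noia(G)
                write_relationship_matrix(H.round(10), outdir / "H_noia.tsv")
            _write_json(outdir / "qc_report.json", {
                "n_input": qc_report.n_input, "n_retained": qc_report.n_retained,
                "removed": qc_report.removed.to_dict(orient="records")})

        # ------------------------------------------------ model fits
        stage = "fit"
        fits: dict[str, dict] = {}
        reml_kwargs = {"max_iter": config.reml_max_iter, "tol": config.reml_tol}
        for model in config.models:
            spec = ModelSpec(model=model,
                             include_checks_in_genomic=config.include_checks_in_genomic)
            bundle = assemble_model(plots, spec, G=G, H=H)
            vc = ai_reml_estimate(bundle, **reml_kwargs)
            sol = solve_mme(bundle, vc)
            fits[model] = {"spec": spec, "bundle": bundle, "vc": vc, "solution": sol}
            _write_json(outdir / f"vc_{_slug(model)}.json", vc.to_dict())
            report = heritability_report(vc, model)
            _write_json(outdir / f"heritability_{_slug(model)}.json",
                        report.to_dict() | {"rounded": report.rounded()})
            sol_df = pd.DataFrame({"l_hat": sol.random_effects["line"]})
            if sol.gebv is not None:
                sol_df["gebv"] = sol.gebv
            if sol.geev is not None:
                sol_df["geev"] = sol.geev
            sol_df.round(8).to_csv(outdir / f"solutions_{_slug(model)}.csv",
                                   index_label="line_id")
            logger.info("fitted %s: logL=%.4f in %d iterations", model,
                        vc.loglik, vc.n_iter)

        if "I+GA" in fits and "I+GA+GAA" in fits:
            _write_json(outdir / "nonorthogonality.json",
                        vc_nonorthogonality_report(fits["I+GA"]["vc"],
                                                   fits["I+GA+GAA"]["vc"]))
            rho, overlap = prediction_agreement(
                fits["I+GA"]["solution"].gebv, fits["I+GA+GAA"]["solution"].gebv,
                k=min(10, len(fits["I+GA"]["solution"].gebv)))
            _write_json(outdir / "prediction_agreement.json",
                        {"gebv_correlation": rho, "top10_overlap": overlap})

        # ------------------------------------------------ cross-validation
        stage = "cross_validation"
        ref_model = "I+GA" if "I+GA" in fits else next(iter(genomic_models), None)
        cv_out = {}
        if config.cv_schemes and ref_model:
            means = corrected_line_means(plots, fits[ref_model]["solution"])
            for scheme in config.cv_schemes:
                runner = run_loo_cv if scheme == "loo" else run_lso_cv
                per_model = {}
                for model in genomic_models:
                    f = fits[model]
                    cv = runner(plots, f["spec"], G=G, H=H, vc=f["vc"],
                                vc_policy=config.vc_policy, reml_kwargs=reml_kwargs)
                    pa = {"gebv": predictive_ability(cv.predictions["gebv"], means)}
                    if model == "I+GA+GAA":
                        pa["total"] = predictive_ability(cv.predictions["total"], means)
                    whole = fits[model]["solution"]
                    lr = {"gebv": lr_statistics(whole.gebv, cv.predictions["gebv"],
                                                "GEBV", scheme.upper()).to_dict()}
                    if model == "I+GA+GAA":
                        lr["geev"] = lr_statistics(whole.geev, cv.predictions["geev"],
                                                   "GEEV", scheme.upper()).to_dict()
                    per_model[model] = {"pa": pa, "lr": lr, "n_folds": cv.n_folds,
                                        "failures": cv.failures}
                    cv.predictions.round(8).to_csv(
                        outdir / f"cv_{scheme}_{_slug(model)}.csv", index_label="line_id")
                    per_model[model]["_pred"] = cv.predictions
                if "I+GA" in per_model and "I+GA+GAA" in per_model:
                    comp = bootstrap_compare(
                        per_model["I+GA+GAA"]["_pred"]["total"],
                        per_model["I+GA"]["_pred"]["gebv"],
                        means, n_boot=config.n_boot, seed=config.seed)
                    rd = relative_difference(per_model["I+GA+GAA"]["pa"]["total"],
                                             per_model["I+GA"]["pa"]["gebv"])
                    per_model["comparison"] = comp.to_dict() | {"relative_difference": rd}
                vc_ga = fits[ref_model]["vc"]
                h2 = narrow_sense_h2(vc_ga, "I+GA") if ref_model == "I+GA" else None
                if h2 is not None:
                    per_model["max_potential_pa_gebv"] = max_potential_pa(h2, means.n_bar)
                if "I+GA+GAA" in fits:
                    vc_aa = fits["I+GA+GAA"]["vc"]
                    prop = (vc_aa.sigma2["additive"] + vc_aa.sigma2["epistatic"]) \
                        / phenotypic_variance(vc_aa, "I+GA+GAA")
                    per_model["max_potential_pa_total"] = max_potential_pa(prop, means.n_bar)
                for m in list(per_model):
                    if isinstance(per_model[m], dict):
                        per_model[m].pop("_pred", None)
                cv_out[scheme] = per_model
            _write_json(outdir / "cv_results.json", cv_out)

        # ------------------------------------------------ manifest
        stage = "manifest"
        manifest = {
            "package": "epinoia",
            "version": __version__,
            "seed": config.seed,
            "models": config.models,
            "cv_schemes": config.cv_schemes,
            "n_obs": int(len(plots)),
            "library_versions": {"numpy": np.__version__, "pandas": pd.__version__},
        }
        if config.simulation is not None:
            sim = dataclasses.asdict(config.simulation)
            sim["founder_maf_distribution"] = list(sim["founder_maf_distribution"])
            manifest["simulation"] = sim
            if config.architecture is not None:
                manifest["architecture"] = dataclasses.asdict(config.architecture)
        _write_json(outdir / "manifest.json", manifest)
    except Exception as exc:
        logger.error("pipeline stage %r failed after %.1fs: %s", stage,
                     time.time() - t0, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def _slug(model: str) -> str:
    return model.replace("+", "_").lower()
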