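"""End-to-end analysis workflow, configuration and publication outputs.

``run_analysis`` ties the stages together the way the applied analysis
proceeds: load or simulate a cohort, run the complete-case analysis
(primary), optionally repeat it on singly imputed data (sensitivity),
attach percentile-bootstrap intervals to everything, and quantify
robustness to unmeasured mediator-outcome confounding.  Outputs are a
per-contrast results CSV (one row per contrast with Adj-TA, IDM-DE and
their difference, each with 95% bounds), a JSON metadata sidecar with
all seeds, sample sizes and a configuration hash, and a plain-text log
of each stage with row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import AnalysisSpec, BootstrapResult, bootstrap_pipeline
from .core import (
    EXPOSURE,
    MEDIATOR,
    OUTCOME,
    PGS,
    ValidationError,
    spawn_seeds,
)
from .estimands import EstimandConfig
from .imputation import ImputationSpec
from .models import FormulaSpec
from .sensitivity import SensitivityResult, find_null_rho
from .synthetic import (
    GeneratingParams,
    MissingnessSpec,
    generate_cohort,
    induce_missingness,
    params_from_dict,
    params_to_dict,
    read_cohort,
)

__all__ = [
    "PipelineConfig",
    "AnalysisBundle",
    "run_analysis",
    "summarize_associations",
    "AssociationSummary",
    "load_config",
    "save_config",
]

logger = logging.getLogger("pgsidm")


# -- configuration ----------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Whole-pipeline configuration.

    Exactly one of ``input_path`` (cohort CSV) or ``params`` (simulation)
    must be set.  All stage seeds are derived from ``seed``.
    """

    input_path: str | None = None
    params: GeneratingParams | None = None
    missingness: MissingnessSpec | None = None
    analysis: AnalysisSpec = field(default_factory=AnalysisSpec)
    bootstrap_b: int = 200
    sensitivity_grid: tuple[float, float, int] | None = (-0.5, 0.5, 41)
    sensitivity_b: int = 0
    output_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_path is None) == (self.params is None):
            raise ValidationError(
                "exactly one of input_path or simulation params must be set"
            )
        if self.bootstrap_b < 2:
            raise ValidationError(
                f"bootstrap_b must be >= 2, got {self.bootstrap_b}"
            )


@dataclass
class AnalysisBundle:
    """In-memory results of a full run."""

    config: PipelineConfig
    cohort: pd.DataFrame
    complete_case: BootstrapResult
    imputed: BootstrapResult | None
    sensitivity: SensitivityResult | None
    output_files: list[str]


# -- descriptive summary ----------------------------------------------------


@dataclass
class AssociationSummary:
    """Per-quintile descriptives plus pairwise correlations."""

    by_quintile: pd.DataFrame
    correlations: pd.DataFrame


def summarize_associations(cohort: pd.DataFrame) -> AssociationSummary:
    """Per-quintile mediator/outcome means and SDs with cell counts, and
    pairwise correlations of (pgs, mediator, outcome) on complete pairs.

    Empty quintiles are reported with count 0 and missing summary cells;
    a constant variable yields a missing (not zero) correlation.
    """
    rows = []
    for j in (1, 2, 3, 4, 5):
        sub = cohort[cohort[EXPOSURE] == j]
        row: dict = {"quintile": j, "n": int(len(sub))}
        for var in (MEDIATOR, OUTCOME):
            obs = sub[var].dropna()
            row[f"{var}_n"] = int(obs.size)
            row[f"{var}_mean"] = float(obs.mean()) if obs.size else np.nan
            row[f"{var}_sd"] = float(obs.std(ddof=1)) if obs.size > 1 else np.nan
        rows.append(row)
    corr = cohort[[PGS, MEDIATOR, OUTCOME]].corr()
    return AssociationSummary(by_quintile=pd.DataFrame(rows), correlations=corr)


# -- config (de)serialisation ----------------------------------------------


def _formula_to_dict(f: FormulaSpec) -> dict:
    return {
        "response": f.response,
        "exposure": f.exposure,
        "covariates": list(f.covariates),
        "categorical": list(f.categorical),
        "polynomials": [list(p) for p in f.polynomials],
        "interactions": [list(p) for p in f.interactions],
        "reference": f.reference,
    }


def _formula_from_dict(d: dict) -> FormulaSpec:
    return FormulaSpec(
        response=d["response"],
        exposure=d.get("exposure", EXPOSURE),
        covariates=tuple(d.get("covariates", ())),
        categorical=tuple(d.get("categorical", ())),
        polynomials=tuple(tuple(p) for p in d.get("polynomials", ())),
        interactions=tuple(tuple(p) for p in d.get("interactions", ())),
        reference=d.get("reference", 1),
    )


def config_to_dict(config: PipelineConfig) -> dict:
    a = config.analysis
    return {
        "input_path": config.input_path,
        "params": params_to_dict(config.params) if config.params else None,
        "missingness": (
            {
                "seed": config.missingness.seed,
                "targets": {
                    v: {"fraction": t.fraction, "predictors": dict(t.predictors)}
                    for v, t in config.missingness.targets.items()
                },
            }
            if config.missingness
            else None
        ),
        "analysis": {
            "mediator_formula": _formula_to_dict(a.mediator_formula),
            "outcome_formula_conditional": _formula_to_dict(
                a.outcome_formula_conditional
            ),
            "outcome_formula_marginal": _formula_to_dict(a.outcome_formula_marginal),
            "estimand": {
                "k": a.estimand.k,
                "reference": a.estimand.reference,
                "adj_ta_mode": a.estimand.adj_ta_mode,
                "standardization": a.estimand.standardization,
                "truncate_draws": a.estimand.truncate_draws,
            },
            "imputation": (
                {
                    "variables": list(a.imputation.variables),
                    "burn_in": a.imputation.burn_in,
                    "nonlinear": a.imputation.nonlinear,
                }
                if a.imputation
                else None
            ),
        },
        "bootstrap_b": config.bootstrap_b,
        "sensitivity_grid": (
            list(config.sensitivity_grid) if config.sensitivity_grid else None
        ),
        "sensitivity_b": config.sensitivity_b,
        "output_dir": config.output_dir,
        "seed": config.seed,
    }


def config_from_dict(d: dict) -> PipelineConfig:
    from .synthetic import TargetMissingness

    a = d.get("analysis", {})
    est = a.get("estimand", {})
    imp = a.get("imputation")
    analysis = AnalysisSpec(
        mediator_formula=(
            _formula_from_dict(a["mediator_formula"])
            if "mediator_formula" in a
            else AnalysisSpec().mediator_formula
        ),
        outcome_formula_conditional=(
            _formula_from_dict(a["outcome_formula_conditional"])
            if "outcome_formula_conditional" in a
            else AnalysisSpec().outcome_formula_conditional
        ),
        outcome_formula_marginal=(
            _formula_from_dict(a["outcome_formula_marginal"])
            if "outcome_formula_marginal" in a
            else AnalysisSpec().outcome_formula_marginal
        ),
        estimand=EstimandConfig(**est) if est else EstimandConfig(),
        imputation=(
            ImputationSpec(
                variables=tuple(imp.get("variables", ImputationSpec().variables)),
                burn_in=imp.get("burn_in", 10),
                nonlinear=imp.get("nonlinear", True),
            )
            if imp
            else None
        ),
    )
    miss = d.get("missingness")
    missingness = None
    if miss:
        missingness = MissingnessSpec(
            targets={
                v: TargetMissingness(
                    fraction=t["fraction"], predictors=dict(t.get("predictors", {}))
                )
                for v, t in miss.get("targets", {}).items()
            },
            seed=miss.get("seed", 0),
        )
    grid = d.get("sensitivity_grid")
    return PipelineConfig(
        input_path=d.get("input_path"),
        params=params_from_dict(d["params"]) if d.get("params") else None,
        missingness=missingness,
        analysis=analysis,
        bootstrap_b=d.get("bootstrap_b", 200),
        sensitivity_grid=tuple(grid) if grid else None,
        sensitivity_b=d.get("sensitivity_b", 0),
        output_dir=d.get("output_dir", "results"),
        seed=d.get("seed", 0),
    )


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_hash(config: PipelineConfig) -> str:
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


# -- main entry point -------------------------------------------------------


def _run_stage(name: str, fn, *args, **kwargs):
    """Run one stage, attaching the stage name to any failure."""
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_analysis(config: PipelineConfig) -> AnalysisBundle:
    """Execute the configured workflow and write the results bundle.

    Stage errors propagate with the stage name attached and partially
    written outputs are removed.  Running twice with the same master seed
    produces byte-identical output files.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    log_path = outdir / "analysis.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    written.append(str(log_path))

    seeds = spawn_seeds(config.seed, 5)
    try:
        # -- load or simulate ------------------------------------------------
        if config.input_path is not None:
            cohort = _run_stage("load", read_cohort, config.input_path)
            logger.info("loaded cohort from %s: %d rows", config.input_path, len(cohort))
        else:
            params = replace(config.params, seed=seeds[0])
            cohort = _run_stage("simulate", generate_cohort, params)
            logger.info("simulated cohort: %d rows (seed %d)", len(cohort), seeds[0])
            if config.missingness is not None:
                spec = replace(config.missingness, seed=seeds[1])
                cohort = _run_stage("missingness", induce_missingness, cohort, spec)
                logger.info(
                    "induced missingness: %s",
                    {v: int(cohort[v].isna().sum()) for v in spec.targets},
                )

        # -- complete-case (primary) ----------------------------------------
        cc_analysis = replace(config.analysis, imputation=None)
        complete = _run_stage(
            "complete-case", bootstrap_pipeline,
            cohort, cc_analysis, config.bootstrap_b, seeds[2],
        )
        logger.info(
            "complete-case analysis: n=%d, B=%d, %d failed replicates",
            complete.point.meta.get("n_analysis", -1),
            config.bootstrap_b,
            complete.n_failed,
        )

        # -- imputed (sensitivity) ------------------------------------------
        imputed = None
        if config.analysis.imputation is not None:
            imputed = _run_stage(
                "imputed", bootstrap_pipeline,
                cohort, config.analysis, config.bootstrap_b, seeds[3],
            )
            logger.info(
                "imputed-data analysis: n=%d, %d failed replicates",
                imputed.point.meta.get("n_analysis", -1),
                imputed.n_failed,
            )

        # -- unmeasured-confounding sensitivity -----------------------------
        sens = None
        if config.sensitivity_grid is not None:
            sens = _run_stage(
                "sensitivity", find_null_rho,
                cohort,
                cc_analysis,
                grid=config.sensitivity_grid,
                b=config.sensitivity_b,
                seed=seeds[4],
            )
            logger.info(
                "sensitivity: rho*=%s (crossed=%s, contrast %d)",
                f"{sens.rho_star:.4f}" if sens.crossed else "n/a",
                sens.crossed,
                sens.contrast,
            )

        # -- outputs ---------------------------------------------------------
        results = complete.to_frame()
        results.insert(0, "analysis", "complete_case")
        if imputed is not None:
            imp_frame = imputed.to_frame()
            imp_frame.insert(0, "analysis", "imputed")
            results = pd.concat([results, imp_frame], ignore_index=True)
        results_path = outdir / "results.csv"
        results.to_csv(results_path, index=False, float_format="%.6f")
        written.append(str(results_path))

        if sens is not None:
            sens_path = outdir / "sensitivity.csv"
            sens.to_frame().to_csv(sens_path, index=False, float_format="%.6f")
            written.append(str(sens_path))

        meta = {
            "software_version": __version__,
            "master_seed": config.seed,
            "stage_seeds": seeds,
            "config_hash": config_hash(config),
            "n_input": int(len(cohort)),
            "n_complete_case": complete.point.meta.get("n_analysis"),
            "n_imputed": (
                imputed.point.meta.get("n_analysis") if imputed else None
            ),
            "bootstrap_b": config.bootstrap_b,
            "expansion_k": config.analysis.estimand.k,
            "rho_star": sens.rho_star if sens and sens.crossed else None,
            "rho_star_ci": list(sens.ci) if sens and sens.ci else None,
        }
        meta_path = outdir / "metadata.json"
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        written.append(str(meta_path))

        return AnalysisBundle(
            config=config,
            cohort=cohort,
            complete_case=complete,
            imputed=imputed,
            sensitivity=sens,
            output_files=written,
        )
    except Exception:
        for f in written:
            try:
                Path(f).unlink(missing_ok=True)
            except OSError:
                pass
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def plot_disparity(result: BootstrapResult, path) -> None:
    """Point-and-interval chart of Adj-TA and IDM-DE per contrast."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    contrasts = list(result.point.contrasts)
    x = np.arange(len(contrasts), dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    for offset, metric, values, color in (
        (-0.1, "adj_ta", result.point.adj_ta, "#1f77b4"),
        (0.1, "idm_de", result.point.idm_de, "#ff7f0e"),
    ):
        y = [values[j] for j in contrasts]
        lo = [values[j] - result.lower[metric][j] for j in contrasts]
        hi = [result.upper[metric][j] - values[j] for j in contrasts]
        ax.errorbar(
            x + offset, y, yerr=[lo, hi], fmt="o", color=color,
            label=metric.replace("_", "-").upper(), capsize=3,
        )
    ax.set_xticks(x)
    ax.set_xticklabels([f"Q{j} vs Q1" for j in contrasts])
    ax.set_ylabel("BMI difference (kg/m$^2$)")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
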