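"""Percentile-bootstrap uncertainty for the disparity estimands.

Each replicate resamples participants with replacement (n out of n),
then reruns the *entire* pipeline on the resample: the single stochastic
imputation when enabled (with a replicate-specific random substream),
re-derivation of the cohort-specific exposure quintiles, model fits and
estimand computation.  Quintiles are recomputed because the exposure is
defined by the sample at hand; imputation is redone because a shared
imputation would understate between-replicate variability.  Intervals
are the 2.5th/97.5th percentiles of the replicate distribution
(percentile method), with the point estimate taken from the original
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import models
from .core import PGS, EXPOSURE, DisparityEstimate, ValidationError, spawn_seeds
from .estimands import EstimandConfig, estimate_disparity
from .imputation import ImputationSpec, impute_chained
from .models import (
    FormulaSpec,
    default_mediator_formula,
    default_outcome_formula,
    fit_mediator_model,
    fit_outcome_model,
)

__all__ = [
    "AnalysisSpec",
    "BootstrapResult",
    "run_estimation",
    "bootstrap_pipeline",
    "bootstrap_statistic",
]


@dataclass(frozen=True)
class AnalysisSpec:
    """Everything needed to turn a raw cohort into a DisparityEstimate."""

    mediator_formula: FormulaSpec = field(default_factory=default_mediator_formula)
    outcome_formula_conditional: FormulaSpec = field(
        default_factory=lambda: default_outcome_formula(True)
    )
    outcome_formula_marginal: FormulaSpec = field(
        default_factory=lambda: default_outcome_formula(False)
    )
    estimand: EstimandConfig = field(default_factory=EstimandConfig)
    imputation: ImputationSpec | None = None

    def analysis_variables(self) -> tuple[str, ...]:
        vs: list[str] = [PGS]
        for f in (
            self.mediator_formula,
            self.outcome_formula_conditional,
            self.outcome_formula_marginal,
        ):
            for v in f.variables():
                if v not in vs and v != EXPOSURE:
                    vs.append(v)
        return tuple(vs)


def fit_models(cohort_cc: pd.DataFrame, analysis: AnalysisSpec):
    """Fit the mediator, conditional-outcome and marginal-outcome models."""
    mm = fit_mediator_model(cohort_cc, analysis.mediator_formula)
    oc = fit_outcome_model(
        cohort_cc, analysis.outcome_formula_conditional, conditional_on_mediator=True
    )
    om = fit_outcome_model(
        cohort_cc, analysis.outcome_formula_marginal, conditional_on_mediator=False
    )
    return mm, oc, om


def prepare_analysis_sample(
    cohort: pd.DataFrame, analysis: AnalysisSpec, seed: int
) -> pd.DataFrame:
    """Optionally impute, re-derive quintiles, take the complete-case
    intersection over all model variables."""
    df = cohort
    if analysis.imputation is not None:
        df = impute_chained(df, replace(analysis.imputation, seed=seed))
    df = df.copy()
    df[EXPOSURE] = models.assign_quintiles(df[PGS])
    return df.dropna(subset=list(analysis.analysis_variables())).reset_index(
        drop=True
    )


def run_estimation(
    cohort: pd.DataFrame, analysis: AnalysisSpec, seed: int
) -> DisparityEstimate:
    """Full single-pass pipeline: (impute) -> quintiles -> complete cases
    -> model fits -> estimands.  ``seed`` drives the imputation and the
    Monte-Carlo mediator draws through separate substreams."""
    s_imp, s_est = spawn_seeds(seed, 2)
    cc = prepare_analysis_sample(cohort, analysis, s_imp)
    est_cfg = replace(analysis.estimand, seed=s_est)
    mm, oc, om = fit_models(cc, analysis)
    est = estimate_disparity(cc, mm, oc, om, est_cfg)
    est.meta["n_analysis"] = int(len(cc))
    est.meta["small_sample"] = bool(len(cc) < 50)
    return est


@dataclass
class BootstrapResult:
    """Point estimates with percentile bounds per estimand and contrast."""

    point: DisparityEstimate
    lower: dict[str, dict[int, float]]
    upper: dict[str, dict[int, float]]
    b: int
    n_failed: int
    seed: int
    small_sample_warning: bool
    samples: pd.DataFrame = field(repr=False)
    failures: list[str] = field(default_factory=list, repr=False)

    def interval(self, metric: str, contrast: int) -> tuple[float, float]:
        return self.lower[metric][contrast], self.upper[metric][contrast]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in self.point.contrasts:
            row = {"contrast": j}
            for metric, values in (
                ("adj_ta", self.point.adj_ta),
                ("idm_de", self.point.idm_de),
                ("difference", self.point.difference),
            ):
                row[metric] = values[j]
                row[f"{metric}_lo"] = self.lower[metric][j]
                row[f"{metric}_hi"] = self.upper[metric][j]
            rows.append(row)
        return pd.DataFrame(rows)


def bootstrap_statistic(
    cohort: pd.DataFrame,
    statistic,
    b: int,
    seed: int,
    max_failure_fraction: float = 0.10,
) -> tuple[list, list[str], list[int]]:
    """Generic n-out-of-n resampling engine.

    ``statistic(df, seed)`` is evaluated on each resample with an
    independent, derivable substream; failing replicates are recorded and
    skipped, and more than ``max_failure_fraction`` of failures aborts.
    Returns (replicate values, failure messages, per-replicate seeds).
    """
    if b < 2:
        raise ValidationError(f"bootstrap needs B >= 2 replicates, got {b}")
    n = len(cohort)
    seeds = spawn_seeds(seed, 2 * b)
    values, failures = [], []
    for r in range(b):
        rng = np.random.default_rng(seeds[2 * r])
        idx = rng.integers(0, n, n)
        resample = cohort.iloc[idx].reset_index(drop=True)
        try:
            values.append(statistic(resample, seeds[2 * r + 1]))
        except Exception as exc:  # noqa: BLE001 - any stage may fail on a resample
            failures.append(f"replicate {r}: {type(exc).__name__}: {exc}")
    if len(failures) > max_failure_fraction * b:
        raise ValidationError(
            f"{len(failures)}/{b} bootstrap replicates failed; results "
            f"would be unreliable. First failure: {failures[0]}"
        )
    return values, failures, seeds


def bootstrap_pipeline(
    cohort: pd.DataFrame,
    analysis: AnalysisSpec,
    b: int,
    seed: int,
) -> BootstrapResult:
    """Percentile bootstrap of the full estimation pipeline."""
    point_seed, resample_seed = spawn_seeds(seed, 2)
    point = run_estimation(cohort, analysis, point_seed)

    def stat(df: pd.DataFrame, s: int) -> dict:
        est = run_estimation(df, analysis, s)
        row: dict = {}
        for j in est.contrasts:
            row[f"adj_ta_{j}"] = est.adj_ta[j]
            row[f"idm_de_{j}"] = est.idm_de[j]
            row[f"difference_{j}"] = est.difference[j]
        return row

    values, failures, _ = bootstrap_statistic(cohort, stat, b, resample_seed)
    samples = pd.DataFrame(values)
    lower: dict[str, dict[int, float]] = {m: {} for m in ("adj_ta", "idm_de", "difference")}
    upper: dict[str, dict[int, float]] = {m: {} for m in ("adj_ta", "idm_de", "difference")}
    for j in point.contrasts:
        for metric in lower:
            col = samples[f"{metric}_{j}"].dropna().to_numpy()
            lower[metric][j] = float(np.percentile(col, 2.5))
            upper[metric][j] = float(np.percentile(col, 97.5))
    return BootstrapResult(
        point=point,
        lower=lower,
        upper=upper,
        b=b,
        n_failed=len(failures),
        seed=seed,
        small_sample_warning=bool(len(cohort) < 50),
        samples=samples,
        failures=failures,
    )
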