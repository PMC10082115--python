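"""Sensitivity of the mediator's impact to unmeasured M-Y confounding.

An omitted mediator-outcome confounder would induce a correlation rho
between the errors of the mediator model and the outcome model.  Under
the linear-model adjustment of Imai, Keele & Yamamoto, positing a value
of rho pins down the mediator coefficient that would have been obtained
had the confounder been controlled:

    gamma(rho) = (s1 / s2) * ( r12 - rho * sqrt((1 - r12^2) / (1 - rho^2)) )

where r12 is the observed correlation between the residuals of Y ~ X + C
and of M ~ X + C, and s1, s2 are those residuals' standard deviations.
At rho = 0 this is exactly the OLS coefficient of M in Y ~ X + M + C
(Frisch-Waugh), so the adjusted difference at rho = 0 reproduces the
unadjusted one; gamma(rho) crosses zero exactly at rho = r12.

Given gamma(rho), the remaining coefficients are refit under the
constraint (OLS of Y - gamma(rho)*M on X + C), the IDM-DE is recomputed
from the adjusted outcome predictions with the deterministic quadrature
integrator (so the reported rho* carries no Monte-Carlo seed
dependence), and rho* is the root of the adjusted difference
Adj-TA_j - IDM-DE_j(rho) on (-0.95, 0.95).  The adjustment formula
requires the conditional outcome model to be linear in the mediator
(single main effect, no mediator interactions or powers); anything else
is refused.  Its correctness is certified empirically by recovery
simulations in which a latent confounder with known induced residual
correlation generates the entire apparent mediator-outcome association.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .core import MEDIATOR, ValidationError, spawn_seeds
from .bootstrap import AnalysisSpec, bootstrap_statistic, prepare_analysis_sample
from .estimands import EstimandConfig, estimate_adj_ta, numeric_oracle
from .models import (
    FittedLinearModel,
    FormulaSpec,
    fit_mediator_model,
    fit_outcome_model,
)

__all__ = [
    "SensitivityResult",
    "adjusted_difference_at_rho",
    "find_null_rho",
]


@dataclass
class SensitivityResult:
    """Difference-versus-rho curve and the null-crossing correlation."""

    contrast: int
    grid_rho: np.ndarray
    grid_difference: np.ndarray
    rho_star: float
    crossed: bool
    ci: tuple[float, float] | None = None
    b: int = 0
    n_failed: int = 0
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rho": self.grid_rho, "adjusted_difference": self.grid_difference}
        )


# -- engine -----------------------------------------------------------------


class _RhoEngine:
    """Precomputes everything so each rho evaluation is a dot product."""

    def __init__(
        self,
        cohort: pd.DataFrame,
        mediator_model: FittedLinearModel,
        outcome_marginal: FittedLinearModel,
        outcome_conditional: FittedLinearModel,
        config: EstimandConfig,
        contrast: int,
        n_nodes: int = 64,
    ) -> None:
        self._validate_conditional(outcome_conditional, outcome_marginal)
        self.cohort = cohort
        self.mediator_model = mediator_model
        self.outcome_marginal = outcome_marginal
        self.outcome_conditional = outcome_conditional
        self.config = replace(config, truncate_draws=False)
        self.contrast = int(contrast)
        self.n_nodes = n_nodes

        # residuals of Y and M on the marginal design (X dummies + C terms)
        parts = outcome_marginal.design_parts(cohort)
        X = np.column_stack([base for _, _, base in parts])
        y = cohort[outcome_marginal.spec.response].to_numpy(dtype=float)
        m = cohort[MEDIATOR].to_numpy(dtype=float)
        self._bY, *_ = np.linalg.lstsq(X, y, rcond=None)
        self._bM, *_ = np.linalg.lstsq(X, m, rcond=None)
        rY = y - X @ self._bY
        rM = m - X @ self._bM
        self.s1 = float(np.sqrt(rY @ rY / len(rY)))
        self.s2 = float(np.sqrt(rM @ rM / len(rM)))
        if self.s1 == 0.0 or self.s2 == 0.0:
            raise ValidationError(
                "degenerate residuals: sensitivity correlation undefined"
            )
        self.r12 = float(rY @ rM / (len(rY) * self.s1 * self.s2))
        self._X = X
        self._names = [name for name, _, _ in parts]

        adj = estimate_adj_ta(cohort, outcome_marginal, self.config)
        if self.contrast not in adj.values:
            raise ValidationError(
                f"contrast {contrast} not among estimated contrasts "
                f"{sorted(adj.values)}"
            )
        self.adj_ta = adj.values[self.contrast]

    @staticmethod
    def _validate_conditional(
        cond: FittedLinearModel, marg: FittedLinearModel
    ) -> None:
        degs = cond.mediator_degrees()
        med_cols = [(n, d) for n, d in zip(cond.names, degs) if d > 0]
        if med_cols != [(MEDIATOR, 1)]:
            raise ValidationError(
                "the residual-correlation adjustment requires an outcome "
                "model linear in the mediator (single main effect); got "
                f"mediator terms {med_cols or 'none'}"
            )
        non_med = [n for n, d in zip(cond.names, degs) if d == 0]
        if non_med != list(marg.names):
            raise ValidationError(
                "conditional and marginal outcome models must share the "
                f"same non-mediator terms; got {non_med} vs {list(marg.names)}"
            )

    def gamma(self, rho: float) -> float:
        if not -1.0 < rho < 1.0:
            raise ValidationError(f"rho must lie in (-1, 1), got {rho}")
        r = self.r12
        return (self.s1 / self.s2) * (
            r - rho * np.sqrt((1.0 - r * r) / (1.0 - rho * rho))
        )

    def _adjusted_conditional(self, gamma: float) -> FittedLinearModel:
        """Outcome model with the mediator coefficient fixed at ``gamma``
        and all other coefficients refit under that constraint."""
        b = self._bY - gamma * self._bM  # OLS of (Y - gamma*M) on marginal X
        adj = replace(self.outcome_conditional)
        params = np.empty(len(adj.names))
        degs = adj.mediator_degrees()
        for i, (name, d) in enumerate(zip(adj.names, degs)):
            params[i] = gamma if d == 1 else b[self._names.index(name)]
        adj.params = params
        return adj

    def idm_de(self, gamma: float) -> float:
        model = self._adjusted_conditional(gamma)
        vals = numeric_oracle(
            self.cohort, self.mediator_model, model, self.config, self.n_nodes
        )
        return vals.values[self.contrast]

    def difference(self, rho: float) -> float:
        return self.adj_ta - self.idm_de(self.gamma(rho))

    def unadjusted_difference(self) -> float:
        """Quadrature difference using the jointly fitted conditional model
        (no rho adjustment); equals ``difference(0.0)`` up to round-off."""
        vals = numeric_oracle(
            self.cohort,
            self.mediator_model,
            self.outcome_conditional,
            self.config,
            self.n_nodes,
        )
        return self.adj_ta - vals.values[self.contrast]


def adjusted_difference_at_rho(
    cohort: pd.DataFrame,
    mediator_model: FittedLinearModel,
    outcome_marginal: FittedLinearModel,
    outcome_conditional: FittedLinearModel,
    rho: float,
    config: EstimandConfig,
    contrast: int = 5,
) -> float:
    """Adjusted difference Adj-TA_j - IDM-DE_j under hypothesised residual
    correlation ``rho`` (kg/m^2)."""
    engine = _RhoEngine(
        cohort, mediator_model, outcome_marginal, outcome_conditional,
        config, contrast,
    )
    return engine.difference(float(rho))


# -- root finding -----------------------------------------------------------


def _sensitivity_formulas(analysis: AnalysisSpec) -> tuple[FormulaSpec, FormulaSpec]:
    """The adjustment needs a conditional model that is the marginal model
    plus a single mediator main effect; derive it from the marginal spec."""
    marg = analysis.outcome_formula_marginal
    cond = replace(marg, covariates=(MEDIATOR,) + tuple(marg.covariates))
    return marg, cond


def _engine_from_cohort(
    cc: pd.DataFrame, analysis: AnalysisSpec, contrast: int | None, n_nodes: int
) -> _RhoEngine:
    marg_spec, cond_spec = _sensitivity_formulas(analysis)
    mm = fit_mediator_model(cc, analysis.mediator_formula)
    om = fit_outcome_model(cc, marg_spec, conditional_on_mediator=False)
    oc = fit_outcome_model(cc, cond_spec, conditional_on_mediator=True)
    if contrast is None:
        contrast = int(max(l for l in om.exposure_levels))
    return _RhoEngine(cc, mm, om, oc, analysis.estimand, contrast, n_nodes)


def _root(engine: _RhoEngine, bracket: tuple[float, float]) -> tuple[float, bool]:
    lo, hi = bracket
    f_lo, f_hi = engine.difference(lo), engine.difference(hi)
    if f_lo == 0.0:
        return lo, True
    if f_hi == 0.0:
        return hi, True
    if np.sign(f_lo) == np.sign(f_hi):
        return float("nan"), False
    rho = optimize.brentq(engine.difference, lo, hi, xtol=1e-10)
    if abs(engine.difference(rho)) > 1e-6:
        raise ValidationError("root refinement failed to reach |diff| < 1e-6")
    return float(rho), True


def find_null_rho(
    cohort: pd.DataFrame,
    analysis: AnalysisSpec,
    contrast: int | None = None,
    grid: tuple[float, float, int] = (-0.5, 0.5, 41),
    bracket: tuple[float, float] = (-0.95, 0.95),
    b: int = 0,
    seed: int = 0,
    n_nodes: int = 64,
) -> SensitivityResult:
    """Minimal residual correlation rho* nullifying the mediator's impact.

    Runs the standard preparation (quintile derivation, complete cases),
    fits the three models, evaluates the adjusted-difference curve on the
    grid and root-finds rho* on ``bracket``.  If the adjusted difference
    never changes sign, the result is flagged ``crossed=False`` with
    ``rho_star = nan`` instead of a root.  ``b >= 2`` adds a percentile
    bootstrap interval for rho*, re-deriving quintiles and refitting on
    every resample.  The default contrast is the top quintile (largest
    disparity).
    """
    s_prep, s_boot = spawn_seeds(seed, 2)
    cc = prepare_analysis_sample(cohort, analysis, s_prep)
    engine = _engine_from_cohort(cc, analysis, contrast, n_nodes)
    rho_star, crossed = _root(engine, bracket)

    lo, hi, npts = grid
    grid_rho = np.linspace(lo, hi, int(npts))
    grid_diff = np.array([engine.difference(r) for r in grid_rho])

    ci = None
    n_failed = 0
    if b >= 2:

        def stat(df: pd.DataFrame, s: int) -> float:
            cc_r = prepare_analysis_sample(df, analysis, s)
            eng = _engine_from_cohort(cc_r, analysis, engine.contrast, n_nodes)
            r, ok = _root(eng, bracket)
            if not ok:
                raise ValidationError("no null crossing on this resample")
            return r

        values, failures, _ = bootstrap_statistic(cohort, stat, b, s_boot)
        n_failed = len(failures)
        arr = np.asarray(values, dtype=float)
        ci = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))

    return SensitivityResult(
        contrast=engine.contrast,
        grid_rho=grid_rho,
        grid_difference=grid_diff,
        rho_star=rho_star,
        crossed=crossed,
        ci=ci,
        b=b,
        n_failed=n_failed,
        meta={
            "r12": engine.r12,
            "adj_ta": engine.adj_ta,
            "n_analysis": int(len(cc)),
        },
    )
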