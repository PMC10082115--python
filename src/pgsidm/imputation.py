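"""Single stochastic imputation by chained equations (FCS).

One completed dataset is produced: missing cells are first filled by
random draws from the observed marginals, then a fixed number of burn-in
cycles (default 10) re-imputes each incomplete variable from a
conditional model fitted to the current completed data, drawing
*stochastically* (normal residual draws for continuous variables,
category draws for binary/ordinal ones) rather than plugging in
conditional means.  Observed cells are never altered, and the whole
procedure is deterministic given the seed.

Single imputation is appropriate here because estimate uncertainty comes
from the bootstrap, with the imputation redone inside every bootstrap
replicate; confidence intervals on imputed data should therefore only be
reported through that path.  Chain non-convergence is not detected (a
single chain with a fixed burn-in, by design).  Predictive-mean matching
would be a drop-in alternative draw mechanism but is not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (
    ANALYSIS_VARIABLES,
    EDUCATION,
    MATERNAL_BMI,
    MEDIATOR,
    OUTCOME,
    SEX,
    ValidationError,
)

__all__ = ["ImputationSpec", "impute_chained"]


@dataclass(frozen=True)
class ImputationSpec:
    """Chained-equations settings.

    Each imputed variable's conditional model includes all other analysis
    variables; with ``nonlinear=True`` the predictors additionally include
    squared maternal BMI / mediator terms and the mediator-by-sex product,
    mirroring the non-linearities and interactions of the analysis models.
    The derived quintile column is not used as a predictor (it is
    recomputed from the completed score downstream).
    """

    variables: tuple[str, ...] = (MEDIATOR, OUTCOME, MATERNAL_BMI)
    burn_in: int = 10
    nonlinear: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 1:
            raise ValidationError(f"burn_in must be >= 1, got {self.burn_in}")


_FAMILIES = {SEX: "logistic", EDUCATION: "multinomial"}


def _design(df: pd.DataFrame, predictors: list[str], nonlinear: bool) -> np.ndarray:
    cols = [np.ones(len(df))]
    cols += [df[p].to_numpy(dtype=float) for p in predictors]
    if nonlinear:
        for p in (MATERNAL_BMI, MEDIATOR):
            if p in predictors:
                cols.append(df[p].to_numpy(dtype=float) ** 2)
        if MEDIATOR in predictors and SEX in predictors:
            cols.append(
                df[MEDIATOR].to_numpy(dtype=float) * df[SEX].to_numpy(dtype=float)
            )
    return np.column_stack(cols)


def _draw_gaussian(
    rng: np.random.Generator,
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    X_mis: np.ndarray,
    lower: float | None,
) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta
    dof = max(len(y_obs) - X_obs.shape[1], 1)
    sigma = float(np.sqrt((resid @ resid) / dof))
    mu = X_mis @ beta
    draw = mu + sigma * rng.standard_normal(len(mu))
    if lower is not None and sigma > 0:
        for _ in range(50):
            bad = draw < lower
            if not bad.any():
                break
            draw[bad] = mu[bad] + sigma * rng.standard_normal(int(bad.sum()))
        np.clip(draw, lower, None, out=draw)
    return draw


def _draw_categorical(
    rng: np.random.Generator,
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    X_mis: np.ndarray,
    binary: bool,
) -> np.ndarray:
    cats = np.unique(y_obs)
    if cats.size < 2:
        return np.full(len(X_mis), cats[0], dtype=float)
    try:
        if binary:
            codes = (y_obs == cats[-1]).astype(float)
            fit = sm.Logit(codes, X_obs).fit(disp=0, maxiter=100)
            p1 = np.clip(fit.predict(X_mis), 0.0, 1.0)
            return np.where(rng.random(len(X_mis)) < p1, cats[-1], cats[0]).astype(float)
        codes = np.searchsorted(cats, y_obs).astype(int)
        fit = sm.MNLogit(codes, X_obs).fit(disp=0, maxiter=100)
        probs = np.asarray(fit.predict(X_mis))
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(len(X_mis))[:, None]
        idx = (probs.cumsum(axis=1) < u).sum(axis=1)
        return cats[np.minimum(idx, cats.size - 1)].astype(float)
    except Exception:
        # perfect separation or non-convergence: fall back to a marginal draw
        return rng.choice(cats, size=len(X_mis)).astype(float)


def impute_chained(cohort: pd.DataFrame, spec: ImputationSpec) -> pd.DataFrame:
    """Return a completed copy of the cohort.

    Raises if any listed variable has no observed values or if no fully
    observed analysis variable exists to anchor the chain.
    """
    out = cohort.copy()
    analysis_vars = [v for v in ANALYSIS_VARIABLES if v in cohort.columns]
    for v in spec.variables:
        if v not in cohort.columns:
            raise ValidationError(f"imputation variable {v!r} not in cohort")
        if cohort[v].notna().sum() == 0:
            raise ValidationError(
                f"variable {v!r} has no observed values; cannot impute"
            )
    if not any(cohort[v].notna().all() for v in analysis_vars):
        raise ValidationError(
            "chained imputation needs at least one fully observed analysis "
            "variable"
        )

    masks = {v: cohort[v].isna().to_numpy() for v in spec.variables}
    incomplete = [v for v in spec.variables if masks[v].any()]
    if not incomplete:
        return out

    rng = np.random.default_rng(spec.seed)

    # initial fill from observed marginals
    for v in sorted(incomplete):
        obs = cohort[v].dropna().to_numpy(dtype=float)
        out.loc[masks[v], v] = rng.choice(obs, size=int(masks[v].sum()))

    # visit order: increasing missingness fraction, alphabetical tie-break
    order = sorted(incomplete, key=lambda v: (masks[v].mean(), v))
    lower_bounds = {MEDIATOR: 0.0, OUTCOME: 1e-6}

    for _ in range(spec.burn_in):
        for v in order:
            predictors = [p for p in analysis_vars if p != v]
            X = _design(out, predictors, spec.nonlinear)
            mis = masks[v]
            y_obs = cohort.loc[~mis, v].to_numpy(dtype=float)
            family = _FAMILIES.get(v, "gaussian")
            if family == "gaussian":
                out.loc[mis, v] = _draw_gaussian(
                    rng, X[~mis], y_obs, X[mis], lower_bounds.get(v)
                )
            else:
                out.loc[mis, v] = _draw_categorical(
                    rng, X[~mis], y_obs, X[mis], binary=(family == "logistic")
                )

    # observed cells are untouched by construction; enforce it anyway
    for v in spec.variables:
        out.loc[~masks[v], v] = cohort.loc[~masks[v], v]
    return out
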