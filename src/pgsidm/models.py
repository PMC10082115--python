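"""Parametric working models for the plug-in estimator.

Three regressions drive the g-computation: the mediator model
``f(M | X, C)``, the conditional outcome model ``E(Y | X, M, C)`` and the
marginal outcome model ``E(Y | X, C)``.  The exposure X always enters as
categorical dummies against a reference level (default: quintile 1,
lowest liability); confounders C may enter with polynomial and pairwise
interaction terms, including mediator-by-confounder interactions in the
conditional outcome model.

Designs are built directly from a structured :class:`FormulaSpec` rather
than a formula string, which lets the estimators substitute mediator
*draw moments* for the mediator columns: every design column is the
product of a mediator power ``M**d`` (``d >= 0``) and a mediator-free
base column, so the expectation of a prediction over mediator draws is
obtained by replacing ``M**d`` with the mean of ``draws**d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import (
    EDUCATION,
    EXPOSURE,
    MATERNAL_BMI,
    MEDIATOR,
    SEX,
    ValidationError,
)

__all__ = [
    "FormulaSpec",
    "FittedLinearModel",
    "fit_mediator_model",
    "fit_outcome_model",
    "draw_mediator",
    "assign_quintiles",
    "default_mediator_formula",
    "default_outcome_formula",
]


# -- formula specification --------------------------------------------------


@dataclass(frozen=True)
class FormulaSpec:
    """Additive model specification over cohort columns.

    Parameters
    ----------
    response : str
        Name of the modelled column.
    exposure : str or None
        Categorical exposure column entering as dummies against
        ``reference``; ``None`` omits the exposure entirely.
    covariates : tuple of str
        Main effects.  Columns listed in ``categorical`` are expanded to
        dummies against their lowest observed level; all others enter
        numerically.
    polynomials : tuple of (str, int)
        Extra powers 2..degree of a numeric variable (the main effect is
        not implied; list it in ``covariates``).
    interactions : tuple of (str, str)
        Pairwise products of numeric/binary variables.  The exposure may
        appear only in an exposure-by-mediator pair, which expands to one
        dummy-times-mediator column per non-reference level (letting the
        mediator's effect vary with liability).
    reference : int
        Exposure reference level (1 = lowest liability by default).
    """

    response: str
    exposure: str | None = EXPOSURE
    covariates: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()
    polynomials: tuple[tuple[str, int], ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    reference: int = 1

    def __post_init__(self) -> None:
        if self.exposure is not None:
            for a, b in self.interactions:
                if self.exposure in (a, b) and {a, b} != {self.exposure, MEDIATOR}:
                    raise ValidationError(
                        "the exposure may only interact with the mediator "
                        f"(got {a}:{b})"
                    )
        for var, deg in self.polynomials:
            if deg < 2:
                raise ValidationError(
                    f"polynomial degree for {var!r} must be >= 2, got {deg}"
                )

    def variables(self) -> tuple[str, ...]:
        """All columns referenced by the formula, response included."""
        seen: list[str] = [self.response]
        pool = list(self.covariates)
        if self.exposure is not None:
            pool.append(self.exposure)
        pool += [v for v, _ in self.polynomials]
        for a, b in self.interactions:
            pool += [a, b]
        for v in pool:
            if v not in seen:
                seen.append(v)
        return tuple(seen)

    def rhs_variables(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables() if v != self.response)


def default_mediator_formula() -> FormulaSpec:
    """Exposure dummies + confounder mains + maternal-BMI quadratic."""
    return FormulaSpec(
        response=MEDIATOR,
        covariates=(SEX, EDUCATION, MATERNAL_BMI),
        categorical=(EDUCATION,),
        polynomials=((MATERNAL_BMI, 2),),
    )


def default_outcome_formula(conditional_on_mediator: bool) -> FormulaSpec:
    """Default outcome model.

    The conditional variant adds the mediator main effect plus
    mediator-by-sex and mediator-by-maternal-BMI interactions, allowing a
    general parametric response surface; the marginal variant contains no
    mediator term at all.
    """
    covs: tuple[str, ...] = (SEX, EDUCATION, MATERNAL_BMI)
    inter: tuple[tuple[str, str], ...] = ()
    if conditional_on_mediator:
        covs = (MEDIATOR,) + covs
        inter = ((MEDIATOR, SEX), (MEDIATOR, MATERNAL_BMI))
    return FormulaSpec(
        response="outcome",
        covariates=covs,
        categorical=(EDUCATION,),
        polynomials=((MATERNAL_BMI, 2),),
        interactions=inter,
    )


def linear_formula(response: str, with_mediator: bool = False) -> FormulaSpec:
    """Plain main-effects formula (used for linear-truth analyses)."""
    covs: tuple[str, ...] = (SEX, EDUCATION, MATERNAL_BMI)
    if with_mediator:
        covs = (MEDIATOR,) + covs
    return FormulaSpec(response=response, covariates=covs)


# -- design construction ----------------------------------------------------


def _build_parts(
    spec: FormulaSpec,
    df: pd.DataFrame,
    levels: dict[str, tuple],
    mediator_var: str | None,
    exposure_level: int | None = None,
) -> list[tuple[str, int, np.ndarray]]:
    """Return design columns as ``(name, mediator_degree, base)`` triples.

    ``base`` excludes the ``M**degree`` factor; assembling the actual
    design multiplies it back in (or substitutes draw moments).
    When ``exposure_level`` is given, exposure dummies are constants for
    that level (counterfactual design); otherwise they come from the data.
    """
    n = len(df)
    parts: list[tuple[str, int, np.ndarray]] = [("Intercept", 0, np.ones(n))]

    def numeric(v: str) -> np.ndarray:
        return df[v].to_numpy(dtype=float)

    if spec.exposure is not None:
        for lev in levels[spec.exposure]:
            if lev == spec.reference:
                continue
            if exposure_level is not None:
                base = np.full(n, 1.0 if lev == exposure_level else 0.0)
            else:
                base = (df[spec.exposure].to_numpy() == lev).astype(float)
            parts.append((f"{spec.exposure}[{lev}]", 0, base))

    for v in spec.covariates:
        if v in spec.categorical:
            for lev in levels[v][1:]:
                parts.append(
                    (f"{v}[{lev}]", 0, (df[v].to_numpy() == lev).astype(float))
                )
        elif v == mediator_var:
            parts.append((v, 1, np.ones(n)))
        else:
            parts.append((v, 0, numeric(v)))

    for v, deg in spec.polynomials:
        for d in range(2, deg + 1):
            if v == mediator_var:
                parts.append((f"{v}^{d}", d, np.ones(n)))
            else:
                parts.append((f"{v}^{d}", 0, numeric(v) ** d))

    for a, b in spec.interactions:
        if spec.exposure is not None and spec.exposure in (a, b):
            other = b if a == spec.exposure else a
            deg = 1 if other == mediator_var else 0
            for lev in levels[spec.exposure]:
                if lev == spec.reference:
                    continue
                if exposure_level is not None:
                    dummy = np.full(n, 1.0 if lev == exposure_level else 0.0)
                else:
                    dummy = (df[spec.exposure].to_numpy() == lev).astype(float)
                base = dummy if deg == 1 else dummy * numeric(other)
                parts.append((f"{spec.exposure}[{lev}]:{other}", deg, base))
        elif mediator_var is not None and a == mediator_var and b == mediator_var:
            parts.append((f"{a}:{b}", 2, np.ones(n)))
        elif mediator_var is not None and a == mediator_var:
            parts.append((f"{a}:{b}", 1, numeric(b)))
        elif mediator_var is not None and b == mediator_var:
            parts.append((f"{a}:{b}", 1, numeric(a)))
        else:
            parts.append((f"{a}:{b}", 0, numeric(a) * numeric(b)))

    return parts


def _assemble(
    parts: list[tuple[str, int, np.ndarray]],
    mediator_values: np.ndarray | None = None,
    moments: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    cols = []
    for _, deg, base in parts:
        if deg == 0:
            cols.append(base)
        elif mediator_values is not None:
            cols.append(base * mediator_values**deg)
        elif moments is not None:
            cols.append(base * moments[deg])
        else:
            raise ValidationError(
                "design has mediator columns but no mediator values or "
                "moments were supplied"
            )
    return np.column_stack(cols)


# -- fitted model -----------------------------------------------------------


@dataclass
class FittedLinearModel:
    """A least-squares fit with homoscedastic Gaussian residuals.

    ``kind`` is one of ``"mediator"``, ``"outcome-conditional"`` or
    ``"outcome-marginal"``.  ``sigma`` is the residual standard deviation
    (``sqrt(SSR / (n - p))``), non-negative by construction.
    """

    spec: FormulaSpec
    kind: str
    params: np.ndarray
    names: list[str]
    bse: np.ndarray
    sigma: float
    n_used: int
    r2: float
    levels: dict[str, tuple]
    mediator_var: str | None
    resid: np.ndarray = field(repr=False)
    row_index: pd.Index = field(repr=False)

    # -- introspection ------------------------------------------------------

    @property
    def exposure_levels(self) -> tuple:
        if self.spec.exposure is None:
            return ()
        return self.levels[self.spec.exposure]

    @property
    def conditional_on_mediator(self) -> bool:
        return self.kind == "outcome-conditional"

    def coef(self, name: str) -> float:
        try:
            return float(self.params[self.names.index(name)])
        except ValueError:
            raise KeyError(f"no coefficient named {name!r}; have {self.names}")

    def coef_se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def exposure_coef(self, level: int) -> float:
        return self.coef(f"{self.spec.exposure}[{level}]")

    def exposure_coef_se(self, level: int) -> float:
        return self.coef_se(f"{self.spec.exposure}[{level}]")

    @property
    def max_mediator_degree(self) -> int:
        return max(
            (deg for _, deg, _ in self._parts_cache), default=0
        ) if self._parts_cache else 0

    # -- design helpers -----------------------------------------------------

    _parts_cache: list = field(default_factory=list, repr=False)

    def design_parts(
        self,
        df: pd.DataFrame,
        exposure_level: int | None = None,
        check: bool = True,
    ) -> list[tuple[str, int, np.ndarray]]:
        if check:
            self._check_inputs(df, need_exposure=exposure_level is None)
        return _build_parts(
            self.spec, df, self.levels, self.mediator_var, exposure_level
        )

    def mediator_degrees(self) -> tuple[int, ...]:
        """Mediator degree of each design column, in column order."""
        dummy = pd.DataFrame(
            {v: [0.0] for v in self.spec.variables()}
        )
        parts = _build_parts(self.spec, dummy, self.levels, self.mediator_var)
        return tuple(deg for _, deg, _ in parts)

    def poly_coefs(
        self,
        df: pd.DataFrame,
        exposure_level: int | None = None,
        check: bool = True,
    ) -> np.ndarray:
        """Per-row polynomial coefficients of the prediction in M.

        Returns an ``(n, dmax+1)`` array ``c`` with
        ``prediction_i(M) = sum_d c[i, d] * M**d``.
        """
        parts = self.design_parts(df, exposure_level, check=check)
        dmax = max(deg for _, deg, _ in parts)
        out = np.zeros((len(df), dmax + 1))
        for (name, deg, base), beta in zip(parts, self.params):
            out[:, deg] += beta * base
        return out

    def predict(
        self,
        df: pd.DataFrame,
        exposure_level: int | None = None,
        mediator: np.ndarray | float | None = None,
        check: bool = True,
    ) -> np.ndarray:
        """Model prediction, optionally at a counterfactual exposure level
        and/or overriding the mediator column."""
        parts = self.design_parts(df, exposure_level, check=check)
        if any(deg > 0 for _, deg, _ in parts):
            if mediator is None:
                if self.mediator_var not in df.columns:
                    raise ValidationError(
                        f"prediction requires mediator column "
                        f"{self.mediator_var!r} or an explicit override"
                    )
                mediator = df[self.mediator_var].to_numpy(dtype=float)
            mediator = np.broadcast_to(
                np.asarray(mediator, dtype=float), (len(df),)
            )
            X = _assemble(parts, mediator_values=mediator)
        else:
            X = _assemble(parts)
        return X @ self.params

    def _check_inputs(self, df: pd.DataFrame, need_exposure: bool) -> None:
        needed = [
            v
            for v in self.spec.rhs_variables()
            if not (v == self.spec.exposure and not need_exposure)
            and v != self.mediator_var
        ]
        for v in needed:
            if v not in df.columns:
                raise ValidationError(f"input table lacks column {v!r}")
            isna = df[v].isna()
            if isna.any():
                rows = list(df.index[isna][:5])
                raise ValidationError(
                    f"missing values in required variable {v!r} at rows "
                    f"{rows}{'...' if isna.sum() > 5 else ''}"
                )


# -- fitting ----------------------------------------------------------------


def _collinear_names(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in range(len(names)) if diag[i] <= tol]


def _fit(
    cohort: pd.DataFrame, spec: FormulaSpec, kind: str, mediator_var: str | None
) -> FittedLinearModel:
    vars_ = list(spec.variables())
    for v in vars_:
        if v not in cohort.columns:
            raise ValidationError(f"formula references unknown column {v!r}")
    cc = cohort.dropna(subset=vars_)

    def _canon(values) -> tuple:
        lev = sorted(pd.unique(values))
        if all(float(v).is_integer() for v in lev):
            return tuple(int(v) for v in lev)
        return tuple(lev)

    levels: dict[str, tuple] = {}
    if spec.exposure is not None:
        obs = _canon(cc[spec.exposure])
        if spec.reference not in obs:
            raise ValidationError(
                f"reference level {spec.reference} absent from "
                f"{spec.exposure} (observed {obs})"
            )
        levels[spec.exposure] = obs
    for v in spec.categorical:
        levels[v] = _canon(cc[v])

    parts = _build_parts(spec, cc, levels, mediator_var)
    names = [name for name, _, _ in parts]
    p = len(parts)
    if len(cc) < 10 * p:
        raise ValidationError(
            f"insufficient complete rows to fit {spec.response!r}: "
            f"{len(cc)} rows for {p} coefficients (need >= {10 * p})"
        )
    mvals = (
        cc[mediator_var].to_numpy(dtype=float)
        if mediator_var is not None and any(d > 0 for _, d, _ in parts)
        else None
    )
    X = _assemble(parts, mediator_values=mvals) if mvals is not None else _assemble(parts)
    y = cc[spec.response].to_numpy(dtype=float)
    # plain least squares (QR); deterministic, no stochastic fitting
    params, ssr, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        bad = _collinear_names(X, names)
        raise ValidationError(
            f"rank-deficient design for {spec.response!r}; collinear "
            f"terms: {bad or names}"
        )
    resid = y - X @ params
    df_resid = len(cc) - p
    scale = float(resid @ resid) / max(df_resid, 1)
    xtx_inv = np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.clip(np.diag(xtx_inv) * scale, 0.0, None))
    tss = float(np.sum((y - y.mean()) ** 2))
    model = FittedLinearModel(
        spec=spec,
        kind=kind,
        params=np.asarray(params, dtype=float),
        names=names,
        bse=bse,
        sigma=float(np.sqrt(max(scale, 0.0))),
        n_used=int(len(cc)),
        r2=1.0 - float(resid @ resid) / tss if tss > 0 else float("nan"),
        levels=levels,
        mediator_var=mediator_var,
        resid=resid,
        row_index=cc.index,
    )
    model._parts_cache = [(name, deg, None) for name, deg, _ in parts]
    return model


def fit_mediator_model(
    cohort: pd.DataFrame, spec: FormulaSpec | None = None
) -> FittedLinearModel:
    """Fit the mediator model f(M | X, C) on complete rows.

    Least squares with a homoscedastic Gaussian residual; records the
    number of rows used and R^2.
    """
    spec = spec or default_mediator_formula()
    if MEDIATOR in spec.rhs_variables():
        raise ValidationError("mediator model may not include the mediator "
                              "as a regressor")
    return _fit(cohort, spec, "mediator", mediator_var=None)


def fit_outcome_model(
    cohort: pd.DataFrame,
    spec: FormulaSpec | None = None,
    conditional_on_mediator: bool = True,
) -> FittedLinearModel:
    """Fit E(Y | X, M, C) (conditional) or E(Y | X, C) (marginal)."""
    spec = spec or default_outcome_formula(conditional_on_mediator)
    has_med = MEDIATOR in spec.rhs_variables()
    if conditional_on_mediator and not has_med:
        raise ValidationError(
            "conditional outcome model must include the mediator term"
        )
    if not conditional_on_mediator and has_med:
        raise ValidationError(
            "marginal outcome model may not contain a mediator term"
        )
    kind = "outcome-conditional" if conditional_on_mediator else "outcome-marginal"
    return _fit(cohort, spec, kind, mediator_var=MEDIATOR if has_med else None)


# -- stochastic mediator draws ----------------------------------------------


def truncated_normal_draws(
    rng: np.random.Generator,
    mu: np.ndarray,
    sigma: float,
    n_draws: int,
    truncate: bool,
    max_resample: int = 50,
) -> np.ndarray:
    """(n_rows, n_draws) Normal(mu_i, sigma) draws, optionally left-truncated
    at 0 by resampling (inverse-CDF fallback for stubborn cells)."""
    mu = np.asarray(mu, dtype=float)
    n = mu.shape[0]
    if sigma == 0.0:
        return np.tile(mu[:, None], (1, n_draws))
    draws = rng.standard_normal((n, n_draws))
    draws *= sigma
    draws += mu[:, None]
    if not truncate or draws.min() >= 0:
        return draws
    mu_grid = np.broadcast_to(mu[:, None], draws.shape)
    for _ in range(max_resample):
        neg = draws < 0
        if not neg.any():
            return draws
        k = int(neg.sum())
        draws[neg] = mu_grid[neg] + sigma * rng.standard_normal(k)
    neg = draws < 0
    if neg.any():
        # inverse-CDF truncated draw for cells where resampling is hopeless
        lo = special.ndtr(-mu_grid[neg] / sigma)
        u = lo + rng.random(int(neg.sum())) * (1.0 - lo)
        draws[neg] = mu_grid[neg] + sigma * special.ndtri(u)
    return draws


def draw_mediator(
    model: FittedLinearModel,
    covariate_rows: pd.DataFrame,
    exposure_level: int,
    n_draws: int,
    seed: int,
    truncate: bool = True,
) -> np.ndarray:
    """Draw from the fitted mediator distribution at a set exposure level.

    For each covariate row, ``n_draws`` independent values from
    ``Normal(mu(X=exposure_level, C=row), sigma)``, left-truncated at 0
    (minutes of activity cannot be negative) unless ``truncate`` is False.
    Deterministic given ``seed``.
    """
    if model.kind != "mediator":
        raise ValidationError("draw_mediator requires a fitted mediator model")
    if exposure_level not in model.exposure_levels:
        raise ValidationError(
            f"exposure level {exposure_level} outside fitted levels "
            f"{model.exposure_levels}"
        )
    mu = model.predict(covariate_rows, exposure_level=exposure_level)
    rng = np.random.default_rng(seed)
    return truncated_normal_draws(rng, mu, model.sigma, n_draws, truncate)


# -- quintile assignment ----------------------------------------------------


def assign_quintiles(values, n_groups: int = 5) -> pd.Series:
    """Cohort-specific quantile-group labels 1..n_groups (1 = lowest).

    Cut points are empirical quantiles of the non-missing values; a value
    equal to a cut point goes to the lower group, so labels are invariant
    to strictly monotone transforms.  Missing inputs get missing labels.
    """
    s = pd.Series(values)
    obs = s.dropna().to_numpy(dtype=float)
    if obs.size < n_groups:
        raise ValidationError(
            f"need at least {n_groups} non-missing values, got {obs.size}"
        )
    if np.all(obs == obs[0]):
        raise ValidationError(
            "all values identical: quantile groups are undefined"
        )
    qs = np.quantile(obs, np.arange(1, n_groups) / n_groups)
    labels = pd.Series(np.nan, index=s.index, dtype=float)
    v = s.to_numpy(dtype=float)
    ok = ~np.isnan(v)
    # strict inequality sends values equal to a cut point to the lower group
    labels[ok] = 1 + np.sum(v[ok][:, None] > qs[None, :], axis=1)
    return labels


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> float:
    """p-value of the two-sample Kolmogorov-Smirnov test (test helper)."""
    return float(stats.ks_2samp(np.ravel(a), np.ravel(b)).pvalue)
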