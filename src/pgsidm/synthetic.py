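"""Synthetic cohorts emulating a genomic-liability mediation study.

Generates per-participant records with the structure the analysis
assumes: a standard-normal polygenic score for BMI categorised into
cohort-specific quintiles (the exposure X), average daily minutes of
moderate-to-vigorous physical activity (the mediator M), BMI in kg/m^2
(the outcome Y) and three confounders C (child sex, ordinal maternal
education, continuous maternal pre-pregnancy BMI).  The default
calibration reproduces the qualitative pattern of the motivating
application: the score is negatively associated with activity and
positively with BMI, activity and BMI are negatively associated, and the
per-quintile activity shift grows from the second to the top quintile.

The structural equations are linear with optional interaction/quadratic
terms and an optional unobserved standard-normal confounder U acting on
both M and Y; U's induced residual correlation between the two equations
is available in closed form, which anchors the unmeasured-confounding
sensitivity analysis to formula-independent ground truth.

Because the generating model is known, the estimands have closed forms
on the linear subfamily (no interactions, no latent confounder, no
active truncation): Adj-TA_j = beta_j + gamma * alpha_j and
IDM-DE_j = beta_j.  :func:`closed_form_truth` returns these and refuses
parameter sets for which they are invalid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .core import (
    COHORT_COLUMNS,
    EDUCATION,
    EXPOSURE,
    MATERNAL_BMI,
    MEDIATOR,
    OUTCOME,
    PGS,
    SEX,
    DisparityEstimate,
    ValidationError,
)
from .models import assign_quintiles, truncated_normal_draws

__all__ = [
    "ConfounderSpec",
    "PGSSpec",
    "MediatorCoefs",
    "OutcomeCoefs",
    "LatentConfounder",
    "GeneratingParams",
    "MissingnessSpec",
    "default_params",
    "generate_cohort",
    "induce_missingness",
    "closed_form_truth",
    "latent_residual_correlation",
    "solve_latent_effect",
    "write_cohort",
    "read_cohort",
]


# -- parameter types --------------------------------------------------------


@dataclass(frozen=True)
class ConfounderSpec:
    sex_p: float = 0.5
    education_probs: tuple[float, ...] = (0.30, 0.45, 0.25)
    maternal_bmi_mean: float = 24.0
    maternal_bmi_sd: float = 4.0


@dataclass(frozen=True)
class PGSSpec:
    """Standard-normal score with optional confounder loadings.

    Loadings act on centred confounders; they are 0 by default so the
    score is exactly N(0, 1) and exogenous given C.
    """

    loading_sex: float = 0.0
    loading_education: float = 0.0
    loading_maternal_bmi: float = 0.0


@dataclass(frozen=True)
class MediatorCoefs:
    """M-equation: minutes/day of moderate-to-vigorous activity."""

    intercept: float = 52.0
    quintile_shifts: tuple[float, ...] = (0.0, -2.0, -4.0, -6.0, -9.0)
    sex: float = 8.0
    education: float = 2.0
    maternal_bmi: float = -0.3
    sex_x_maternal_bmi: float = 0.0
    sigma: float = 7.0


@dataclass(frozen=True)
class OutcomeCoefs:
    """Y-equation: BMI in kg/m^2; ``mediator`` is gamma (kg/m^2 per min/day)."""

    intercept: float = 17.3
    quintile_shifts: tuple[float, ...] = (0.0, 0.4, 0.9, 1.5, 2.55)
    mediator: float = -0.05
    sex: float = -0.4
    education: float = -0.2
    maternal_bmi: float = 0.15
    mediator_x_sex: float = 0.0
    maternal_bmi_sq: float = 0.0
    sigma: float = 2.5


@dataclass(frozen=True)
class LatentConfounder:
    """Unobserved U ~ N(0, 1) acting additively on M and Y."""

    on_mediator: float = 0.0
    on_outcome: float = 0.0


@dataclass(frozen=True)
class GeneratingParams:
    n: int = 5000
    confounders: ConfounderSpec = field(default_factory=ConfounderSpec)
    pgs: PGSSpec = field(default_factory=PGSSpec)
    mediator: MediatorCoefs = field(default_factory=MediatorCoefs)
    outcome: OutcomeCoefs = field(default_factory=OutcomeCoefs)
    latent: LatentConfounder = field(default_factory=LatentConfounder)
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
            raise ValidationError(f"n must be a positive integer, got {self.n!r}")
        c = self.confounders
        if not 0.0 <= c.sex_p <= 1.0:
            raise ValidationError(f"sex_p must lie in [0, 1], got {c.sex_p}")
        probs = np.asarray(c.education_probs, dtype=float)
        if probs.size < 2 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValidationError(
                "education_probs must be >= 2 non-negative probabilities "
                f"summing to 1, got {c.education_probs}"
            )
        if c.maternal_bmi_sd <= 0:
            raise ValidationError(
                f"maternal_bmi_sd must be > 0, got {c.maternal_bmi_sd}"
            )
        for label, coefs in ((MEDIATOR, self.mediator), (OUTCOME, self.outcome)):
            shifts = tuple(coefs.quintile_shifts)
            if len(shifts) != 5 or shifts[0] != 0.0:
                raise ValidationError(
                    f"{label} quintile_shifts must have 5 entries with the "
                    f"reference shift fixed at 0, got {shifts}"
                )
            if coefs.sigma < 0:
                raise ValidationError(
                    f"{label} sigma must be >= 0, got {coefs.sigma}"
                )


def default_params(n: int = 5000, seed: int = 0, **overrides) -> GeneratingParams:
    """Packaged calibration: top-quintile Adj-TA = 3.0 and difference
    gamma*alpha_5 = 0.45 kg/m^2, with differences increasing over quintiles."""
    return GeneratingParams(n=n, seed=seed, **overrides)


def linear_truth_params(n: int = 5000, seed: int = 0) -> GeneratingParams:
    """Defaults restricted to the linear subfamily (they already are)."""
    return default_params(n=n, seed=seed)


# -- closed-form helpers ----------------------------------------------------


def latent_residual_correlation(params: GeneratingParams) -> float:
    """Residual correlation between the M- and Y-equation errors induced
    by the latent confounder: a*b / (sqrt(a^2+s_M^2) * sqrt(b^2+s_Y^2))."""
    a, b = params.latent.on_mediator, params.latent.on_outcome
    sm_tot = np.hypot(a, params.mediator.sigma)
    sy_tot = np.hypot(b, params.outcome.sigma)
    if sm_tot == 0.0 or sy_tot == 0.0:
        return 0.0
    return float(a * b / (sm_tot * sy_tot))


def solve_latent_effect(
    effect_on_mediator: float,
    sigma_m: float,
    sigma_y: float,
    rho: float,
) -> float:
    """Outcome-side latent effect b giving residual correlation ``rho``
    for a fixed mediator-side effect a (closed-form inversion)."""
    a = effect_on_mediator
    A2 = a * a + sigma_m * sigma_m
    denom = a * a - rho * rho * A2
    if denom <= 0:
        raise ValidationError(
            f"|rho|={abs(rho):.3f} unattainable with a={a} and sigma_m={sigma_m}"
        )
    b = abs(rho) * np.sqrt(A2) * sigma_y / np.sqrt(denom)
    return float(np.sign(rho) * np.sign(a) * b)


def _education_mean(spec: ConfounderSpec) -> float:
    probs = np.asarray(spec.education_probs, dtype=float)
    return float(np.dot(np.arange(probs.size), probs))


def truncation_probabilities(params: GeneratingParams) -> tuple[float, float]:
    """Pre-truncation P(M < 0) and P(Y < 0) under the generating model.

    Exact over the discrete confounders and quintiles; maternal BMI and
    the residuals are folded into a single Gaussian (exact when the
    equations are linear, which is the regime where this check matters).
    """
    c = params.confounders
    med, out = params.mediator, params.outcome
    probs_e = np.asarray(c.education_probs, dtype=float)
    p_m = 0.0
    p_y = 0.0
    for j in range(5):
        for s in (0, 1):
            w_s = c.sex_p if s == 1 else 1.0 - c.sex_p
            for e, w_e in enumerate(probs_e):
                w = 0.2 * w_s * w_e
                slope_m = med.maternal_bmi + s * med.sex_x_maternal_bmi
                mu_m = (
                    med.intercept
                    + med.quintile_shifts[j]
                    + med.sex * s
                    + med.education * e
                    + slope_m * c.maternal_bmi_mean
                )
                var_m = (
                    (slope_m * c.maternal_bmi_sd) ** 2
                    + params.latent.on_mediator**2
                    + med.sigma**2
                )
                p_m += w * special.ndtr(-mu_m / max(np.sqrt(var_m), 1e-12))
                g = out.mediator + s * out.mediator_x_sex
                mu_y = (
                    out.intercept
                    + out.quintile_shifts[j]
                    + g * mu_m
                    + out.sex * s
                    + out.education * e
                    + out.maternal_bmi * c.maternal_bmi_mean
                    + out.maternal_bmi_sq
                    * (c.maternal_bmi_mean**2 + c.maternal_bmi_sd**2)
                )
                var_y = (
                    (out.maternal_bmi + g * slope_m) ** 2 * c.maternal_bmi_sd**2
                    + (g * med.sigma) ** 2
                    + (params.latent.on_outcome + g * params.latent.on_mediator) ** 2
                    + out.sigma**2
                )
                p_y += w * special.ndtr(-mu_y / max(np.sqrt(var_y), 1e-12))
    return float(p_m), float(p_y)


def closed_form_truth(params: GeneratingParams) -> DisparityEstimate:
    """Analytic Adj-TA_j, IDM-DE_j for the linear generating subfamily.

    Valid only when the generating equations are linear (no interaction or
    quadratic terms), the latent confounder is off, the score carries no
    confounder loadings, and left-truncation at 0 is negligible
    (P(M < 0) and P(Y < 0) both < 1e-6); otherwise refuses with an
    explanation rather than returning a silently wrong value.
    """
    params.validate()
    reasons = []
    if params.mediator.sex_x_maternal_bmi != 0.0:
        reasons.append("mediator equation has a sex x maternal-BMI interaction")
    if params.outcome.mediator_x_sex != 0.0:
        reasons.append("outcome equation has a mediator x sex interaction")
    if params.outcome.maternal_bmi_sq != 0.0:
        reasons.append("outcome equation has a quadratic maternal-BMI term")
    if params.latent.on_mediator != 0.0 or params.latent.on_outcome != 0.0:
        reasons.append("latent confounder active")
    if any(
        v != 0.0
        for v in (
            params.pgs.loading_sex,
            params.pgs.loading_education,
            params.pgs.loading_maternal_bmi,
        )
    ):
        reasons.append("polygenic score loads on confounders")
    p_m, p_y = truncation_probabilities(params)
    if p_m >= 1e-6 or p_y >= 1e-6:
        reasons.append(
            f"truncation non-negligible (P(M<0)={p_m:.2e}, P(Y<0)={p_y:.2e})"
        )
    if reasons:
        raise ValidationError(
            "closed-form estimands invalid for these params: "
            + "; ".join(reasons)
        )
    gamma = params.outcome.mediator
    alpha = params.mediator.quintile_shifts
    beta = params.outcome.quintile_shifts
    contrasts = range(2, 6)
    return DisparityEstimate(
        reference=1,
        adj_ta={j: beta[j - 1] + gamma * alpha[j - 1] for j in contrasts},
        idm_de={j: beta[j - 1] for j in contrasts},
        k=None,
        n=None,
        meta={"source": "closed_form"},
    )


# -- cohort generation ------------------------------------------------------


def generate_cohort(params: GeneratingParams) -> pd.DataFrame:
    """Simulate a fully observed cohort.

    Draw order (fixed, so cohorts are bit-identical given params + seed):
    confounders, latent U, polygenic score, mediator residuals (resampled
    where M would be negative), outcome residuals (resampled where Y
    would be non-positive).  Quintiles are empirical, cohort-specific.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n
    c = params.confounders

    sex = (rng.random(n) < c.sex_p).astype(float)
    edu_probs = np.asarray(c.education_probs, dtype=float)
    education = rng.choice(edu_probs.size, size=n, p=edu_probs).astype(float)
    maternal_bmi = c.maternal_bmi_mean + c.maternal_bmi_sd * rng.standard_normal(n)
    u = rng.standard_normal(n)

    g = params.pgs
    pgs = (
        rng.standard_normal(n)
        + g.loading_sex * (sex - c.sex_p)
        + g.loading_education * (education - _education_mean(c))
        + g.loading_maternal_bmi * (maternal_bmi - c.maternal_bmi_mean)
    )
    quintile = assign_quintiles(pgs).to_numpy()

    med = params.mediator
    alpha = np.asarray(med.quintile_shifts)[quintile.astype(int) - 1]
    mu_m = (
        med.intercept
        + alpha
        + med.sex * sex
        + med.education * education
        + (med.maternal_bmi + sex * med.sex_x_maternal_bmi) * maternal_bmi
        + params.latent.on_mediator * u
    )
    mediator = truncated_normal_draws(
        rng, mu_m, med.sigma, 1, truncate=True
    )[:, 0]

    out = params.outcome
    beta = np.asarray(out.quintile_shifts)[quintile.astype(int) - 1]
    mu_y = (
        out.intercept
        + beta
        + (out.mediator + out.mediator_x_sex * sex) * mediator
        + out.sex * sex
        + out.education * education
        + out.maternal_bmi * maternal_bmi
        + out.maternal_bmi_sq * maternal_bmi**2
        + params.latent.on_outcome * u
    )
    outcome = truncated_normal_draws(rng, mu_y, out.sigma, 1, truncate=True)[:, 0]

    return pd.DataFrame(
        {
            PGS: pgs,
            EXPOSURE: quintile,
            MEDIATOR: mediator,
            OUTCOME: outcome,
            SEX: sex,
            EDUCATION: education,
            MATERNAL_BMI: maternal_bmi,
        }
    )


# -- missingness ------------------------------------------------------------


@dataclass(frozen=True)
class TargetMissingness:
    """MAR mechanism for one variable: overall missing fraction plus logit
    slopes on fully observed predictors (the calibrated intercept hits the
    target fraction on average)."""

    fraction: float
    predictors: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class MissingnessSpec:
    targets: dict[str, TargetMissingness] = field(default_factory=dict)
    seed: int = 0


def default_missingness(
    fraction_mediator: float = 0.30,
    fraction_outcome: float = 0.15,
    seed: int = 0,
) -> MissingnessSpec:
    """MAR missingness concentrated in mediator and outcome, driven by the
    fully observed confounders (heavier where maternal BMI is higher and
    maternal education lower)."""
    return MissingnessSpec(
        targets={
            MEDIATOR: TargetMissingness(
                fraction=fraction_mediator,
                predictors={MATERNAL_BMI: 0.08, EDUCATION: -0.3},
            ),
            OUTCOME: TargetMissingness(
                fraction=fraction_outcome,
                predictors={MATERNAL_BMI: 0.05, EDUCATION: -0.2},
            ),
        },
        seed=seed,
    )


def induce_missingness(cohort: pd.DataFrame, spec: MissingnessSpec) -> pd.DataFrame:
    """Blank cells of the target variables under a MAR logistic mechanism.

    The per-variable intercept is calibrated on the data so the expected
    missing fraction equals the target; the realised fraction is then
    binomial around it.  Deterministic given ``spec.seed``.
    """
    out = cohort.copy()
    rng = np.random.default_rng(spec.seed)
    for var in sorted(spec.targets):
        t = spec.targets[var]
        if var not in cohort.columns:
            raise ValidationError(f"missingness target {var!r} not in cohort")
        if not 0.0 <= t.fraction < 1.0:
            raise ValidationError(
                f"missing fraction for {var!r} must lie in [0, 1), got {t.fraction}"
            )
        eta = np.zeros(len(cohort))
        for pred, slope in t.predictors.items():
            if pred in spec.targets:
                raise ValidationError(
                    f"predictor {pred!r} of missingness in {var!r} is itself a "
                    "missingness target; the mechanism would not be MAR"
                )
            if pred not in cohort.columns:
                raise ValidationError(f"missingness predictor {pred!r} not in cohort")
            if cohort[pred].isna().any():
                raise ValidationError(
                    f"missingness predictor {pred!r} must be fully observed"
                )
            eta += slope * cohort[pred].to_numpy(dtype=float)
        if t.fraction == 0.0:
            continue
        lo, hi = -40.0, 40.0
        c0 = optimize.brentq(
            lambda c: special.expit(c + eta).mean() - t.fraction, lo, hi
        )
        p = special.expit(c0 + eta)
        mask = rng.random(len(cohort)) < p
        out.loc[mask, var] = np.nan
    return out


# -- cohort I/O -------------------------------------------------------------


def write_cohort(
    cohort: pd.DataFrame, path, metadata: dict | None = None
) -> None:
    """Write the cohort CSV (missing cells as empty fields) plus a JSON
    sidecar ``<path>.meta.json`` recording seeds and provenance."""
    cohort.to_csv(path, index=False, columns=list(COHORT_COLUMNS))
    meta = dict(metadata or {})
    meta.setdefault("columns", list(COHORT_COLUMNS))
    meta.setdefault("n", int(len(cohort)))
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file lacks columns {missing}")
    return df


def params_to_dict(params: GeneratingParams) -> dict:
    return dataclasses.asdict(params)


def params_from_dict(d: dict) -> GeneratingParams:
    d = dict(d)

    def sub(cls, key):
        if key in d and isinstance(d[key], dict):
            kw = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d[key].items()
            }
            d[key] = cls(**kw)

    sub(ConfounderSpec, "confounders")
    sub(PGSSpec, "pgs")
    sub(MediatorCoefs, "mediator")
    sub(OutcomeCoefs, "outcome")
    sub(LatentConfounder, "latent")
    return GeneratingParams(**d)
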