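"""Plug-in g-computation of the two disparity estimands.

Adj-TA_j standardizes the exposure-outcome association over the
empirical confounder distribution of the analysis sample; IDM-DE_j is
the disparity that would remain under a hypothetical shift of the
mediator to its distribution in the reference (lowest-liability)
exposure group.  Both realise sums of the form
``sum_c E{. | X, C=c} Pr(C=c)`` as empirical means over analysis-sample
rows, which handles continuous confounders and reduces to the categorical
sum when C is discrete.

The IDM-DE Monte-Carlo integral follows the expanded-dataset recipe:
each analysis row is notionally replicated K times (K = 1000 by
default), a mediator value M* is drawn for each replicate from the
fitted mediator distribution at the reference exposure, the conditional
outcome model is evaluated at (X=j, M*, C) and (X=ref, M*, C) with the
*same* draws in both arms (common random numbers), and the arm
difference is averaged within and then across rows.  Because the
outcome models are polynomial in the mediator, the average of the K
replicate predictions equals the prediction evaluated at the empirical
draw moments; the implementation exploits that identity so K only costs
random-number generation, not K-fold design matrices.  The estimator,
its draws and its Monte-Carlo variance are identical to the literal
expansion (an explicit-expansion path is kept for verification).

A Gauss-Hermite quadrature oracle replaces the draws by deterministic
nodes over the untruncated Normal mediator law; it is exact for
polynomial integrands and serves as the independent check on the
Monte-Carlo integral.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special

from .core import EXPOSURE, DisparityEstimate, ValidationError
from .models import FittedLinearModel

__all__ = [
    "EstimandConfig",
    "ContrastEstimates",
    "estimate_adj_ta",
    "estimate_idm_de",
    "estimate_idm_de_binary",
    "numeric_oracle",
    "estimate_disparity",
]


@dataclass(frozen=True)
class EstimandConfig:
    """Estimation settings.

    k : Monte-Carlo expansion factor (draws per row), default 1000.
    reference : exposure reference level (1 = lowest liability).
    adj_ta_mode : 'marginal' fits/uses a separate Y ~ X + C model;
        'integrated' integrates the conditional outcome model over the
        fitted mediator law at each exposure level (internal-consistency
        mode).
    standardization : 'pooled' averages confounder rows over the whole
        analysis sample; 'stratified' restricts contrast j to the rows in
        exposure group j.
    truncate_draws : left-truncate mediator draws at 0 (minutes/day
        support); must be off for the quadrature oracle.
    """

    k: int = 1000
    reference: int = 1
    adj_ta_mode: str = "marginal"
    standardization: str = "pooled"
    truncate_draws: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"expansion factor k must be >= 1, got {self.k}")
        if self.adj_ta_mode not in ("marginal", "integrated"):
            raise ValidationError(f"unknown adj_ta_mode {self.adj_ta_mode!r}")
        if self.standardization not in ("pooled", "stratified"):
            raise ValidationError(
                f"unknown standardization {self.standardization!r}"
            )


@dataclass
class ContrastEstimates:
    """Per-contrast point values with optional Monte-Carlo / model SEs."""

    values: dict[int, float]
    mc_se: dict[int, float] | None = None
    se: dict[int, float] | None = None


# -- internals --------------------------------------------------------------


def _check_models(
    cohort: pd.DataFrame,
    mediator_model: FittedLinearModel,
    outcome_model: FittedLinearModel,
    config: EstimandConfig,
) -> tuple[tuple, list[int]]:
    if outcome_model.kind != "outcome-conditional":
        raise ValidationError(
            "IDM-DE requires the conditional outcome model E(Y | X, M, C)"
        )
    if mediator_model.kind != "mediator":
        raise ValidationError("a fitted mediator model is required")
    if mediator_model.spec.response != outcome_model.mediator_var:
        raise ValidationError(
            "model mismatch: mediator model response "
            f"{mediator_model.spec.response!r} != outcome model mediator "
            f"{outcome_model.mediator_var!r}"
        )
    m_lev = set(mediator_model.exposure_levels)
    o_lev = set(outcome_model.exposure_levels)
    if m_lev != o_lev:
        raise ValidationError(
            f"model mismatch: exposure levels differ ({sorted(m_lev)} vs "
            f"{sorted(o_lev)})"
        )
    levels = outcome_model.exposure_levels
    if config.reference not in levels:
        raise ValidationError(
            f"reference level {config.reference} not among fitted levels {levels}"
        )
    contrasts = [int(l) for l in levels if l != config.reference]
    return levels, contrasts


def _strat_masks(
    cohort: pd.DataFrame, contrasts: list[int], config: EstimandConfig
) -> dict[int, np.ndarray]:
    if config.standardization == "pooled":
        full = np.ones(len(cohort), dtype=bool)
        return {j: full for j in contrasts}
    x = cohort[EXPOSURE].to_numpy()
    masks = {j: x == j for j in contrasts}
    for j, m in masks.items():
        if not m.any():
            raise ValidationError(
                f"stratified standardization: no rows in exposure group {j}"
            )
    return masks


def _draw_moments(
    mu: np.ndarray,
    sigma: float,
    k: int,
    seed: int,
    truncate: bool,
    max_degree: int,
) -> dict[int, np.ndarray]:
    """Per-row empirical moments of K mediator draws, chunked over draws.

    This is the single source of mediator randomness for an IDM-DE
    evaluation: both contrast arms (and all contrasts) reuse the same
    draws, which is the common-random-numbers coupling.
    """
    from .models import truncated_normal_draws

    rng = np.random.default_rng(seed)
    n = len(mu)
    sums = {d: np.zeros(n) for d in range(1, max_degree + 1)}
    chunk = max(1, min(k, int(5_000_000 // max(n, 1)) or 1))
    done = 0
    while done < k:
        c = min(chunk, k - done)
        draws = truncated_normal_draws(rng, mu, sigma, c, truncate)
        for d in sums:
            if d == 1:
                sums[d] += draws.sum(axis=1)
            elif d == 2:
                sums[d] += np.einsum("ij,ij->i", draws, draws)
            else:
                sums[d] += (draws**d).sum(axis=1)
        done += c
    return {d: s / k for d, s in sums.items()}


def _gauss_hermite_moments(
    mu: np.ndarray, sigma: float, n_nodes: int, max_degree: int
) -> dict[int, np.ndarray]:
    """Moments of N(mu_i, sigma) by Gauss-Hermite quadrature (exact for
    polynomial degree < 2*n_nodes)."""
    x, w = special.roots_hermite(n_nodes)
    wt = w / np.sqrt(np.pi)
    nodes = mu[:, None] + np.sqrt(2.0) * sigma * x[None, :]
    return {d: (nodes**d) @ wt for d in range(1, max_degree + 1)}


def _level_coefs(
    outcome_model: FittedLinearModel,
    cohort: pd.DataFrame,
    levels,
) -> dict[int, np.ndarray]:
    """Per-row polynomial-in-M prediction coefficients, one array per
    counterfactual exposure level (inputs validated once)."""
    out: dict[int, np.ndarray] = {}
    for i, lev in enumerate(levels):
        out[int(lev)] = outcome_model.poly_coefs(
            cohort, exposure_level=int(lev), check=(i == 0)
        )
    return out


def _idm_from_moments(
    c: np.ndarray, moments: dict[int, np.ndarray], mask: np.ndarray, k: int
) -> tuple[float, float]:
    """Mean and MC standard error of the arm difference given per-row
    polynomial coefficients ``c`` and draw moments."""
    dmax = c.shape[1] - 1
    mean_i = c[:, 0].copy()
    for d in range(1, dmax + 1):
        mean_i += c[:, d] * moments[d]
    value = float(mean_i[mask].mean())
    # Var over draws of a degree-d polynomial needs moments up to 2d.
    var_i = np.zeros(len(mean_i))
    for d in range(1, dmax + 1):
        for e in range(1, dmax + 1):
            m_de = moments[d + e]
            var_i += c[:, d] * c[:, e] * (m_de - moments[d] * moments[e])
    var_i = np.clip(var_i, 0.0, None)
    n_rows = int(mask.sum())
    mc_se = float(np.sqrt(var_i[mask].sum() / k) / n_rows)
    return value, mc_se


# -- Adjusted Total Association --------------------------------------------


def estimate_adj_ta(
    cohort: pd.DataFrame,
    outcome_model: FittedLinearModel,
    config: EstimandConfig,
    mediator_model: FittedLinearModel | None = None,
) -> ContrastEstimates:
    """Adjusted Total Association per contrast.

    In the default marginal-regression mode the model must be the
    marginal fit E(Y | X, C): for each contrast j the estimate is the
    empirical mean over analysis rows of
    ``pred(X=j, C=c_i) - pred(X=ref, C=c_i)``.  In integrated mode the
    conditional model is integrated over the fitted mediator law at each
    exposure level (requires ``mediator_model``), with common random
    numbers across arms.
    """
    levels = outcome_model.exposure_levels
    if config.reference not in levels:
        raise ValidationError(
            f"reference level {config.reference} not among fitted levels {levels}"
        )
    contrasts = [int(l) for l in levels if l != config.reference]
    masks = _strat_masks(cohort, contrasts, config)

    if config.adj_ta_mode == "marginal":
        if outcome_model.kind != "outcome-marginal":
            raise ValidationError(
                "marginal Adj-TA mode requires the mediator-free outcome "
                "model (got a model containing a mediator term)"
            )
        values: dict[int, float] = {}
        se: dict[int, float] = {}
        pred_ref = outcome_model.predict(cohort, exposure_level=config.reference)
        for j in contrasts:
            diff = outcome_model.predict(
                cohort, exposure_level=j, check=False
            ) - pred_ref
            values[j] = float(diff[masks[j]].mean())
            # With exposure entering only through dummies the row-wise
            # difference is constant and equals the dummy coefficient, whose
            # SE is then the estimate's SE.
            if np.ptp(diff) < 1e-12:
                se[j] = outcome_model.exposure_coef_se(j)
        return ContrastEstimates(values=values, se=se or None)

    if mediator_model is None:
        raise ValidationError("integrated Adj-TA mode requires a mediator model")
    _check_models(cohort, mediator_model, outcome_model, config)
    dmax = max(outcome_model.mediator_degrees())
    sigma = mediator_model.sigma
    rng = np.random.default_rng(config.seed)
    n = len(cohort)
    mus = {
        int(l): mediator_model.predict(cohort, exposure_level=int(l))
        for l in levels
    }
    sums = {int(l): {d: np.zeros(n) for d in range(1, dmax + 1)} for l in levels}
    chunk = max(1, min(config.k, int(5_000_000 // max(n, 1)) or 1))
    done = 0
    from .models import truncated_normal_draws

    while done < config.k:
        c = min(chunk, config.k - done)
        z = rng.standard_normal((n, c))  # shared across arms (CRN)
        for l in levels:
            draws = mus[int(l)][:, None] + sigma * z
            if config.truncate_draws and (draws < 0).any():
                neg = draws < 0
                # per-arm resample of offending cells only
                sub_rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, int(l), done])
                )
                mu_grid = np.broadcast_to(mus[int(l)][:, None], draws.shape)
                repl = truncated_normal_draws(
                    sub_rng, mu_grid[neg], sigma, 1, True
                )[:, 0]
                draws[neg] = repl
            for d in range(1, dmax + 1):
                sums[int(l)][d] += (draws**d).sum(axis=1)
        done += c
    values = {}
    for j in contrasts:
        mj = {d: sums[j][d] / config.k for d in sums[j]}
        mref = {d: sums[config.reference][d] / config.k for d in sums[j]}
        cj = outcome_model.poly_coefs(cohort, exposure_level=j)
        cref = outcome_model.poly_coefs(cohort, exposure_level=config.reference)
        pred_j = cj[:, 0].copy()
        pred_r = cref[:, 0].copy()
        for d in range(1, cj.shape[1]):
            pred_j += cj[:, d] * mj[d]
            pred_r += cref[:, d] * mref[d]
        values[j] = float((pred_j - pred_r)[masks[j]].mean())
    return ContrastEstimates(values=values)


# -- IDM direct effect ------------------------------------------------------


def estimate_idm_de(
    cohort: pd.DataFrame,
    mediator_model: FittedLinearModel,
    outcome_model: FittedLinearModel,
    config: EstimandConfig,
) -> ContrastEstimates:
    """Interventional Disparity Measure - Direct Effect per contrast.

    Monte-Carlo standardization on the K-fold expanded dataset: mediator
    draws from the fitted law at the reference exposure, identical draws
    in both arms of every contrast, averaged within then across rows.
    Deterministic given ``config.seed``.
    """
    levels, contrasts = _check_models(cohort, mediator_model, outcome_model, config)
    masks = _strat_masks(cohort, contrasts, config)
    mu_ref = mediator_model.predict(cohort, exposure_level=config.reference)
    dmax = max(outcome_model.mediator_degrees())
    moments = _draw_moments(
        mu_ref,
        mediator_model.sigma,
        config.k,
        config.seed,
        config.truncate_draws,
        2 * dmax,
    )
    coefs = _level_coefs(outcome_model, cohort, levels)
    values: dict[int, float] = {}
    mc_se: dict[int, float] = {}
    for j in contrasts:
        c = coefs[j] - coefs[config.reference]
        values[j], mc_se[j] = _idm_from_moments(c, moments, masks[j], config.k)
    return ContrastEstimates(values=values, mc_se=mc_se)


def estimate_idm_de_expanded(
    cohort: pd.DataFrame,
    mediator_model: FittedLinearModel,
    outcome_model: FittedLinearModel,
    config: EstimandConfig,
) -> ContrastEstimates:
    """Literal K-fold expansion (verification path; identical estimator).

    Materialises the K replicate predictions per row instead of using the
    draw-moment identity.  Small inputs only.
    """
    from .models import truncated_normal_draws

    levels, contrasts = _check_models(cohort, mediator_model, outcome_model, config)
    masks = _strat_masks(cohort, contrasts, config)
    mu_ref = mediator_model.predict(cohort, exposure_level=config.reference)
    rng = np.random.default_rng(config.seed)
    draws = truncated_normal_draws(
        rng, mu_ref, mediator_model.sigma, config.k, config.truncate_draws
    )
    coefs = _level_coefs(outcome_model, cohort, levels)
    values: dict[int, float] = {}
    for j in contrasts:
        c = coefs[j] - coefs[config.reference]
        h = np.zeros_like(draws)
        for d in range(c.shape[1]):
            h += c[:, [d]] * draws**d
        values[j] = float(h.mean(axis=1)[masks[j]].mean())
    return ContrastEstimates(values=values)


def estimate_idm_de_binary(
    cohort: pd.DataFrame,
    mediator_model: FittedLinearModel,
    outcome_model: FittedLinearModel,
    config: EstimandConfig,
) -> ContrastEstimates:
    """IDM-DE for a binary exposure (single contrast, reference X=0)."""
    levels = set(outcome_model.exposure_levels)
    if not levels <= {0, 1} or len(levels) != 2:
        raise ValidationError(
            f"binary estimand requires exposure levels {{0, 1}}, got {sorted(levels)}"
        )
    cfg = replace(config, reference=0)
    return estimate_idm_de(cohort, mediator_model, outcome_model, cfg)


# -- quadrature oracle ------------------------------------------------------


def numeric_oracle(
    cohort: pd.DataFrame,
    mediator_model: FittedLinearModel,
    outcome_model: FittedLinearModel,
    config: EstimandConfig,
    n_nodes: int = 64,
) -> ContrastEstimates:
    """Deterministic IDM-DE via Gauss-Hermite quadrature.

    Replaces mediator draws by quadrature over the untruncated
    ``Normal(mu(ref, C), sigma)`` law; otherwise the standardization is
    identical to :func:`estimate_idm_de`.  Refuses when draw truncation
    is enabled, since the node grid assumes full support.
    """
    if config.truncate_draws:
        raise ValidationError(
            "quadrature oracle requires truncate_draws=False (the node grid "
            "assumes an untruncated Gaussian mediator law)"
        )
    levels, contrasts = _check_models(cohort, mediator_model, outcome_model, config)
    masks = _strat_masks(cohort, contrasts, config)
    mu_ref = mediator_model.predict(cohort, exposure_level=config.reference)
    dmax = max(outcome_model.mediator_degrees())
    moments = _gauss_hermite_moments(mu_ref, mediator_model.sigma, n_nodes, dmax)
    coefs = _level_coefs(outcome_model, cohort, levels)
    values: dict[int, float] = {}
    for j in contrasts:
        c = coefs[j] - coefs[config.reference]
        mean_i = c[:, 0].copy()
        for d in range(1, dmax + 1):
            mean_i += c[:, d] * moments[d]
        values[j] = float(mean_i[masks[j]].mean())
    return ContrastEstimates(values=values)


# -- joint estimate ---------------------------------------------------------


def estimate_disparity(
    cohort: pd.DataFrame,
    mediator_model: FittedLinearModel,
    outcome_model_conditional: FittedLinearModel,
    outcome_model_marginal: FittedLinearModel,
    config: EstimandConfig,
) -> DisparityEstimate:
    """Joint Adj-TA / IDM-DE estimate; the difference is exact by
    construction of :class:`DisparityEstimate`."""
    adj = estimate_adj_ta(cohort, outcome_model_marginal, config)
    idm = estimate_idm_de(
        cohort, mediator_model, outcome_model_conditional, config
    )
    return DisparityEstimate(
        reference=config.reference,
        adj_ta=adj.values,
        idm_de=idm.values,
        k=config.k,
        n=int(len(cohort)),
        adj_ta_se=adj.se,
        idm_de_mc_se=idm.mc_se,
    )
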