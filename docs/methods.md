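# Methods

## Setting and estimands

The package quantifies how much of the association between a categorised
polygenic score and a continuous health outcome could be removed by a
hypothetical intervention on a behavioural mediator.  The working
example is genomic liability for obesity: a BMI polygenic score (PGS)
split into cohort-specific quintiles X (1 = lowest liability, the
reference), average daily minutes of moderate-to-vigorous physical
activity M as the mediator, BMI (kg/m^2) in later childhood as the
outcome Y, and baseline confounders C (child sex, maternal education,
maternal pre-pregnancy BMI).

Because a polygenic score is not a manipulable exposure, the analysis
targets *interventional disparity measures* rather than causal effects
of X.  Two estimands are computed for each quintile j = 2..5 against the
reference:

- **Adjusted Total Association**:
  `Adj-TA_j = sum_c [E(Y | X=j, C=c) - E(Y | X=1, C=c)] Pr(C=c)` —
  the confounder-standardized disparity with no intervention on M.
- **Interventional Disparity Measure — Direct Effect**:
  `IDM-DE_j = sum_c [E{Y(M_C^1) | X=j, C=c} - E{Y(M_C^1) | X=1, C=c}] Pr(C=c)`,
  where `M_C^1` is a random draw from the mediator's conditional
  distribution given C at the reference exposure — the disparity that
  would remain if everyone's mediator distribution were shifted to that
  of the lowest-liability group.

Their difference `Adj-TA_j - IDM-DE_j` is the portion of the disparity
removable by the hypothetical mediator intervention.  Identification
requires no interference, consistency of the distributional
intervention, and no unmeasured mediator-outcome confounding; the last
is probed by the sensitivity analysis below.

## Plug-in estimation

Working models are fitted by least squares on complete cases (a row
enters a model if every variable in that model's formula is observed;
the pipeline uses the intersection over all three models):

- mediator model `f(M | X, C)`: Gaussian with homoscedastic residual SD,
- conditional outcome model `E(Y | X, M, C)`,
- marginal outcome model `E(Y | X, C)`.

The default formulas put the exposure in as dummies against quintile 1
and include a quadratic maternal-BMI term plus mediator-by-sex and
mediator-by-maternal-BMI interactions in the conditional outcome model;
everything is overridable through `FormulaSpec`, including
exposure-by-mediator interactions.  The standardization over Pr(C=c) is
realised as the empirical average over analysis-sample rows (pooled
across quintiles by default; per-stratum averaging is available), which
handles the continuous maternal-BMI confounder and reduces to the
categorical sum when C is discrete.

`Adj-TA_j` defaults to the marginal-regression mode — averaging
counterfactual predictions of the mediator-free model — because the
estimand conditions only on X and C.  An integrated mode (integrating
the conditional model over the fitted mediator law) is kept for
internal-consistency checks.

`IDM-DE_j` is a Monte-Carlo standardization on a K-fold expanded
dataset (K = 1000 by default): each analysis row is replicated K times,
a mediator value is drawn per replicate from
`Normal(mu(X=1, C), sigma_M)` left-truncated at zero, the conditional
outcome model is evaluated at `(X=j, M*, C)` and `(X=1, M*, C)` with the
*same* draws in both arms and all contrasts (common random numbers), and
arm differences are averaged within then across rows.

**Implementation note.** All supported outcome models are polynomial in
M per row, so the average of the K replicate predictions equals the
prediction evaluated at the empirical moments of the K draws.  The
implementation uses that identity: it generates the same K draws per row
but avoids materialising K-fold design matrices.  The estimator, its
draws, and its Monte-Carlo variance are bit-for-bit identical to the
literal expansion (`estimate_idm_de_expanded`, retained and tested as a
verification path).  A consequence of common random numbers worth
knowing: when the outcome model contains no exposure-by-mediator
interaction, the mediator terms cancel exactly between the two arms and
the IDM-DE integral has *zero* Monte-Carlo variance; MC noise appears
only when the mediator's coefficient differs across exposure levels.

A deterministic oracle (`numeric_oracle`) replaces the draws by 64-node
Gauss-Hermite quadrature over the untruncated Gaussian mediator law —
exact for polynomial integrands — and anchors the Monte-Carlo path in
tests and the sensitivity root-finder.

## Uncertainty

Percentile bootstrap, resampling participants with replacement (n out of
n; one participant per family, so no cluster structure).  Every
replicate reruns the whole pipeline: single stochastic imputation when
enabled (with a replicate-specific substream), re-derivation of the
cohort-specific quintile cut points (the exposure is defined by the
sample at hand), model fits, estimands.  Intervals are the 2.5th/97.5th
percentiles of the replicate distribution; replicates whose fits fail
(e.g. an empty quintile) are recorded and skipped, and more than 10%
failures aborts.  B = 1000 mirrors the applied analysis; simulations in
the test suite use B = 200.

## Missing data

The primary analysis is complete-case; the sensitivity analysis singly
imputes missing values by chained equations: initial fill from observed
marginals, then 10 burn-in cycles re-imputing each incomplete variable
from a conditional model on all other analysis variables (with optional
squared and interaction terms mirroring the analysis models), drawing
stochastically — normal residual draws for continuous variables
(respecting the mediator's non-negative support), logistic/multinomial
category draws for binary/ordinal ones.  Visit order is increasing
missingness fraction with alphabetical tie-break.  Observed cells are
never altered.  A single imputation suffices because uncertainty comes
from the bootstrap with the imputation redone on each replicate;
intervals for imputed analyses are therefore only reported through that
path.  Chain non-convergence is not monitored (fixed burn-in by
design), and predictive-mean matching is a known alternative draw
mechanism that is not implemented.

## Sensitivity to unmeasured mediator-outcome confounding

An omitted confounder of the M-Y relation would induce a correlation
rho between the errors of the mediator and outcome equations.  Under
linear models, positing rho determines the mediator coefficient that
controlling for the confounder would have produced:

    gamma(rho) = (s1/s2) * ( r12 - rho * sqrt((1 - r12^2) / (1 - rho^2)) )

with r12 the observed correlation between the residuals of `Y ~ X + C`
and `M ~ X + C` and s1, s2 their standard deviations.  At rho = 0 this
is exactly the OLS coefficient of M (Frisch–Waugh), so the adjusted
difference reproduces the unadjusted one; gamma crosses zero at
rho = r12.  Given gamma(rho), the remaining coefficients are refit under
the constraint (OLS of `Y - gamma(rho) M` on X + C) and IDM-DE is
recomputed with the quadrature integrator, so the reported crossing
point rho* — the minimal residual correlation that nullifies the
mediator's impact — is reproducible without any Monte-Carlo seed.  The
adjustment requires an outcome model linear in the mediator (single main
effect); richer models are refused rather than approximated.  The
formula's correctness is certified empirically: cohorts generated with a
latent confounder of known induced residual correlation (computable in
closed form from the generator parameters) must yield rho* within 0.03
of the truth.  rho* is reported for the top-quintile contrast by
default (the largest disparity); a bootstrap percentile interval re-runs
the whole procedure per resample.

## Synthetic cohorts

No public data exist for the motivating cohorts (both are
restricted-access), so the generator is a first-class module that
produces cohorts with the structure the analysis assumes:

- confounders: sex ~ Bernoulli(0.5); maternal education with three
  levels (0.30/0.45/0.25); maternal BMI ~ Normal(24, 4) kg/m^2;
- PGS ~ Normal(0, 1), optionally loading on centred confounders
  (0 by default), categorised into empirical quintiles (ties go to the
  lower quintile, making labels invariant to monotone transforms);
- mediator: `M = 52 + alpha_X + 8*sex + 2*edu - 0.3*matBMI + a*U + eps`,
  `alpha = (0, -2, -4, -6, -9)` min/day, residual SD 7, left-truncated
  at 0 by resampling (truncation probability ~2e-7 at the defaults, so
  the linear closed forms remain valid);
- outcome: `Y = 17.3 + beta_X + gamma*M - 0.4*sex - 0.2*edu
  + 0.15*matBMI + b*U + eps`, `beta = (0, 0.4, 0.9, 1.5, 2.55)` kg/m^2,
  `gamma = -0.05` kg/m^2 per min/day, residual SD 2.5;
- U ~ Normal(0, 1) is an optional latent mediator-outcome confounder
  (off by default) whose induced residual correlation
  `a*b / sqrt((a^2+sigma_M^2)(b^2+sigma_Y^2))` is available in closed
  form.

The calibration was chosen once so that the qualitative pattern of the
motivating application holds — PGS positively associated with BMI,
negatively with activity, activity negatively with BMI, top-quintile
total association near 3 kg/m^2 with a removable portion of
0.45 kg/m^2 increasing over quintiles, mean BMI ~19 kg/m^2 and mean
activity ~47 min/day — with activity levels high enough that support
truncation never distorts the linear oracle.  These constants are
package defaults for testing and demonstration, not estimates of any
real cohort.

On the linear subfamily (no interactions, no latent confounder, no
loadings, negligible truncation) the estimands have closed forms —
`Adj-TA_j = beta_j + gamma*alpha_j`, `IDM-DE_j = beta_j` — and
`closed_form_truth` refuses any parameter set outside that subfamily
instead of returning an invalid value.

MAR missingness is induced by logistic mechanisms on fully observed
variables, with the intercept calibrated to hit a target overall
fraction; a mechanism whose predictor is itself a missingness target is
rejected (it would be self-masking, not MAR).

What the generator does *not* emulate: genotype or LD structure (the
score is simulated directly), accelerometer measurement error and
time-series structure, selection into participation, sibling
relatedness, non-Gaussian mediator/outcome shapes, and intermediate
confounders on the M-Y path.  Passing tests therefore certify the
estimation machinery under the stated generating model, not robustness
of any substantive finding to real-data complications.

## Numerical choices and problem sizes

- Quintile ties: boundary values go to the lower quintile; group sizes
  differ by at most 1 under distinct values.
- Model fits: QR least squares; rank-deficient designs are refused with
  the collinear terms named; fits require at least 10 rows per
  coefficient.
- Mediator draws: truncation by resampling (inverse-CDF fallback after
  50 rounds); `truncate_draws=False` switches to the untruncated law for
  oracle-equivalence work.
- All randomness flows through integer seeds expanded via
  `numpy.random.SeedSequence` substreams, so every stage is reproducible
  and bootstrap replicate r's stream is derivable from the master seed.
- Root-finding for rho*: Brent's method on (-0.95, 0.95) to machine
  tolerance, verified to |difference| < 1e-6 kg/m^2; if the adjusted
  difference does not change sign the result is flagged "no crossing"
  rather than rooted.
- Simulation studies in the test suite run at reduced sizes chosen to
  keep the statistical checks sharp: coverage uses 200 cohorts of
  n = 2000 with K = 200 and B = 200; the imputation bias study uses 200
  replicates of n = 5000; parameter-recovery and pattern checks use
  n = 20000 with K = 300–500.  The acceptance script uses n = 20000,
  K = 500, B = 200.

## Known limitations

- The sensitivity adjustment covers outcome models linear in the
  mediator only; with mediator interactions the rho* machinery refuses
  (the estimands themselves are unaffected).
- Single-chain imputation has no convergence diagnostics.
- The percentile bootstrap can under-cover slightly at small n; coverage
  is verified empirically in the 90–98% band at n = 2000.
- Whether standardization should pool confounder rows across quintiles
  or stratify by exposure group is ambiguous in principle; both are
  implemented and pooled is the default, chosen for comparability of
  contrasts against a common reference population.
- Whether mediator draws should be truncated at zero is a judgment
  call; truncation is the default (the mediator is a non-negative
  measurement) and is switchable off, with the default calibration
  keeping the two numerically indistinguishable.
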