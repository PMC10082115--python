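"""Shared fixtures: linear-truth cohorts and fitted models.

Session-scoped fixtures cache the expensive cohorts; everything is
seeded, so the suite is fully deterministic.
"""

import pytest
from hypothesis import settings

import pgsidm as pk
from pgsidm.bootstrap import AnalysisSpec
from pgsidm.models import linear_formula

settings.register_profile("deterministic", derandomize=True, max_examples=25)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def linear_analysis() -> AnalysisSpec:
    """Main-effects-only analysis matching the linear generating model."""
    return AnalysisSpec(
        mediator_formula=linear_formula("mediator"),
        outcome_formula_conditional=linear_formula("outcome", with_mediator=True),
        outcome_formula_marginal=linear_formula("outcome"),
        estimand=pk.EstimandConfig(k=200),
    )


@pytest.fixture(scope="session")
def default_params_20k() -> pk.GeneratingParams:
    return pk.default_params(n=20000, seed=11)


@pytest.fixture(scope="session")
def cohort_20k(default_params_20k):
    return pk.generate_cohort(default_params_20k)


@pytest.fixture(scope="session")
def cohort_2k():
    return pk.generate_cohort(pk.default_params(n=2000, seed=7))


@pytest.fixture(scope="session")
def linear_models_20k(cohort_20k, linear_analysis):
    """(mediator, conditional-outcome, marginal-outcome) fits on the
    20k linear-truth cohort."""
    mm = pk.fit_mediator_model(cohort_20k, linear_analysis.mediator_formula)
    oc = pk.fit_outcome_model(
        cohort_20k, linear_analysis.outcome_formula_conditional, True
    )
    om = pk.fit_outcome_model(
        cohort_20k, linear_analysis.outcome_formula_marginal, False
    )
    return mm, oc, om
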