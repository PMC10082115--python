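"""g-computation estimands: oracles, invariances and error contracts."""

import copy
from dataclasses import replace

import numpy as np
import pytest

import pgsidm as pk
import pgsidm.estimands as est_mod
from pgsidm.core import (
    EXPOSURE,
    MATERNAL_BMI,
    MEDIATOR,
    OUTCOME,
    SEX,
    ValidationError,
)
from pgsidm.estimands import (
    EstimandConfig,
    estimate_adj_ta,
    estimate_disparity,
    estimate_idm_de,
    estimate_idm_de_binary,
    estimate_idm_de_expanded,
    numeric_oracle,
)
from pgsidm.models import FormulaSpec, linear_formula


def _zero_exposure(model):
    m = copy.deepcopy(model)
    for j in m.exposure_levels:
        if j != m.spec.reference:
            m.params[m.names.index(f"{EXPOSURE}[{j}]")] = 0.0
    return m


def _zero_mediator_terms(model):
    m = copy.deepcopy(model)
    for name, deg in zip(m.names, m.mediator_degrees()):
        if deg > 0:
            m.params[m.names.index(name)] = 0.0
    return m


@pytest.fixture(scope="module")
def interaction_outcome_20k(cohort_20k):
    """Conditional outcome fit with exposure-by-mediator and
    mediator-by-sex interactions.  The exposure-by-mediator terms keep the
    two standardization arms from cancelling, so the IDM-DE integral has
    genuine Monte-Carlo noise."""
    spec = FormulaSpec(
        response=OUTCOME,
        covariates=(MEDIATOR, SEX, "maternal_education", MATERNAL_BMI),
        interactions=((EXPOSURE, MEDIATOR), (MEDIATOR, SEX)),
    )
    return pk.fit_outcome_model(cohort_20k, spec, True)


class TestAdjTA:
    def test_zero_exposure_coefficients_give_zero(self, linear_models_20k, cohort_20k):
        _, _, om = linear_models_20k
        vals = estimate_adj_ta(cohort_20k, _zero_exposure(om), EstimandConfig())
        assert all(v == 0.0 for v in vals.values.values())

    def test_row_permutation_invariance(self, linear_models_20k, cohort_20k):
        _, _, om = linear_models_20k
        cfg = EstimandConfig()
        a = estimate_adj_ta(cohort_20k, om, cfg)
        shuffled = cohort_20k.sample(frac=1.0, random_state=3).reset_index(drop=True)
        b = estimate_adj_ta(shuffled, om, cfg)
        for j in a.values:
            assert a.values[j] == pytest.approx(b.values[j], abs=1e-12)

    def test_recovers_total_association_within_three_se(
        self, linear_models_20k, cohort_20k, default_params_20k
    ):
        _, _, om = linear_models_20k
        truth = pk.closed_form_truth(default_params_20k)
        res = estimate_adj_ta(cohort_20k, om, EstimandConfig())
        for j in res.values:
            assert res.values[j] == pytest.approx(
                truth.adj_ta[j], abs=3 * res.se[j]
            )

    def test_marginal_mode_rejects_mediator_model(self, linear_models_20k, cohort_20k):
        _, oc, _ = linear_models_20k
        with pytest.raises(ValidationError, match="marginal"):
            estimate_adj_ta(cohort_20k, oc, EstimandConfig())

    def test_integrated_mode_agrees_with_marginal_under_linear_truth(
        self, linear_models_20k, cohort_20k
    ):
        mm, oc, om = linear_models_20k
        cfg = EstimandConfig(k=300, seed=5)
        marg = estimate_adj_ta(cohort_20k, om, cfg)
        integ = estimate_adj_ta(
            cohort_20k, oc, replace(cfg, adj_ta_mode="integrated"),
            mediator_model=mm,
        )
        for j in marg.values:
            assert integ.values[j] == pytest.approx(
                marg.values[j], abs=3 * marg.se[j]
            )


class TestIdmDe:
    def test_matches_closed_form_within_three_se(
        self, linear_models_20k, cohort_20k, default_params_20k
    ):
        mm, oc, _ = linear_models_20k
        truth = pk.closed_form_truth(default_params_20k)
        res = estimate_idm_de(cohort_20k, mm, oc, EstimandConfig(k=300, seed=2))
        for j in res.values:
            se = np.hypot(oc.exposure_coef_se(j), res.mc_se[j])
            assert res.values[j] == pytest.approx(truth.idm_de[j], abs=3 * se)

    def test_zero_mediator_coefficients_collapse_to_integrated_adj_ta(
        self, linear_models_20k, cohort_20k
    ):
        mm, oc, _ = linear_models_20k
        oc0 = _zero_mediator_terms(oc)
        cfg = EstimandConfig(k=50, seed=9)
        idm = estimate_idm_de(cohort_20k, mm, oc0, cfg)
        adj = estimate_adj_ta(
            cohort_20k, oc0, replace(cfg, adj_ta_mode="integrated"),
            mediator_model=mm,
        )
        for j in idm.values:
            assert idm.values[j] == pytest.approx(adj.values[j], abs=1e-12)

    def test_moment_path_equals_literal_expansion(
        self, linear_models_20k, cohort_20k, interaction_outcome_20k
    ):
        # same seed, same draws: the draw-moment identity is exact
        mm, _, _ = linear_models_20k
        small = cohort_20k.head(400)
        cfg = EstimandConfig(k=60, seed=13)
        a = estimate_idm_de(small, mm, interaction_outcome_20k, cfg)
        b = estimate_idm_de_expanded(small, mm, interaction_outcome_20k, cfg)
        for j in a.values:
            assert a.values[j] == pytest.approx(b.values[j], abs=1e-10)

    def test_single_draw_stream_shared_across_arms_and_contrasts(
        self, linear_models_20k, cohort_20k, monkeypatch
    ):
        mm, oc, _ = linear_models_20k
        calls = []
        original = est_mod._draw_moments

        def counting(*args, **kwargs):
            calls.append(1)
            return original(*args, **kwargs)

        monkeypatch.setattr(est_mod, "_draw_moments", counting)
        estimate_idm_de(cohort_20k.head(200), mm, oc, EstimandConfig(k=20, seed=1))
        assert len(calls) == 1  # one stream for all 4 contrasts x 2 arms

    def test_mc_dispersion_scales_inversely_with_k(
        self, cohort_20k, interaction_outcome_20k, linear_models_20k
    ):
        mm, _, _ = linear_models_20k
        small = cohort_20k.head(200)
        reps = 40
        k_small, k_big = 1, 64

        def sweep(k):
            return [
                estimate_idm_de(
                    small, mm, interaction_outcome_20k,
                    EstimandConfig(k=k, seed=s),
                ).values[5]
                for s in range(reps)
            ]

        v1 = np.var(sweep(k_small))
        v2 = np.var(sweep(k_big))
        ratio = v1 / v2
        assert k_big / 3 < ratio < k_big * 3

    def test_difference_identity_exact(self, linear_models_20k, cohort_20k):
        mm, oc, om = linear_models_20k
        cfg = EstimandConfig(k=40, seed=4)
        joint = estimate_disparity(cohort_20k, mm, oc, om, cfg)
        adj = estimate_adj_ta(cohort_20k, om, cfg)
        idm = estimate_idm_de(cohort_20k, mm, oc, cfg)
        for j in joint.contrasts:
            assert joint.difference[j] == adj.values[j] - idm.values[j]

    def test_null_mediator_shift_preserves_null_difference(self):
        # no X -> M path: difference_j should be indistinguishable from 0
        from pgsidm.synthetic import MediatorCoefs

        p = pk.default_params(
            n=10000, seed=19,
            mediator=replace(MediatorCoefs(), quintile_shifts=(0.0,) * 5),
        )
        co = pk.generate_cohort(p)
        mm = pk.fit_mediator_model(co, linear_formula(MEDIATOR))
        oc = pk.fit_outcome_model(co, linear_formula(OUTCOME, True), True)
        om = pk.fit_outcome_model(co, linear_formula(OUTCOME), False)
        res = estimate_disparity(co, mm, oc, om, EstimandConfig(k=200, seed=3))
        for j in res.contrasts:
            se = np.hypot(om.exposure_coef_se(j), oc.exposure_coef_se(j))
            assert abs(res.difference[j]) < 3 * se

    def test_model_mismatch_detected(self, linear_models_20k, cohort_20k):
        mm, oc, _ = linear_models_20k
        sub = cohort_20k[cohort_20k[EXPOSURE] <= 4]
        mm_sub = pk.fit_mediator_model(sub, linear_formula(MEDIATOR))
        with pytest.raises(ValidationError, match="levels"):
            estimate_idm_de(cohort_20k, mm_sub, oc, EstimandConfig(k=5))

    def test_invalid_expansion_factor_rejected(self):
        with pytest.raises(ValidationError, match="k"):
            EstimandConfig(k=0)


@pytest.fixture(scope="module")
def binary_setup(cohort_20k):
    sub = cohort_20k[cohort_20k[EXPOSURE].isin([1, 5])].copy()
    sub[EXPOSURE] = (sub[EXPOSURE] == 5).astype(int)
    spec_m = replace(linear_formula(MEDIATOR), reference=0)
    spec_o = replace(linear_formula(OUTCOME, True), reference=0)
    mm = pk.fit_mediator_model(sub, spec_m)
    oc = pk.fit_outcome_model(sub, spec_o, True)
    return sub, mm, oc


class TestBinaryExposure:
    def test_collapsed_top_contrast_matches_five_level_run(
        self, binary_setup, linear_models_20k, cohort_20k
    ):
        sub, mm_b, oc_b = binary_setup
        res_b = estimate_idm_de_binary(
            sub, mm_b, oc_b, EstimandConfig(k=200, seed=6)
        )
        mm, oc, _ = linear_models_20k
        res_5 = estimate_idm_de(cohort_20k, mm, oc, EstimandConfig(k=200, seed=6))
        se = np.hypot(oc.exposure_coef_se(5), oc_b.exposure_coef_se(1))
        assert res_b.values[1] == pytest.approx(res_5.values[5], abs=3 * se)

    def test_zero_coefficient_model_gives_zero(self, binary_setup):
        sub, mm_b, oc_b = binary_setup
        oc0 = _zero_exposure(_zero_mediator_terms(oc_b))
        res = estimate_idm_de_binary(sub, mm_b, oc0, EstimandConfig(k=20, seed=1))
        assert res.values[1] == pytest.approx(0.0, abs=1e-12)

    def test_non_binary_exposure_rejected(self, linear_models_20k, cohort_20k):
        mm, oc, _ = linear_models_20k
        with pytest.raises(ValidationError, match="binary"):
            estimate_idm_de_binary(cohort_20k, mm, oc, EstimandConfig(k=5))

    def test_label_swap_flips_contrast_sign_in_linear_model(self, binary_setup):
        sub, _, _ = binary_setup
        swapped = sub.copy()
        swapped[EXPOSURE] = 1 - swapped[EXPOSURE]
        spec_m = replace(linear_formula(MEDIATOR), reference=0)
        spec_o = replace(linear_formula(OUTCOME, True), reference=0)
        mm_s = pk.fit_mediator_model(swapped, spec_m)
        oc_s = pk.fit_outcome_model(swapped, spec_o, True)
        res_s = estimate_idm_de_binary(
            swapped, mm_s, oc_s, EstimandConfig(k=100, seed=2, truncate_draws=False)
        )
        mm_b = pk.fit_mediator_model(sub, spec_m)
        oc_b = pk.fit_outcome_model(sub, spec_o, True)
        res = estimate_idm_de_binary(
            sub, mm_b, oc_b, EstimandConfig(k=100, seed=2, truncate_draws=False)
        )
        # linear in M with no interactions: the contrast is the exposure
        # coefficient, which exactly changes sign under a label swap
        assert res_s.values[1] == pytest.approx(-res.values[1], abs=1e-10)


class TestNumericOracle:
    def test_linear_model_quadrature_equals_plugin_closed_form(
        self, linear_models_20k, cohort_20k
    ):
        mm, oc, _ = linear_models_20k
        cfg = EstimandConfig(k=10, truncate_draws=False)
        q = numeric_oracle(cohort_20k, mm, oc, cfg)
        for j in q.values:
            # with a linear conditional model the mediator cancels between
            # arms and IDM-DE_j reduces to the fitted exposure coefficient
            assert q.values[j] == pytest.approx(
                oc.exposure_coef(j), rel=1e-10
            )

    def test_quadratic_mediator_term_integrates_exactly(self, cohort_20k):
        spec = FormulaSpec(
            response=OUTCOME,
            covariates=(MEDIATOR, SEX, "maternal_education", MATERNAL_BMI),
            polynomials=((MEDIATOR, 2),),
        )
        oc = pk.fit_outcome_model(cohort_20k, spec, True)
        mm = pk.fit_mediator_model(cohort_20k, linear_formula(MEDIATOR))
        cfg = EstimandConfig(truncate_draws=False)
        q = numeric_oracle(cohort_20k, mm, oc, cfg)
        # symbolic expectation: E[M] = mu, E[M^2] = mu^2 + sigma^2
        mu = mm.predict(cohort_20k, exposure_level=1)
        moments = {1: mu, 2: mu**2 + mm.sigma**2}
        for j in q.values:
            c = oc.poly_coefs(cohort_20k, exposure_level=j) - oc.poly_coefs(
                cohort_20k, exposure_level=1
            )
            expected = (
                c[:, 0] + c[:, 1] * moments[1] + c[:, 2] * moments[2]
            ).mean()
            assert q.values[j] == pytest.approx(expected, rel=1e-10)

    def test_monte_carlo_agrees_with_quadrature(
        self, cohort_20k, interaction_outcome_20k, linear_models_20k
    ):
        mm, _, _ = linear_models_20k
        small = cohort_20k.head(500)
        cfg = EstimandConfig(k=2000, seed=10, truncate_draws=False)
        mc = estimate_idm_de(small, mm, interaction_outcome_20k, cfg)
        q = numeric_oracle(small, mm, interaction_outcome_20k, cfg)
        for j in q.values:
            assert mc.values[j] == pytest.approx(
                q.values[j], abs=max(3 * mc.mc_se[j], 1e-12)
            )

    def test_refuses_truncated_draw_config(self, linear_models_20k, cohort_20k):
        mm, oc, _ = linear_models_20k
        with pytest.raises(ValidationError, match="truncate"):
            numeric_oracle(cohort_20k, mm, oc, EstimandConfig())
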