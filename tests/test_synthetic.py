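"""Generator: structure, calibration, missingness and analytic truth."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import pgsidm as pk
from pgsidm.core import (
    EXPOSURE,
    MATERNAL_BMI,
    MEDIATOR,
    OUTCOME,
    PGS,
    SEX,
    ValidationError,
)
from pgsidm.synthetic import (
    MediatorCoefs,
    MissingnessSpec,
    OutcomeCoefs,
    TargetMissingness,
    truncation_probabilities,
)


def _expected_mediator_mean(params, j):
    """Closed-form mean of the M-equation in quintile j (oracle)."""
    c, m = params.confounders, params.mediator
    edu_mean = float(
        np.dot(np.arange(len(c.education_probs)), c.education_probs)
    )
    return (
        m.intercept
        + m.quintile_shifts[j - 1]
        + m.sex * c.sex_p
        + m.education * edu_mean
        + m.maternal_bmi * c.maternal_bmi_mean
    )


class TestGenerateCohort:
    def test_seed_determinism(self):
        p = pk.default_params(n=2000, seed=5)
        a, b = pk.generate_cohort(p), pk.generate_cohort(p)
        pd.testing.assert_frame_equal(a, b)
        c = pk.generate_cohort(replace(p, seed=6))
        assert not a[PGS].equals(c[PGS])

    def test_degenerate_noiseless_cohort_is_constant(self):
        p = pk.default_params(
            n=200,
            mediator=MediatorCoefs(
                intercept=30.0, quintile_shifts=(0.0,) * 5, sex=0.0,
                education=0.0, maternal_bmi=0.0, sigma=0.0,
            ),
            outcome=OutcomeCoefs(
                intercept=18.0, quintile_shifts=(0.0,) * 5, mediator=0.0,
                sex=0.0, education=0.0, maternal_bmi=0.0, sigma=0.0,
            ),
        )
        co = pk.generate_cohort(p)
        assert (co[MEDIATOR] == 30.0).all()
        assert (co[OUTCOME] == 18.0).all()

    def test_association_signs_match_study_pattern(self, cohort_20k):
        corr = cohort_20k[[PGS, MEDIATOR, OUTCOME]].corr()
        assert corr.loc[PGS, OUTCOME] > 0
        assert corr.loc[PGS, MEDIATOR] < 0
        assert corr.loc[MEDIATOR, OUTCOME] < 0

    def test_quintile_sizes_balanced_and_support_respected(self, cohort_20k):
        sizes = cohort_20k[EXPOSURE].value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert (cohort_20k[MEDIATOR] >= 0).all()
        assert (cohort_20k[OUTCOME] > 0).all()

    def test_per_quintile_mediator_means_match_structural_oracle(self):
        p = pk.default_params(n=10000, seed=21)
        co = pk.generate_cohort(p)
        means = co.groupby(EXPOSURE)[MEDIATOR].mean()
        assert means.is_monotonic_decreasing
        n_q = len(co) / 5
        # total SD of M around its quintile mean (confounders + residual)
        sd = np.sqrt(
            p.mediator.sigma**2
            + (p.mediator.maternal_bmi * p.confounders.maternal_bmi_sd) ** 2
            + p.mediator.sex**2 * 0.25
            + p.mediator.education**2
        )
        for j in (1, 2, 3, 4, 5):
            assert means[j] == pytest.approx(
                _expected_mediator_mean(p, j), abs=3 * sd / np.sqrt(n_q)
            )

    def test_marginal_moments_within_three_se(self):
        p = pk.default_params(n=10000, seed=31)
        co = pk.generate_cohort(p)
        c = p.confounders
        assert co[SEX].mean() == pytest.approx(
            c.sex_p, abs=3 * 0.5 / np.sqrt(len(co))
        )
        assert co[MATERNAL_BMI].mean() == pytest.approx(
            c.maternal_bmi_mean, abs=3 * c.maternal_bmi_sd / np.sqrt(len(co))
        )
        assert co[MATERNAL_BMI].std() == pytest.approx(
            c.maternal_bmi_sd, rel=0.05
        )
        assert co[PGS].std() == pytest.approx(1.0, rel=0.05)

    @pytest.mark.parametrize(
        "bad, msg",
        [
            (dict(n=0), "n"),
            (
                dict(confounders=pk.ConfounderSpec(maternal_bmi_sd=-1.0)),
                "maternal_bmi_sd",
            ),
            (dict(mediator=MediatorCoefs(sigma=-2.0)), "sigma"),
            (
                dict(mediator=MediatorCoefs(quintile_shifts=(1.0, 0, 0, 0, 0))),
                "quintile_shifts",
            ),
        ],
    )
    def test_validation_errors_name_the_field(self, bad, msg):
        with pytest.raises(ValidationError, match=msg):
            pk.generate_cohort(pk.default_params(**bad))


class TestLatentConfounder:
    def test_induced_residual_correlation_calibrates(self):
        base = pk.default_params(n=10000, seed=41)
        b = pk.solve_latent_effect(3.0, base.mediator.sigma, base.outcome.sigma, -0.15)
        p = replace(
            base,
            outcome=replace(base.outcome, mediator=0.0),
            latent=pk.LatentConfounder(on_mediator=3.0, on_outcome=b),
        )
        assert pk.latent_residual_correlation(p) == pytest.approx(-0.15, abs=1e-12)
        co = pk.generate_cohort(p)
        # residuals of M and Y on (X, C) expose the U-induced correlation
        mm = pk.fit_mediator_model(co, pk.linear_formula(MEDIATOR))
        om = pk.fit_outcome_model(co, pk.linear_formula(OUTCOME), False)
        r = np.corrcoef(mm.resid, om.resid)[0, 1]
        assert r == pytest.approx(-0.15, abs=0.02)


class TestClosedFormTruth:
    def test_linear_truth_values(self):
        p = pk.default_params()
        t = pk.closed_form_truth(p)
        gamma = p.outcome.mediator
        for j in (2, 3, 4, 5):
            assert t.idm_de[j] == p.outcome.quintile_shifts[j - 1]
            assert t.adj_ta[j] == pytest.approx(
                p.outcome.quintile_shifts[j - 1]
                + gamma * p.mediator.quintile_shifts[j - 1]
            )
        assert t.difference[5] == pytest.approx(0.45)

    def test_no_mediator_pathway_collapses_estimands(self):
        p = pk.default_params(outcome=replace(pk.OutcomeCoefs(), mediator=0.0))
        t = pk.closed_form_truth(p)
        assert t.adj_ta == t.idm_de
        p2 = pk.default_params(
            mediator=replace(pk.MediatorCoefs(), quintile_shifts=(0.0,) * 5)
        )
        t2 = pk.closed_form_truth(p2)
        assert all(d == pytest.approx(0.0) for d in t2.difference.values())

    @pytest.mark.parametrize(
        "bad, msg",
        [
            (
                dict(outcome=replace(pk.OutcomeCoefs(), mediator_x_sex=0.1)),
                "interaction",
            ),
            (
                dict(latent=pk.LatentConfounder(on_mediator=1.0, on_outcome=1.0)),
                "latent",
            ),
            (
                dict(mediator=replace(pk.MediatorCoefs(), sigma=30.0)),
                "truncation",
            ),
        ],
    )
    def test_refuses_outside_linear_subfamily(self, bad, msg):
        with pytest.raises(ValidationError, match=msg):
            pk.closed_form_truth(pk.default_params(**bad))

    def test_truncation_probability_negligible_at_default_calibration(self):
        p_m, p_y = truncation_probabilities(pk.default_params())
        assert p_m < 1e-6 and p_y < 1e-6


class TestMissingness:
    def test_zero_fraction_is_identity(self, cohort_2k):
        spec = MissingnessSpec(
            targets={MEDIATOR: TargetMissingness(fraction=0.0)}, seed=1
        )
        out = pk.induce_missingness(cohort_2k, spec)
        pd.testing.assert_frame_equal(out, cohort_2k)

    def test_target_fraction_achieved_within_binomial_bounds(self):
        co = pk.generate_cohort(pk.default_params(n=5000, seed=3))
        spec = MissingnessSpec(
            targets={
                MEDIATOR: TargetMissingness(
                    fraction=0.30, predictors={MATERNAL_BMI: 0.08}
                )
            },
            seed=4,
        )
        out = pk.induce_missingness(co, spec)
        assert 3350 <= out[MEDIATOR].notna().sum() <= 3650
        # non-target cells untouched
        pd.testing.assert_series_equal(out[OUTCOME], co[OUTCOME])
        pd.testing.assert_frame_equal(
            pk.induce_missingness(co, spec), out
        )  # deterministic

    def test_mar_mechanism_shifts_predictor_distribution(self, cohort_2k):
        spec = MissingnessSpec(
            targets={
                MEDIATOR: TargetMissingness(
                    fraction=0.35, predictors={MATERNAL_BMI: 0.25}
                )
            },
            seed=5,
        )
        out = pk.induce_missingness(cohort_2k, spec)
        miss = out[MEDIATOR].isna()
        assert (
            out.loc[miss, MATERNAL_BMI].mean()
            > out.loc[~miss, MATERNAL_BMI].mean()
        )

    def test_self_masking_predictor_rejected(self, cohort_2k):
        spec = MissingnessSpec(
            targets={
                MEDIATOR: TargetMissingness(
                    fraction=0.2, predictors={OUTCOME: 0.1}
                ),
                OUTCOME: TargetMissingness(fraction=0.1),
            },
            seed=1,
        )
        with pytest.raises(ValidationError, match="MAR"):
            pk.induce_missingness(cohort_2k, spec)


class TestCohortIO:
    def test_csv_round_trip_preserves_missing_cells(self, tmp_path, cohort_2k):
        co = pk.induce_missingness(cohort_2k, pk.default_missingness(seed=2))
        path = tmp_path / "cohort.csv"
        pk.write_cohort(co, path, metadata={"seed": 2})
        back = pk.read_cohort(path)
        assert back[MEDIATOR].isna().sum() == co[MEDIATOR].isna().sum()
        np.testing.assert_allclose(back[PGS], co[PGS], rtol=1e-12)
        assert (path.parent / "cohort.csv.meta.json").exists()

    def test_params_dict_round_trip(self):
        p = pk.default_params(n=123, seed=9)
        from pgsidm.synthetic import params_from_dict, params_to_dict

        assert params_from_dict(params_to_dict(p)) == p
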