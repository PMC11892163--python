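"""Effect combination, proportion mediated and end-to-end point estimation."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import survmediate as sm
from survmediate.errors import (EstimationError, InputError,
                                UndefinedProportionWarning)
from survmediate.mediation import (fits_from_structural,
                                   structural_covariate_setting)


@pytest.fixture(scope="module")
def structural_fits():
    params = sm.default_params("female")
    outcome_fit, mediator_fit = fits_from_structural(params)
    spec = sm.MediationSpec("sae_lifetime", params.mediator_name,
                            params.outcome_name)
    c = structural_covariate_setting(params, "weighted_mean")
    return params, outcome_fit, mediator_fit, spec, c


class TestCombineEffects:
    def test_nie_is_one_when_mediator_unmoved(self, structural_fits):
        params, ofit, mfit, spec, c = structural_fits
        mfit.coefficients["sae_lifetime"] = 0.0
        try:
            nde, nie, te = sm.combine_effects(ofit, mfit, spec, c)
        finally:
            mfit.coefficients["sae_lifetime"] = \
                params.mediator_model.exposure
        assert nie == pytest.approx(1.0, abs=1e-14)

    def test_formula_collapse_without_mediator_effect(self, structural_fits):
        params, ofit, mfit, spec, c = structural_fits
        saved = ofit.coefficients.copy()
        ofit.coefficients[params.mediator_name] = 0.0
        ofit.coefficients[f"sae_lifetime:{params.mediator_name}"] = 0.0
        try:
            nde, nie, te = sm.combine_effects(ofit, mfit, spec, c)
        finally:
            ofit.coefficients[:] = saved
        assert nie == pytest.approx(1.0, abs=1e-14)
        assert nde == pytest.approx(
            math.exp(params.outcome_model.exposure), rel=1e-12)

    def test_decomposition_identity(self, structural_fits):
        _, ofit, mfit, spec, c = structural_fits
        nde, nie, te = sm.combine_effects(ofit, mfit, spec, c)
        assert te == pytest.approx(nde * nie, rel=1e-12)

    def test_agrees_with_oracle_in_rare_outcome_limit(self):
        """With a rare outcome the regression combination converges to the
        exact counterfactual odds ratios."""
        base = sm.default_params("female")
        rare = replace(base, outcome_model=replace(base.outcome_model,
                                                   intercept=-6.0))
        ofit, mfit = fits_from_structural(rare)
        spec = sm.MediationSpec("sae_lifetime", rare.mediator_name,
                                rare.outcome_name)
        c = structural_covariate_setting(rare, "weighted_mean")
        nde, nie, te = sm.combine_effects(ofit, mfit, spec, c)
        truth = sm.oracle_true_effects(rare, "weighted_mean")
        assert te == pytest.approx(truth.true_or_te, rel=0.01)
        assert nde == pytest.approx(truth.true_or_nde, rel=0.01)
        assert nie == pytest.approx(truth.true_or_nie, rel=0.01)

    def test_non_finite_coefficient_is_estimation_error(self,
                                                        structural_fits):
        _, ofit, mfit, spec, c = structural_fits
        saved = ofit.coefficients.copy()
        ofit.coefficients["sae_lifetime"] = math.inf
        try:
            with pytest.raises(EstimationError):
                sm.combine_effects(ofit, mfit, spec, c)
        finally:
            ofit.coefficients[:] = saved


class TestProportionMediated:
    @pytest.mark.parametrize("nie,te,expected", [
        (1.23, 4.09, 0.147), (1.14, 2.67, 0.1334), (1.00, 2.50, 0.0),
    ])
    def test_worked_examples(self, nie, te, expected):
        assert sm.proportion_mediated(nie, te) == pytest.approx(expected,
                                                                abs=5e-4)

    def test_undefined_when_total_effect_is_one(self):
        with pytest.warns(UndefinedProportionWarning):
            assert math.isnan(sm.proportion_mediated(1.2, 1.0))

    def test_opposite_direction_effects_warn_but_return(self):
        with pytest.warns(UndefinedProportionWarning):
            pm = sm.proportion_mediated(0.8, 2.0)
        assert pm == pytest.approx(math.log(0.8) / math.log(2.0))

    def test_nonpositive_odds_ratio_rejected(self):
        with pytest.raises(InputError):
            sm.proportion_mediated(-1.0, 2.0)

    @given(nie=st.floats(1.05, 3.0), te=st.floats(1.2, 6.0),
           power=st.floats(0.2, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_joint_powers(self, nie, te, power):
        """PM is unchanged when both ORs are raised to the same power."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedProportionWarning)
            base = sm.proportion_mediated(nie, te)
            scaled = sm.proportion_mediated(nie ** power, te ** power)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestRunMediation:
    def test_spec_rejects_degenerate_roles(self):
        with pytest.raises(InputError):
            sm.MediationSpec("a", "m", "m")
        with pytest.raises(InputError):
            sm.MediationSpec("a", "a", "y")

    def test_null_model_recovers_unit_odds_ratios(self):
        base = sm.default_params("female")
        null = replace(
            base,
            mediator_model=replace(base.mediator_model, exposure=0.0),
            outcome_model=replace(base.outcome_model, exposure=0.0,
                                  mediator=0.0, interaction=0.0))
        table, _ = sm.generate_cohort(null, 50_000, seed=71)
        est = sm.run_mediation(
            table, sm.MediationSpec("sae_lifetime", "heavy_tobacco",
                                    "depression"), sm.SurveyDesign())
        # sampling error on log TE at this n is below ~0.1
        for odds_ratio in (est.or_te, est.or_nde, est.or_nie):
            assert abs(math.log(odds_ratio)) < 0.3

    def test_point_estimates_recover_oracle(self, female_params, design):
        table, _ = sm.generate_cohort(female_params, 200_000, seed=3)
        est = sm.run_mediation(
            table, sm.MediationSpec("sae_lifetime", "heavy_tobacco",
                                    "depression"), design)
        truth = sm.oracle_true_effects(female_params, "weighted_mean")
        assert abs(math.log(est.or_te)
                   - math.log(truth.true_or_te)) < 0.05
        assert est.or_te == pytest.approx(est.or_nde * est.or_nie,
                                          rel=1e-10)
        assert est.n_used == len(table)
        assert est.meta["outcome_prevalence"] == pytest.approx(0.107,
                                                               abs=0.01)

    def test_direction_swap_runs_on_same_data(self, female_cohort, design):
        """The machinery is symmetric in which variable plays the mediator:
        swapping roles produces the reverse-direction analysis."""
        table, _ = female_cohort
        forward = sm.run_mediation(
            table, sm.MediationSpec("sae_lifetime", "heavy_tobacco",
                                    "depression"), design)
        reverse = sm.run_mediation(
            table, sm.MediationSpec("sae_lifetime", "depression",
                                    "heavy_tobacco"), design)
        assert forward.n_used == reverse.n_used
        assert forward.or_te != reverse.or_te

    def test_empty_exposure_class_is_estimation_error(self, female_cohort,
                                                      design):
        table, _ = female_cohort
        unexposed = table[table["sae_lifetime"] == 0]
        with pytest.raises(EstimationError):
            sm.run_mediation(
                unexposed, sm.MediationSpec("sae_lifetime", "heavy_tobacco",
                                            "depression"), design)

    def test_listwise_deletion_sets_n_used(self, female_params, design):
        table, _ = sm.generate_cohort(female_params, 20_000, seed=73)
        holey = sm.inject_missingness(table, {"heavy_tobacco": 0.04}, seed=4)
        est = sm.run_mediation(
            holey, sm.MediationSpec("sae_lifetime", "heavy_tobacco",
                                    "depression"), design)
        assert est.n_used == holey.dropna(
            subset=["sae_lifetime", "heavy_tobacco", "depression",
                    "age_group", "education"]).shape[0]
        assert est.n_used < len(table)

    def test_modal_and_explicit_covariate_evaluation(self, female_cohort,
                                                     design):
        table, _ = female_cohort
        modal = sm.run_mediation(
            table, sm.MediationSpec("sae_lifetime", "heavy_tobacco",
                                    "depression",
                                    covariate_evaluation="modal"), design)
        explicit = sm.run_mediation(
            table, sm.MediationSpec(
                "sae_lifetime", "heavy_tobacco", "depression",
                covariate_evaluation={"age_group": "46-55",
                                      "education": "high"}), design)
        assert modal.or_te > 1.0 and explicit.or_te > 1.0
        # women's modal covariate cell is age 46-55 / high education, so the
        # two evaluations coincide here
        assert modal.or_te == pytest.approx(explicit.or_te, rel=1e-9)
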