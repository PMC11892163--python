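"""Synthetic-cohort generator: determinism, calibration machinery, nesting,
missingness and the exact counterfactual oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import survmediate as sm
from survmediate.cohort import (PUBLISHED_PREVALENCE, expected_mediator_prevalence,
                                oracle_true_effects,
                                simulate_counterfactual_effects)
from survmediate.errors import InputError


def test_generation_is_deterministic(female_params):
    a, _ = sm.generate_cohort(female_params, 1000, seed=7)
    b, _ = sm.generate_cohort(female_params, 1000, seed=7)
    pd.testing.assert_frame_equal(a, b)
    c, _ = sm.generate_cohort(female_params, 1000, seed=8)
    assert not a.equals(c)


def test_default_params_rejects_bad_labels():
    with pytest.raises(InputError):
        sm.default_params("other")
    with pytest.raises(InputError):
        sm.default_params("female", mediator="depression",
                          outcome="depression")
    with pytest.raises(InputError):
        sm.generate_cohort(sm.default_params("male"), 0, seed=1)


def test_childhood_and_repeated_flags_nest_within_lifetime(female_cohort):
    table, _ = female_cohort
    assert ((table["sae_childhood"] == 1) <= (table["sae_lifetime"] == 1)).all()
    assert ((table["sae_repeated"] == 1) <= (table["sae_lifetime"] == 1)).all()


def test_psus_nest_within_strata(female_cohort):
    table, _ = female_cohort
    psu_strata = table.groupby("psu", observed=True)["stratum"].nunique()
    assert (psu_strata == 1).all()


def test_null_structural_model_gives_null_exposure_outcome_association():
    p = sm.default_params("female")
    null = replace(
        p,
        mediator_model=replace(p.mediator_model, exposure=0.0),
        outcome_model=replace(p.outcome_model, exposure=0.0, mediator=0.0,
                              interaction=0.0),
    )
    table, truth = sm.generate_cohort(null, 100_000, seed=5)
    crosstab = pd.crosstab(table["sae_lifetime"], table["depression"])
    odds_ratio = (crosstab.loc[1, 1] * crosstab.loc[0, 0]
                  / (crosstab.loc[1, 0] * crosstab.loc[0, 1]))
    se_log = math.sqrt((1.0 / crosstab.to_numpy()).sum())
    assert abs(math.log(odds_ratio)) < 3 * se_log
    assert truth.true_or_te == pytest.approx(1.0)


def test_mediator_prevalence_matches_closed_form_expectation(female_params):
    table, _ = sm.generate_cohort(female_params, 100_000, seed=11)
    expected = expected_mediator_prevalence(female_params)
    observed = table[female_params.mediator_name].mean()
    mc_se = math.sqrt(expected * (1 - expected) / len(table))
    assert abs(observed - expected) < 3 * mc_se


@pytest.mark.parametrize("sex", ["female", "male"])
def test_childhood_fraction_matches_published_ratio(sex):
    params = sm.default_params(sex)
    table, _ = sm.generate_cohort(params, 200_000, seed=13)
    targets = PUBLISHED_PREVALENCE[sex]
    exposed = table[table["sae_lifetime"] == 1]
    frac = exposed["sae_childhood"].mean()
    expected = targets["sae_childhood"] / targets["sae_lifetime"]
    se = math.sqrt(expected * (1 - expected) / len(exposed))
    assert abs(frac - expected) < 3 * se


class TestOracle:
    def test_nie_is_one_when_exposure_does_not_move_mediator(self,
                                                             female_params):
        p = replace(female_params,
                    mediator_model=replace(female_params.mediator_model,
                                           exposure=0.0))
        truth = oracle_true_effects(p)
        assert truth.true_or_nie == pytest.approx(1.0, abs=1e-14)

    def test_nie_is_one_when_mediator_does_not_affect_outcome(self,
                                                              female_params):
        p = replace(female_params,
                    outcome_model=replace(female_params.outcome_model,
                                          mediator=0.0, interaction=0.0))
        truth = oracle_true_effects(p)
        assert truth.true_or_nie == pytest.approx(1.0, abs=1e-14)
        assert truth.true_or_nde == pytest.approx(
            truth.true_or_te, rel=1e-14)

    def test_decomposition_identity_exact(self, female_params):
        truth = oracle_true_effects(female_params, "weighted_mean")
        assert truth.true_or_te == pytest.approx(
            truth.true_or_nde * truth.true_or_nie, rel=1e-14)

    def test_pm_flagged_when_total_effect_is_null(self, female_params):
        p = replace(female_params,
                    mediator_model=replace(female_params.mediator_model,
                                           exposure=0.0),
                    outcome_model=replace(female_params.outcome_model,
                                          exposure=0.0, mediator=0.0,
                                          interaction=0.0))
        truth = oracle_true_effects(p)
        assert not truth.pm_defined
        assert math.isnan(truth.true_pm)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_oracle_matches_monte_carlo_counterfactuals(self, seed):
        """Closed-form counterfactual odds ratios agree with brute-force
        simulation on randomly drawn structural parameters."""
        rng = np.random.default_rng(900 + seed)
        base = sm.default_params("female" if seed % 2 else "male")
        p = replace(
            base,
            mediator_model=replace(base.mediator_model,
                                   intercept=rng.uniform(-3.0, -1.0),
                                   exposure=rng.uniform(-0.5, 1.2)),
            outcome_model=replace(base.outcome_model,
                                  intercept=rng.uniform(-4.0, -1.5),
                                  exposure=rng.uniform(-0.5, 1.2),
                                  mediator=rng.uniform(-0.5, 1.2),
                                  interaction=rng.uniform(-0.3, 0.3)),
        )
        truth = oracle_true_effects(p, "modal")
        n_draws = 1_000_000
        mc_nde, mc_nie, mc_te = simulate_counterfactual_effects(
            p, "modal", n_draws, seed=seed)
        # conservative MC error bound on each log odds ratio: each of the
        # three risks enters two odds with binomial error
        for exact, approx in ((truth.true_or_nde, mc_nde),
                              (truth.true_or_nie, mc_nie),
                              (truth.true_or_te, mc_te)):
            se = 3.0 / math.sqrt(n_draws * 0.01)  # risks stay above ~1%
            assert abs(math.log(approx) - math.log(exact)) < 3 * se


class TestMissingness:
    def test_zero_rates_leave_cohort_unchanged(self, female_cohort):
        table, _ = female_cohort
        out = sm.inject_missingness(table, {"heavy_tobacco": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out, table)

    def test_missing_fraction_matches_rate(self, female_params):
        table, _ = sm.generate_cohort(female_params, 100_000, seed=21)
        rate = 0.03
        out = sm.inject_missingness(table, {"heavy_tobacco": rate}, seed=2)
        frac = out["heavy_tobacco"].isna().mean()
        se = math.sqrt(rate * (1 - rate) / len(out))
        assert abs(frac - rate) < 3 * se

    def test_same_seed_same_pattern(self, female_cohort):
        table, _ = female_cohort
        a = sm.inject_missingness(table, {"depression": 0.04}, seed=3)
        b = sm.inject_missingness(table, {"depression": 0.04}, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_rate_outside_unit_interval_rejected(self, female_cohort):
        table, _ = female_cohort
        with pytest.raises(InputError):
            sm.inject_missingness(table, {"depression": 1.5}, seed=1)


def test_cohort_roundtrip_through_csv(tmp_path, female_params):
    table, truth = sm.generate_cohort(female_params, 500, seed=31)
    path = tmp_path / "cohort.csv"
    sm.write_cohort(table, path, params=female_params, truth=truth)
    back = sm.read_cohort(path)
    assert len(back) == 500
    assert list(back["age_group"].cat.categories) == list(
        table["age_group"].cat.categories)
    assert (path.parent / "cohort.params.json").exists()
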