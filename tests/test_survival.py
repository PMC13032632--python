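"""Weibull PH survival, life table and censored maximum likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import blcea
from blcea.survival import (
    MONTHS_PER_WEEK,
    STAGE_ADVANCED,
    STAGE_LIMITED,
    LifeTable,
    SurvivalParams,
    cycle_death_probs,
    background_cycle_prob,
    fit_weibull_ph,
    remaining_life_expectancy,
    survival_at,
)
from blcea.synth import SimulationSpec, simulate_patients


@pytest.fixture(scope="module")
def params():
    return SurvivalParams()


class TestSurvivalAt:
    def test_survival_starts_at_one(self, params):
        assert survival_at(0.0, STAGE_LIMITED, params) == 1.0
        assert survival_at(0.0, STAGE_ADVANCED, params) == 1.0

    def test_24_month_anchors(self, params):
        """The published coefficients imply 24-month survival 0.720 / 0.427,
        matching the stage-stratified Kaplan-Meier estimates of 70% / 45%."""
        assert survival_at(24.0, STAGE_LIMITED, params) == pytest.approx(0.720, abs=5e-4)
        assert survival_at(24.0, STAGE_ADVANCED, params) == pytest.approx(0.427, abs=5e-4)

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            survival_at(-1.0, STAGE_LIMITED, params)

    @given(t=st.floats(min_value=1e-6, max_value=120.0))
    @settings(max_examples=50, deadline=None)
    def test_advanced_below_limited(self, t):
        p = SurvivalParams()
        assert survival_at(t, STAGE_ADVANCED, p) <= survival_at(t, STAGE_LIMITED, p)

    @given(t=st.floats(min_value=0.0, max_value=120.0),
           dt=st.floats(min_value=0.0, max_value=24.0))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing(self, t, dt):
        p = SurvivalParams()
        assert survival_at(t + dt, STAGE_LIMITED, p) <= survival_at(t, STAGE_LIMITED, p)

    def test_proportional_hazards_offset(self, params):
        """log(-log S) curves are parallel with vertical gap beta_advanced."""
        for t in (3.0, 12.0, 24.0):
            gap = (math.log(-math.log(survival_at(t, STAGE_ADVANCED, params)))
                   - math.log(-math.log(survival_at(t, STAGE_LIMITED, params))))
            assert gap == pytest.approx(params.beta_advanced, rel=1e-9)


class TestCycleDeathProbs:
    @pytest.mark.parametrize("stage, s24", [(STAGE_LIMITED, 0.7199448915533025),
                                            (STAGE_ADVANCED, 0.4272166169997771)])
    def test_survivor_product_telescopes(self, params, stage, s24):
        q = cycle_death_probs(3.0, 24.0, stage, params)
        assert len(q) == 8
        assert np.prod(1.0 - q) == pytest.approx(s24, abs=1e-9)

    @given(cycle_len=st.sampled_from([0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
                                      12.0, MONTHS_PER_WEEK, 5.0, 7.0]))
    @settings(max_examples=20, deadline=None)
    def test_telescoping_for_any_cycle_length(self, cycle_len):
        """Survivor product equals S(24) regardless of the cycle grid, even
        when the final cycle is truncated."""
        p = SurvivalParams()
        q = cycle_death_probs(cycle_len, 24.0, STAGE_LIMITED, p)
        assert np.prod(1.0 - q) == pytest.approx(
            survival_at(24.0, STAGE_LIMITED, p), abs=1e-9)

    def test_week_cycles_match_to_six_decimals(self, params):
        q = cycle_death_probs(MONTHS_PER_WEEK, 24.0, STAGE_ADVANCED, params)
        assert abs(np.prod(1.0 - q) - survival_at(24.0, STAGE_ADVANCED, params)) < 1e-6

    def test_exponential_gives_equal_probs(self):
        p = SurvivalParams(gamma=1.0)
        q = cycle_death_probs(3.0, 24.0, STAGE_LIMITED, p)
        assert np.allclose(q, q[0], atol=1e-12)

    def test_all_probs_in_unit_interval(self, params):
        q = cycle_death_probs(3.0, 24.0, STAGE_ADVANCED, params)
        assert np.all((q >= 0) & (q <= 1))


class TestBackgroundMortality:
    def test_zero_annual_prob(self):
        lt = LifeTable([0.0], [0.0], [0.0])
        assert background_cycle_prob(30.0, 3.0, lt) == 0.0

    def test_closed_form(self):
        lt = LifeTable([0.0], [0.012], [0.0])
        assert background_cycle_prob(30.0, 3.0, lt) == pytest.approx(
            1.0 - 0.988 ** 0.25, rel=1e-12)

    def test_certain_death(self):
        lt = LifeTable([0.0], [1.0], [0.0])
        assert background_cycle_prob(30.0, 1.0, lt) == 1.0


class TestLifeTable:
    def test_fixture_anchor_e10(self, life_table):
        """The packaged fixture is calibrated so e(10) = 65 years."""
        assert remaining_life_expectancy(10.0, life_table) == pytest.approx(65.0, abs=0.5)

    def test_zero_mortality_horizon_cap(self):
        lt = LifeTable([0.0], [0.0], [0.0], max_age=100.0)
        assert remaining_life_expectancy(10.0, lt) == pytest.approx(90.0, abs=1e-9)

    def test_e_strictly_decreasing(self, life_table):
        ages = np.arange(0.0, 95.0, 5.0)
        e = [remaining_life_expectancy(a, life_table) for a in ages]
        assert np.all(np.diff(e) < 0)

    def test_background_weights_monotone(self, life_table):
        assert np.all(np.diff(life_table.disability_weight) >= 0)

    def test_csv_roundtrip(self, tmp_path, life_table):
        p = tmp_path / "lt.csv"
        life_table.to_csv(p)
        again = LifeTable.from_csv(p)
        assert np.allclose(again.q_annual, life_table.q_annual, rtol=1e-10)
        assert np.array_equal(again.age_start, life_table.age_start)


class TestWeibullFit:
    def test_parameter_recovery_large_sample(self):
        """MLE on 2000 simulated records with dropout censoring recovers the
        generating parameters within 3 reported standard errors."""
        truth = SurvivalParams()
        recs = simulate_patients(SimulationSpec(
            n_patients=2000, p_limited=0.4, survival=truth,
            censoring_window_months=80.0, seed=7))
        fit = fit_weibull_ph(recs)
        assert abs(fit.beta0 - truth.beta0) < 3 * fit.beta0_se
        assert abs(fit.beta_advanced - truth.beta_advanced) < 3 * fit.beta_advanced_se
        assert abs(fit.gamma - truth.gamma) < 3 * fit.gamma_se

    def test_exponential_closed_form(self):
        """With gamma = 1 and no censoring the stage-wise MLE has the
        closed form events / exposure."""
        truth = SurvivalParams(beta0=-2.0, beta_advanced=0.7, gamma=1.0)
        recs = simulate_patients(SimulationSpec(
            n_patients=4000, p_limited=0.5, survival=truth,
            censoring_window_months=1e9, admin_censor_months=1e9, seed=11))
        fit = fit_weibull_ph(recs)
        assert fit.gamma == pytest.approx(1.0, abs=3 * fit.gamma_se)
        lim = [r for r in recs if r.stage == STAGE_LIMITED]
        rate_hat = len(lim) / sum(r.time for r in lim)
        # at gamma ~= 1 the intercept is the log limited-stage event rate
        assert math.exp(fit.beta0) == pytest.approx(rate_hat, rel=0.05)

    def test_duplication_shrinks_se_by_sqrt2(self):
        recs = simulate_patients(SimulationSpec(n_patients=400, seed=3))
        fit1 = fit_weibull_ph(recs)
        fit2 = fit_weibull_ph(recs + recs)
        assert fit2.beta0 == pytest.approx(fit1.beta0, abs=1e-4)
        assert fit2.gamma == pytest.approx(fit1.gamma, abs=1e-4)
        assert fit2.beta0_se / fit1.beta0_se == pytest.approx(1 / math.sqrt(2), rel=0.02)

    def test_no_events_rejected(self):
        recs = [blcea.PatientRecord(stage=s, time=5.0, event=False)
                for s in (STAGE_LIMITED, STAGE_ADVANCED) for _ in range(10)]
        with pytest.raises(ValueError):
            fit_weibull_ph(recs)

    def test_cross_check_against_lifelines(self):
        """Independent route: lifelines' Weibull AFT fit, converted to the
        PH parameterisation (beta = -rho * a, gamma = rho), agrees with the
        in-house MLE on the same data."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        recs = simulate_patients(SimulationSpec(
            n_patients=1500, p_limited=0.45, censoring_window_months=60.0, seed=5))
        df = pd.DataFrame({
            "T": [r.time for r in recs],
            "E": [int(r.event) for r in recs],
            "adv": [int(r.stage == STAGE_ADVANCED) for r in recs],
        })
        aft = lifelines.WeibullAFTFitter()
        aft.fit(df, duration_col="T", event_col="E", formula="adv")
        rho = float(np.exp(aft.params_[("rho_", "Intercept")]))
        a0 = float(aft.params_[("lambda_", "Intercept")])
        a1 = float(aft.params_[("lambda_", "adv")])
        fit = fit_weibull_ph(recs)
        assert fit.gamma == pytest.approx(rho, rel=1e-3)
        assert fit.beta0 == pytest.approx(-rho * a0, rel=1e-3)
        assert fit.beta_advanced == pytest.approx(-rho * a1, rel=2e-3)
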