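"""ICER computation, one-way SA, PSA machinery and scenarios."""

import numpy as np
import pytest

from _oracle import oracle_arm

import blcea
from blcea import (
    ARM_LIQUID,
    ARM_PATHOLOGY,
    ScenarioSpec,
    Unc,
    ceac,
    ceac_crossing,
    compute_icer,
    draw_psa_params,
    evaluate_arm,
    evaluate_basecase,
    one_way_sa,
    run_psa,
    run_scenario,
)
from blcea.cea import ArmResult, beta_moments, gamma_moments
from blcea.costing import CostResult
from blcea.daly import DalyResult


def _arm(cost, dalys, arm="x"):
    return ArmResult(arm=arm, cost_tzs=cost, dalys=dalys,
                     cost_breakdown=CostResult(),
                     daly_breakdown=DalyResult(0, 0, 0, 0))


class TestIcer:
    def test_simple_ratio(self, base_config):
        res = compute_icer(_arm(0.0, 12.0), _arm(100.0, 10.0), base_config.econ)
        assert res.delta_cost_tzs == 100.0
        assert res.delta_dalys_averted == 2.0
        assert res.icer_tzs_per_daly == 50.0

    def test_dominance_flag(self, base_config):
        res = compute_icer(_arm(1.0, 11.0), _arm(0.0, 10.0), base_config.econ)
        assert res.dominant

    def test_zero_effect_sentinel(self, base_config):
        res = compute_icer(_arm(0.0, 10.0), _arm(5.0, 10.0), base_config.econ)
        assert res.icer_tzs_per_daly == float("inf")

    def test_currency_consistency(self, base_config):
        res = evaluate_basecase(base_config)
        assert res.icer_usd_per_daly == pytest.approx(
            res.icer_tzs_per_daly / 2595.0, rel=1e-12)

    def test_net_benefit_linear_in_lambda(self, base_config):
        res = evaluate_basecase(base_config)
        lams = sorted(res.net_benefit_usd)
        de, dc = res.delta_dalys_averted, res.delta_cost_tzs / 2595.0
        for lam in lams:
            assert res.net_benefit_usd[lam] == pytest.approx(lam * de - dc, rel=1e-9)

    def test_determinism(self, base_config):
        a = evaluate_basecase(base_config)
        b = evaluate_basecase(base_config)
        assert a.icer_usd_per_daly == b.icer_usd_per_daly


class TestScalarOracle:
    @pytest.mark.parametrize("arm", [ARM_PATHOLOGY, ARM_LIQUID])
    def test_engine_matches_brute_force_loop(self, base_config, arm):
        """The vectorised engine agrees with an independent pure-Python
        per-cycle loop over the whole model to 1e-9 relative."""
        cost, dalys = oracle_arm(arm, base_config)
        res = evaluate_arm(arm, base_config)
        assert res.cost_tzs == pytest.approx(cost, rel=1e-9)
        assert res.dalys == pytest.approx(dalys, rel=1e-9)

    def test_oracle_agreement_under_modified_settings(self, cfg):
        cfg.diag.fn_stage_policy = "retain"
        cfg.econ.discount_rate_outcomes = 0.035
        cfg.econ.overhead_on_diagnosis = True
        for arm in (ARM_PATHOLOGY, ARM_LIQUID):
            cost, dalys = oracle_arm(arm, cfg)
            res = evaluate_arm(arm, cfg)
            assert res.cost_tzs == pytest.approx(cost, rel=1e-9)
            assert res.dalys == pytest.approx(dalys, rel=1e-9)


class TestOneWay:
    def test_zero_width_range_zero_span(self, base_config):
        df = one_way_sa(base_config, {"overhead_rate": (0.20, 0.20)})
        assert df["span"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_outcome_discount_direction(self, base_config):
        """A higher outcome discount rate raises the ICER (future health
        gains are worth less)."""
        df = one_way_sa(base_config,
                        {"discount_rate_outcomes": (0.035, 0.10)})
        row = df.iloc[0]
        assert row["icer_high"] > row["icer_base"] > row["icer_low"]

    def test_unknown_parameter_listed(self, base_config):
        with pytest.raises(KeyError, match="valid names"):
            one_way_sa(base_config, {"not_a_parameter": (0, 1)})

    def test_no_range_exceeds_highest_threshold(self, base_config):
        """None of the published one-way ranges pushes the ICER above the
        3xGDP threshold of $3633 per DALY averted."""
        df = one_way_sa(base_config)
        assert df[["icer_low", "icer_high"]].to_numpy().max() < 3633.0


class TestPsaDraws:
    def test_beta_method_of_moments(self):
        a, b = beta_moments(0.288, 0.0526)
        assert a == pytest.approx(21.06, abs=0.05)
        assert b == pytest.approx(52.06, abs=0.05)

    def test_gamma_cv20_shape(self):
        shape, _ = gamma_moments(1_000.0, 200.0)
        assert shape == pytest.approx(25.0, rel=1e-12)

    def test_zero_se_held_fixed(self, cfg):
        cfg.weights.active_disease.se = 0.0
        rng = np.random.default_rng(0)
        for _ in range(5):
            draw = draw_psa_params(cfg, rng)
            assert draw.weights.active_disease.value == 0.288

    def test_draw_means_close_to_base(self, base_config):
        rng = np.random.default_rng(1)
        vals = [draw_psa_params(base_config, rng).weights.active_disease.value
                for _ in range(400)]
        assert np.mean(vals) == pytest.approx(0.288, abs=0.01)

    def test_fixed_quantities_never_drawn(self, base_config):
        rng = np.random.default_rng(2)
        d = draw_psa_params(base_config, rng)
        assert d.diag.nnt == 4
        assert d.econ.annual_discount_rate == 0.05
        assert d.econ.overhead_rate == 0.20


@pytest.fixture(scope="module")
def psa(base_config):
    return run_psa(base_config, iterations=300, seed=123)


class TestPsa:
    def test_seeded_bit_reproducibility(self, base_config, psa):
        again = run_psa(base_config, iterations=300, seed=123)
        assert np.array_equal(psa.cost_liquid, again.cost_liquid)
        assert np.array_equal(psa.dalys_pathology, again.dalys_pathology)

    def test_iteration_count(self, psa):
        assert psa.iterations == 300

    def test_ci_bounds_ordered(self, psa):
        lo, hi = psa.ci_delta_cost_usd()
        assert lo < hi
        lo, hi = psa.ci_delta_dalys()
        assert lo < hi

    def test_ceac_limits(self, psa):
        curve = ceac(psa, [0.0, 1e9])
        frac_saving = float((psa.delta_cost_usd < 0).mean())
        frac_gain = float((psa.delta_dalys_averted > 0).mean())
        assert curve["prob_cost_effective"].iloc[0] == pytest.approx(frac_saving)
        assert curve["prob_cost_effective"].iloc[-1] == pytest.approx(frac_gain)

    def test_ceac_no_crossing_sentinel(self, psa):
        curve = ceac(psa, [0.0])  # acceptability at zero WTP is ~0
        assert np.isnan(ceac_crossing(curve))


class TestScenarios:
    def test_unknown_kind(self, base_config):
        with pytest.raises(ValueError, match="unknown scenario kind"):
            run_scenario(base_config, ScenarioSpec("nonsense"))

    def test_nnt_uses_lower_throughput_tier_below_four(self, base_config):
        r2 = run_scenario(base_config, ScenarioSpec("nnt", {"nnt": 2}))
        r4 = run_scenario(base_config, ScenarioSpec("nnt", {"nnt": 4}))
        base = evaluate_basecase(base_config)
        # NNT=4 reproduces the base case; NNT=2 is cheaper despite the
        # higher 300 samples/yr unit cost
        assert r4.delta_cost_tzs == pytest.approx(base.delta_cost_tzs, rel=1e-12)
        assert r2.delta_cost_tzs < base.delta_cost_tzs
        assert r2.delta_dalys_averted == pytest.approx(base.delta_dalys_averted,
                                                       rel=1e-12)

    def test_availability_blend_arithmetic(self, base_config):
        """Partial availability blends arm outcomes in proportion:
        DALYs = a*E_liquid + (1-a)*E_pathology."""
        a = 0.2
        res = run_scenario(base_config,
                           ScenarioSpec("availability", {"availability": a}))
        e_p = res.reference.dalys
        e_l_full = evaluate_basecase(base_config).comparator.dalys
        assert res.comparator.dalys == pytest.approx(
            a * e_l_full + (1 - a) * e_p, rel=1e-12)
        assert res.delta_dalys_averted == pytest.approx(
            a * (e_p - e_l_full), rel=1e-12)

    def test_extended_risk_lowers_icer(self, base_config):
        """Extending the disease-risk window raises the control arm's burden
        more, decreasing the ICER."""
        base = evaluate_basecase(base_config).icer_usd_per_daly
        prev = base
        for h in (36.0, 48.0, 60.0):
            r = run_scenario(base_config,
                             ScenarioSpec("extended_risk", {"horizon_months": h}))
            assert r.icer_usd_per_daly < prev
            prev = r.icer_usd_per_daly

    def test_week_cycle_close_to_base(self, base_config):
        """Shortening the cycle to one week changes the ICER only a little
        (the DALY burden is dominated by YLL)."""
        base = evaluate_basecase(base_config).icer_usd_per_daly
        r = run_scenario(base_config, ScenarioSpec("cycle_length"))
        assert r.icer_usd_per_daly == pytest.approx(base, rel=0.05)

    def test_rituximab_hook_substitutes_survival(self, base_config):
        alt = blcea.SurvivalParams(beta0=-2.4, beta_advanced=0.8, gamma=0.55)
        r = run_scenario(base_config,
                         ScenarioSpec("rituximab_free", {"survival": alt}))
        assert r.icer_usd_per_daly != pytest.approx(
            evaluate_basecase(base_config).icer_usd_per_daly, rel=1e-6)
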