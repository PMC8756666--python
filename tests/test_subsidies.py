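"""Construction vs operating subsidy: triggers, required curves, spillovers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from careoptions import (
    InfeasiblePolicyError,
    InvalidParameterError,
    ScenarioParams,
    compare_schemes,
    effective_investment_cost,
    effective_price,
    net_expected_value,
    net_value_construction,
    net_value_operating,
    option_value,
    option_value_construction,
    option_value_operating,
    required_construction_subsidy,
    required_operating_subsidy,
    spillover_table,
    subsidy_curves,
    total_outlay,
    trigger_construction,
    trigger_operating,
    trigger_value,
)


class TestEffectiveQuantities:
    def test_effective_cost_baseline(self, baseline):
        assert effective_investment_cost(baseline) == pytest.approx(56_760_000.0)

    @pytest.mark.parametrize("kwargs", [{"S_cs": 0.0}, {"rho": 0.0}])
    def test_effective_cost_unchanged_without_passthrough(self, baseline, kwargs):
        params = baseline.replace(**kwargs)
        assert effective_investment_cost(params) == baseline.investment_cost

    def test_excessive_subsidy_rejected(self, baseline):
        greedy = baseline.replace(S_cs=baseline.investment_cost)  # rho*N_s*S_cs >> I_t
        with pytest.raises(InfeasiblePolicyError):
            effective_investment_cost(greedy)

    def test_effective_price_baseline(self, baseline):
        assert effective_price(baseline) == pytest.approx(40_320.0)

    @pytest.mark.parametrize("kwargs", [{"S_ps": 0.0}, {"theta": 0.0}])
    def test_effective_price_unchanged_without_passthrough(self, baseline, kwargs):
        assert effective_price(baseline.replace(**kwargs)) == baseline.price


class TestSchemeTriggers:
    def test_baseline_triggers_round_as_reported(self, baseline):
        assert round(trigger_construction(baseline)) == 257
        assert round(trigger_operating(baseline)) == 243

    def test_trigger_ordering(self, baseline):
        assert trigger_value(baseline) > trigger_construction(baseline) > trigger_operating(baseline)

    def test_zero_subsidy_recovers_unsubsidized_trigger(self, baseline):
        no_cs = baseline.replace(S_cs=0.0)
        no_ps = baseline.replace(S_ps=0.0)
        assert trigger_construction(no_cs) == pytest.approx(trigger_value(baseline), rel=1e-12)
        assert trigger_operating(no_ps) == pytest.approx(trigger_value(baseline), rel=1e-12)

    def test_exact_ratio_identities(self, baseline):
        q0 = trigger_value(baseline)
        assert trigger_construction(baseline) / q0 == pytest.approx(
            effective_investment_cost(baseline) / baseline.investment_cost, rel=1e-12
        )
        assert trigger_operating(baseline) / q0 == pytest.approx(
            baseline.price / effective_price(baseline), rel=1e-12
        )

    @pytest.mark.parametrize("coef,trigger_fn", [("rho", trigger_construction), ("theta", trigger_operating)])
    def test_triggers_fall_as_passthrough_rises(self, baseline, coef, trigger_fn):
        values = [trigger_fn(baseline.replace(**{coef: c})) for c in (0.0, 0.3, 0.6, 0.9, 1.0)]
        assert all(b < a for a, b in zip(values, values[1:]))


class TestRequiredSubsidy:
    def test_zero_at_and_above_unsubsidized_trigger(self, baseline):
        q_star = trigger_value(baseline)
        for q in (q_star, q_star + 1, 500.0):
            assert required_construction_subsidy(baseline, q) == 0.0
            assert required_operating_subsidy(baseline, q) == 0.0

    def test_plugin_values_at_200(self, baseline):
        assert required_construction_subsidy(baseline, 200.0) == pytest.approx(58_600, abs=100)
        assert required_operating_subsidy(baseline, 200.0) == pytest.approx(14_300, abs=50)

    @pytest.mark.parametrize("q", [60.0, 120.0, 200.0, 260.0])
    def test_round_trip_through_scheme_triggers(self, baseline, q):
        s_cs = required_construction_subsidy(baseline, q)
        s_ps = required_operating_subsidy(baseline, q)
        assert trigger_construction(baseline.replace(S_cs=s_cs)) == pytest.approx(q, rel=1e-6)
        assert trigger_operating(baseline.replace(S_ps=s_ps)) == pytest.approx(q, rel=1e-6)

    def test_curves_decreasing_with_operating_below_construction(self, baseline):
        grid = np.arange(50.0, 300.0 + 1)
        curves = subsidy_curves(baseline, grid)
        pos = curves[curves["S_cs_required"] > 0]
        assert (np.diff(pos["S_cs_required"]) < 0).all()
        pos_ps = curves[curves["S_ps_required"] > 0]
        assert (np.diff(pos_ps["S_ps_required"]) < 0).all()
        waiting = curves["Q"] < trigger_value(baseline)
        assert (
            curves.loc[waiting, "S_ps_required"] < curves.loc[waiting, "S_cs_required"]
        ).all()
        assert (curves[["S_cs_required", "S_ps_required"]] >= 0).all().all()

    def test_zero_passthrough_is_infeasible_below_trigger(self, baseline):
        with pytest.raises(InfeasiblePolicyError):
            required_construction_subsidy(baseline.replace(rho=0.0), 200.0)
        with pytest.raises(InfeasiblePolicyError):
            required_operating_subsidy(baseline.replace(theta=0.0), 200.0)
        # but at/above the trigger no subsidy is needed, so 0 is returned
        q_star = trigger_value(baseline)
        assert required_operating_subsidy(baseline.replace(theta=0.0), q_star) == 0.0

    def test_nonpositive_demand_rejected(self, baseline):
        with pytest.raises(InvalidParameterError):
            required_construction_subsidy(baseline, 0.0)


class TestSchemeValues:
    def test_construction_payoff_shift_is_constant(self, baseline):
        shift = baseline.premium * baseline.rho * baseline.scale * baseline.construction_subsidy
        assert shift == pytest.approx(3_888_000.0)
        for q in (50.0, 150.0, 272.0):
            assert net_value_construction(baseline, q) - net_expected_value(baseline, q) == pytest.approx(
                shift, rel=1e-12
            )

    def test_operating_payoff_shift_is_linear(self, baseline):
        unit = baseline.theta * baseline.operating_subsidy * baseline.discount_factor / baseline.delta
        at_150 = net_value_operating(baseline, 150.0) - net_expected_value(baseline, 150.0)
        assert at_150 == pytest.approx(150.0 * unit, rel=1e-12)
        assert at_150 == pytest.approx(6.43e6, rel=1e-2)

    @pytest.mark.parametrize(
        "trigger_fn,f_fn,v_fn",
        [
            (trigger_construction, option_value_construction, net_value_construction),
            (trigger_operating, option_value_operating, net_value_operating),
        ],
    )
    def test_tangency_at_scheme_triggers(self, baseline, trigger_fn, f_fn, v_fn):
        q = trigger_fn(baseline)
        assert f_fn(baseline, q) == pytest.approx(v_fn(baseline, q), rel=1e-9)
        h = 1e-6 * q
        f_slope = (f_fn(baseline, q + h) - f_fn(baseline, q - h)) / (2 * h)
        v_slope = (v_fn(baseline, q + h) - v_fn(baseline, q - h)) / (2 * h)
        assert f_slope == pytest.approx(v_slope, rel=1e-4)

    def test_zero_subsidies_collapse_to_unsubsidized(self, baseline):
        none = baseline.replace(S_cs=0.0, S_ps=0.0)
        for q in (100.0, 250.0, 290.0):
            assert option_value_construction(none, q) == option_value(none, q)
            assert option_value_operating(none, q) == option_value(none, q)


class TestSpillovers:
    def test_signs_and_shapes(self, baseline):
        grid = np.arange(150.0, 300.0 + 1)
        table = spillover_table(baseline, grid)
        assert (table[["dF_cs", "dF_ps", "dV_cs", "dV_ps"]] >= -1e-6).all().all()
        assert np.ptp(table["dV_cs"]) < 1e-6  # constant in demand
        slopes = np.diff(table["dV_ps"])
        assert (slopes > 0).all() and np.ptp(slopes) < 1e-6  # linear increasing

    def test_operating_dominates_construction_on_comparison_grid(self, baseline):
        grid = np.arange(150.0, 300.0 + 1)
        table = spillover_table(baseline, grid)
        assert (table["dF_ps"] > table["dF_cs"]).all()
        assert (table["dV_ps"] > table["dV_cs"]).all()

    def test_spillover_ratio_oracle_in_waiting_region(self, baseline):
        # below both triggers dF_ps/dF > dF_cs/dF reduces to
        # ((P + theta S_ps)/P)^beta1 vs (I_t/I'_t)^(beta1-1)
        from careoptions import beta_roots

        b1 = beta_roots(baseline).beta1
        lift_ps = (effective_price(baseline) / baseline.price) ** b1
        lift_cs = (
            baseline.investment_cost / effective_investment_cost(baseline)
        ) ** (b1 - 1)
        assert lift_ps > lift_cs
        q = 200.0  # below all triggers
        f0 = option_value(baseline, q)
        assert option_value_operating(baseline, q) / f0 == pytest.approx(lift_ps, rel=1e-9)
        assert option_value_construction(baseline, q) / f0 == pytest.approx(lift_cs, rel=1e-9)


class TestCompareSchemes:
    def test_baseline_comparison_report(self, baseline):
        report = compare_schemes(baseline, np.arange(150.0, 300.0 + 1))
        rounded = {k: round(v) for k, v in report.triggers.items()}
        assert rounded == {"none": 272, "construction": 257, "operating": 243}
        assert report.ordering_holds
        assert report.preferred.value == "operating"

    def test_zero_subsidies_tie(self, baseline):
        none = baseline.replace(S_cs=0.0, S_ps=0.0)
        report = compare_schemes(none, np.arange(150.0, 300.0 + 1))
        assert report.trigger_none == report.trigger_construction == report.trigger_operating
        assert np.allclose(report.spillovers[["dF_cs", "dF_ps", "dV_cs", "dV_ps"]], 0.0)

    def test_total_outlay_view_labels_denominations(self, baseline):
        view = total_outlay(baseline, [100.0, 200.0])
        assert {"construction_outlay_once", "operating_outlay_per_year"} <= set(view.columns)
        assert (view.iloc[:, 1:] >= 0).all().all()


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    q=st.floats(1.0, 500.0),
    s_cs=st.floats(0.0, 50_000.0),
    s_ps=st.floats(0.0, 20_000.0),
)
def test_subsidies_never_hurt_the_investor(q, s_cs, s_ps):
    """F and V under either scheme dominate the unsubsidized values."""
    params = ScenarioParams(construction_subsidy=s_cs, operating_subsidy=s_ps)
    assert option_value_construction(params, q) >= option_value(params, q) - 1e-6
    assert option_value_operating(params, q) >= option_value(params, q) - 1e-6
    assert net_value_construction(params, q) >= net_expected_value(params, q) - 1e-6
    assert net_value_operating(params, q) >= net_expected_value(params, q) - 1e-6
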