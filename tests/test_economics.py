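import numpy as np
import pytest

from hydrocea import ParameterSet, evaluate, run_cohort
from hydrocea.economics import (
    ArmResult,
    accumulate,
    compare,
    discounted_sum,
    first_cycle_cost,
    state_annual_cost,
)
from hydrocea.markov import ARM_STATES, CohortTrace, State


def arm_result(cost, ly, qaly, arm="shunt", perspective="societal", rate=0.03):
    return ArmResult(arm, perspective, rate, cost, ly, qaly, cost, ly, qaly)


class TestStateCosts:
    def test_dead_costs_nothing(self, params):
        assert state_annual_cost(State.DEAD, 0, params) == 0.0

    def test_natural_history_annual_cost_composition(self, params):
        # 0.42*60,600 + 0.58*(6,900+10,500) + 0.06*9,900
        got = state_annual_cost(State.NATURAL, 0, params)
        assert got == pytest.approx(36_138.0, abs=1e-9)
        assert state_annual_cost(State.DETERIORATED, 0, params) == got
        assert state_annual_cost(State.SURGERY, 0, params) == got

    def test_improved_support_portion(self, params):
        # 0.07*60,600 + 0.23*5,200 + 0.60*6,600 plus annual follow-up
        got = state_annual_cost(State.IMPROVED, 0, params)
        support = got - params.c_inpatient - params.c_outpatient
        assert support == pytest.approx(9_398.0, abs=1e-9)

    def test_complication_adds_a_revision_episode(self, params):
        improved = state_annual_cost(State.IMPROVED, 0, params)
        assert state_annual_cost(State.COMPLICATION, 0, params) == pytest.approx(
            improved + params.c_surgery)

    def test_healthcare_perspective_drops_informal_care(self, params):
        societal = state_annual_cost(State.NATURAL, 0, params, "societal")
        healthcare = state_annual_cost(State.NATURAL, 0, params, "healthcare")
        assert societal - healthcare == pytest.approx(
            params.p_ownhome_nh * params.c_informal_nh)
        imp_soc = state_annual_cost(State.IMPROVED, 0, params, "societal")
        imp_hc = state_annual_cost(State.IMPROVED, 0, params, "healthcare")
        assert imp_soc - imp_hc == pytest.approx(
            params.p_informal_shunt * params.c_informal_shunt)


class TestFirstCycleCost:
    def test_default_is_the_surgical_episode(self, params):
        assert first_cycle_cost(params) == pytest.approx(15_800.0)

    def test_zeroed_components_give_zero(self):
        ps = ParameterSet(c_surgery=0, c_inpatient=0, c_outpatient=0)
        assert first_cycle_cost(ps) == 0.0

    def test_identical_under_both_perspectives(self, params):
        assert first_cycle_cost(params, "societal") == first_cycle_cost(params, "healthcare")


class TestDiscountedSum:
    def test_zero_rate_is_plain_sum(self):
        assert discounted_sum([2.0, 3.0, 4.0], 0.0) == pytest.approx(9.0)

    def test_three_percent_example(self):
        expected = 1 + 1 / 1.03 + 1 / 1.03**2
        assert discounted_sum([1.0, 1.0, 1.0], 0.03) == pytest.approx(expected, abs=1e-9)
        assert discounted_sum([1.0, 1.0, 1.0], 0.03) == pytest.approx(2.91347, abs=5e-6)

    def test_single_cycle_is_undiscounted(self):
        assert discounted_sum([7.5], 0.9) == 7.5

    def test_rate_at_or_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            discounted_sum([1.0], -1.0)


def make_trace(occupancy, arm="natural_history"):
    occ = np.asarray(occupancy, float)
    ages = 70 + np.arange(occ.shape[0])
    return CohortTrace(arm=arm, states=ARM_STATES[arm], ages=ages, occupancy=occ)


class TestAccumulate:
    def test_all_dead_from_start_yields_zero(self, params):
        trace = make_trace([[0.0, 1.0]] * 4)
        res = accumulate(trace, params)
        assert res.discounted_cost == 0.0
        assert res.discounted_life_years == 0.0
        assert res.discounted_qaly == 0.0

    def test_three_full_cycles_flat_utility(self, params):
        ps = params.replace(discount_rate=0.0, half_cycle_correction=False)
        trace = make_trace([[1, 0], [1, 0], [1, 0], [0, 1]])
        res = accumulate(trace, ps)
        assert res.undiscounted_life_years == pytest.approx(3.0)
        assert res.undiscounted_qaly == pytest.approx(3 * 0.57)
        assert res.undiscounted_qaly == pytest.approx(1.71)

    def test_flat_weight_identity_on_calibrated_model(self, params, life_table):
        nh = accumulate(run_cohort("natural_history", params, life_table), params)
        assert nh.discounted_qaly == pytest.approx(0.57 * nh.discounted_life_years, rel=1e-12)

    def test_discounting_never_raises_totals(self, params, life_table):
        for arm in ("shunt", "natural_history"):
            res = accumulate(run_cohort(arm, params, life_table), params)
            assert res.discounted_cost <= res.undiscounted_cost
            assert res.discounted_life_years <= res.undiscounted_life_years
            assert res.discounted_qaly <= res.discounted_life_years  # utilities <= 1


class TestCompare:
    def test_icer_identity_on_table_style_numbers(self):
        cea = compare(arm_result(173_000, 6.60, 4.25),
                      arm_result(160_000, 4.42, 2.52, arm="natural_history"))
        assert cea.incremental_cost == pytest.approx(13_000)
        assert cea.incremental_qaly == pytest.approx(1.73)
        assert cea.icer == pytest.approx(13_000 / 1.73, rel=1e-12)
        assert cea.icer == pytest.approx(7_514, abs=1.0)
        assert cea.dominance == "none"

    def test_identical_arms_have_undefined_icer(self):
        a = arm_result(1000.0, 2.0, 1.5)
        cea = compare(a, arm_result(1000.0, 2.0, 1.5, arm="natural_history"))
        assert cea.incremental_cost == 0.0
        assert cea.icer is None

    def test_cheaper_and_better_is_dominant(self):
        cea = compare(arm_result(900.0, 3.0, 2.5),
                      arm_result(1000.0, 2.0, 1.5, arm="natural_history"))
        assert cea.dominance == "intervention_dominant"

    def test_mismatched_perspectives_rejected(self):
        with pytest.raises(ValueError):
            compare(arm_result(1.0, 1.0, 1.0, perspective="societal"),
                    arm_result(1.0, 1.0, 1.0, perspective="healthcare"))


class TestModelProperties:
    def test_equal_utilities_make_dqaly_proportional_to_dly(self, params, life_table):
        ps = params.replace(u_improved=0.57)
        _, _, cea = evaluate(ps, life_table)
        assert cea.incremental_qaly == pytest.approx(0.57 * cea.incremental_life_years, rel=1e-10)

    def test_residential_cost_raises_untreated_arm_more(self, params, life_table):
        shunt0, nh0, _ = evaluate(params, life_table)
        ps = params.replace(c_residential=params.c_residential * 1.2)
        shunt1, nh1, _ = evaluate(ps, life_table)
        d_shunt = shunt1.discounted_cost - shunt0.discounted_cost
        d_nh = nh1.discounted_cost - nh0.discounted_cost
        assert d_shunt > 0 and d_nh > 0
        assert d_nh > d_shunt

    @pytest.mark.parametrize("cost_field", ["c_surgery", "c_residential", "c_informal_nh"])
    def test_raising_any_cost_weakly_raises_both_arms(self, params, life_table, cost_field):
        shunt0, nh0, _ = evaluate(params, life_table)
        ps = params.replace(**{cost_field: getattr(params, cost_field) * 1.5})
        shunt1, nh1, _ = evaluate(ps, life_table)
        assert shunt1.discounted_cost >= shunt0.discounted_cost - 1e-9
        assert nh1.discounted_cost >= nh0.discounted_cost - 1e-9
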