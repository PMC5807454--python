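import itertools

import numpy as np
import pytest

from hydrocea import ParameterSet
from hydrocea.demography import LifeTable
from hydrocea.markov import (
    ARM_STATES,
    State,
    annual_death_prob,
    build_transition_matrix,
    run_cohort,
)


def make_life_table(q_value, start=70, end=75):
    ages = np.arange(start, end + 1)
    q = np.full(ages.shape, float(q_value))
    q[-1] = 1.0
    return LifeTable(ages, q)


class TestAnnualDeathProb:
    def test_no_baseline_mortality_improved(self, params):
        lt = make_life_table(0.0)
        assert annual_death_prob(70, State.IMPROVED, lt, params) == 0.0

    def test_hazard_scale_multiplier(self, params):
        lt = make_life_table(0.02)
        expected = 1.0 - 0.98**2.5
        assert annual_death_prob(70, State.IMPROVED, lt, params) == pytest.approx(expected, abs=1e-12)

    def test_excess_risk_is_additive_by_default(self, params):
        lt = make_life_table(0.02)
        q_star = 1.0 - 0.98**2.5
        got = annual_death_prob(70, State.DETERIORATED, lt, params)
        assert got == pytest.approx(q_star + 0.10, abs=1e-12)

    def test_independent_competing_risk_mode(self, params):
        lt = make_life_table(0.02)
        ps = params.replace(excess_mode="independent")
        got = annual_death_prob(70, State.NATURAL, lt, ps)
        assert got == pytest.approx(1.0 - (1.0 - (1.0 - 0.98**2.5)) * 0.90, abs=1e-12)
        assert got == pytest.approx(0.1443, abs=1e-4)

    def test_dead_is_absorbing(self, params):
        lt = make_life_table(0.5)
        assert annual_death_prob(70, State.DEAD, lt, params) == 1.0


class TestTransitionMatrix:
    @pytest.mark.parametrize("arm", ["shunt", "natural_history"])
    @pytest.mark.parametrize("cycle,age", [(0, 70), (3, 73)])
    def test_rows_are_stochastic(self, params, arm, cycle, age, life_table):
        m = build_transition_matrix(cycle, age, arm, life_table, params)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((m >= 0) & (m <= 1))

    def test_surgery_row_is_the_printed_first_year_split(self, params, life_table):
        m = build_transition_matrix(0, 70, "shunt", life_table, params)
        row = m[ARM_STATES["shunt"].index(State.SURGERY)]
        assert np.allclose(row, [0.0, 0.73, 0.15, 0.10, 0.02], atol=1e-12)

    def test_improved_row_death_first_composition(self, params):
        # Choose baseline q so the multiplied death probability is exactly 0.05.
        q = 1.0 - 0.95 ** (1.0 / 2.5)
        lt = make_life_table(q)
        m = build_transition_matrix(3, 72, "shunt", lt, params)
        states = ARM_STATES["shunt"]
        row = m[states.index(State.IMPROVED)]
        assert row[states.index(State.DEAD)] == pytest.approx(0.05, abs=1e-12)
        assert row[states.index(State.COMPLICATION)] == pytest.approx(0.95 * 0.02, abs=1e-12)
        assert row[states.index(State.DETERIORATED)] == pytest.approx(0.95 * 0.10, abs=1e-12)
        assert row[states.index(State.IMPROVED)] == pytest.approx(0.95 * 0.88, abs=1e-12)

    def test_complication_is_a_one_cycle_tunnel(self, params, life_table):
        m = build_transition_matrix(2, 72, "shunt", life_table, params)
        states = ARM_STATES["shunt"]
        row = m[states.index(State.COMPLICATION)]
        assert row[states.index(State.COMPLICATION)] == 0.0
        survivors = 1.0 - row[states.index(State.DEAD)]
        assert row[states.index(State.IMPROVED)] == pytest.approx(0.70 * survivors)
        assert row[states.index(State.DETERIORATED)] == pytest.approx(0.30 * survivors)


def enumerate_paths(arm, params, life_table, n_cycles):
    """Exhaustive probability-weighted enumeration over all state paths."""
    states = ARM_STATES[arm]
    start = State.SURGERY if arm == "shunt" else State.NATURAL
    matrices = [build_transition_matrix(t, params.start_age + t, arm, life_table, params)
                for t in range(n_cycles)]
    occ = np.zeros((n_cycles + 1, len(states)))
    for path in itertools.product(range(len(states)), repeat=n_cycles + 1):
        if path[0] != states.index(start):
            continue
        p = 1.0
        for t in range(n_cycles):
            p *= matrices[t][path[t], path[t + 1]]
        if p == 0.0:
            continue
        for t, s in enumerate(path):
            occ[t, s] += p / 1.0
    # each cycle's occupancy double-counts paths; normalise per cycle
    return occ / occ.sum(axis=1, keepdims=True)


class TestRunCohort:
    def test_identity_dynamics_keeps_mass_in_place(self, deathless_life_table, params):
        ps = params.replace(p_complication=0.0, p_deteriorated=0.0,
                            excess_mort_deteriorated=0.0, mort_multiplier=1.0)
        trace = run_cohort("natural_history", ps, deathless_life_table)
        natural = trace.occupancy[:, trace.states.index(State.NATURAL)]
        assert np.allclose(natural[:-1], 1.0, atol=1e-12)

    def test_natural_history_matches_scalar_recursion(self, params, life_table):
        trace = run_cohort("natural_history", params, life_table)
        living = 1.0
        for t in range(trace.n_cycles):
            p = annual_death_prob(params.start_age + t, State.NATURAL, life_table, params)
            living *= 1.0 - p
            assert trace.living()[t + 1] == pytest.approx(living, abs=1e-12)

    def test_first_cycle_occupancy_is_the_printed_split(self, params, life_table):
        trace = run_cohort("shunt", params, life_table)
        assert np.allclose(trace.occupancy[1], [0.0, 0.73, 0.15, 0.10, 0.02], atol=1e-12)

    def test_trace_equals_exhaustive_path_enumeration(self, params):
        lt = make_life_table(0.07, 70, 73)
        ps = params.replace(max_age=73, p_complication=0.05, p_deteriorated=0.15,
                            p_improved_after_complication=0.6)
        for arm in ("shunt", "natural_history"):
            trace = run_cohort(arm, ps, lt)
            oracle = enumerate_paths(arm, ps, lt, trace.n_cycles)
            assert np.allclose(trace.occupancy, oracle, atol=1e-12)

    @pytest.mark.parametrize("arm", ["shunt", "natural_history"])
    def test_mass_conserved_and_death_monotone(self, params, life_table, arm):
        trace = run_cohort(arm, params, life_table)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        dead = trace.occupancy[:, trace.states.index(State.DEAD)]
        assert np.all(np.diff(dead) >= -1e-12)
        assert np.all(trace.occupancy >= -1e-12)

    def test_no_excess_mortality_recovers_population_life_expectancy(self, params, life_table):
        # With the multiplier and excess switched off (and the surgery-year
        # residual set to the population q at the start age, since cycle 0
        # replaces background mortality with the first-year split), both arms
        # must reproduce the life table's own expectancy.
        q70 = life_table.q[0]
        ps = params.replace(mort_multiplier=1.0, excess_mort_deteriorated=0.0,
                            p_improved_y1=0.75 - q70, discount_rate=0.0,
                            half_cycle_correction=False)
        expected = life_table.survival()[:-1].sum()  # cycle-start counting
        for arm in ("shunt", "natural_history"):
            trace = run_cohort(arm, ps, life_table)
            got = trace.living()[:len(life_table.ages)].sum()
            assert got == pytest.approx(expected, abs=1e-9)

    def test_shunt_survivors_see_background_mortality_from_cycle_one(self, params, life_table):
        trace = run_cohort("shunt", params, life_table)
        living = trace.living()
        # cycle 0 -> 1 loses exactly the perioperative residual
        assert living[1] == pytest.approx(0.98, abs=1e-12)
        assert np.all(np.diff(living) <= 1e-12)
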