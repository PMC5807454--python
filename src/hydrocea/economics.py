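"""Costing, discounting, and incremental cost-effectiveness results.

Per-state annual costs are composed from the printed care mix and unit costs:

* Natural history (and Deteriorated, which reverts to untreated-level care,
  and the surgery year, during which the pre-treatment support need persists):
  residential care, home service plus informal care for those in their own
  home, and day care.
* Improved: the post-surgery support mix plus the annual inpatient and
  outpatient follow-up costs measured in the patient survey.
* Complication: Improved's annual cost plus a revision episode valued at the
  surgery cost.

The one-off surgical episode (surgery + inpatient + outpatient) is added to
cycle 0 of the treated arm. The societal perspective counts everything; the
healthcare perspective excludes informal care. Costs and effects are
discounted symmetrically; by default cycle sums use a half-cycle correction
(state membership averaged between cycle boundaries), with the one-off
surgery cost kept as a point cost at time zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import population_utility_norm
from .markov import CohortTrace, State
from .parameters import ParameterSet

__all__ = [
    "ArmResult",
    "CEAResult",
    "PERSPECTIVES",
    "state_annual_cost",
    "state_utility",
    "first_cycle_cost",
    "discounted_sum",
    "accumulate",
    "compare",
    "evaluate",
]

PERSPECTIVES = ("societal", "healthcare")
_ICER_EPS = 1e-9


def _natural_history_annual_cost(params: ParameterSet, informal: bool) -> float:
    inf = params.c_informal_nh if informal else 0.0
    return (params.p_residential_nh * params.c_residential
            + params.p_ownhome_nh * (params.c_homeservice_nh + inf)
            + params.p_daycare_nh * params.c_daycare_nh)


def _improved_annual_cost(params: ParameterSet, informal: bool) -> float:
    support = (params.p_residential_shunt * params.c_residential
               + params.p_homeservice_shunt * params.c_homeservice_shunt)
    if informal:
        support += params.p_informal_shunt * params.c_informal_shunt
    return support + params.c_inpatient + params.c_outpatient


def state_annual_cost(state: State, cycle: int, params: ParameterSet,
                      perspective: str = "societal") -> float:
    """Annual cost (euros per patient-year) of occupying a state."""
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    informal = perspective == "societal"
    if state is State.DEAD:
        return 0.0
    if state in (State.NATURAL, State.DETERIORATED, State.SURGERY):
        return _natural_history_annual_cost(params, informal)
    if state is State.IMPROVED:
        return _improved_annual_cost(params, informal)
    if state is State.COMPLICATION:
        return _improved_annual_cost(params, informal) + params.c_surgery
    raise ValueError(f"unknown state {state!r}")


def state_utility(state: State, params: ParameterSet) -> float:
    if state is State.DEAD:
        return 0.0
    if state is State.IMPROVED:
        return params.u_improved
    return params.u_poor


def first_cycle_cost(params: ParameterSet, perspective: str = "societal") -> float:
    """One-off surgical-episode cost added to cycle 0 of the treated arm.

    All three components are healthcare costs, so the value is identical
    under both perspectives.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    return params.c_surgery + params.c_inpatient + params.c_outpatient


def discounted_sum(stream, rate: float) -> float:
    """Present value of a per-cycle stream: sum of stream[t] / (1+rate)^t."""
    if rate <= -1.0:
        raise ValueError("discount rate must exceed -1")
    stream = np.asarray(stream, float)
    t = np.arange(stream.shape[0])
    return float(np.sum(stream / (1.0 + rate) ** t))


@dataclass(frozen=True)
class ArmResult:
    arm: str
    perspective: str
    discount_rate: float
    discounted_cost: float
    discounted_life_years: float
    discounted_qaly: float
    undiscounted_cost: float
    undiscounted_life_years: float
    undiscounted_qaly: float


def accumulate(trace: CohortTrace, params: ParameterSet,
               perspective: str = "societal") -> ArmResult:
    """Lifetime discounted and undiscounted cost, life years and QALYs."""
    occ = trace.occupancy
    if params.half_cycle_correction:
        weights = 0.5 * (occ[:-1] + occ[1:])
        ages = trace.ages[:-1] + 0.5
    else:
        weights = occ
        ages = trace.ages.astype(float)
    costs = np.array([state_annual_cost(s, 0, params, perspective)
                      for s in trace.states])
    utils = np.array([state_utility(s, params) for s in trace.states])
    living = np.ones(len(trace.states))
    living[trace.states.index(State.DEAD)] = 0.0

    cost_stream = weights @ costs
    ly_stream = weights @ living
    qaly_stream = weights @ utils
    if params.age_adjust_utilities:
        qaly_stream = qaly_stream * population_utility_norm(ages, params.start_age)
    if trace.arm == "shunt":
        cost_stream = cost_stream.copy()
        cost_stream[0] += first_cycle_cost(params, perspective)

    r = params.discount_rate
    return ArmResult(
        arm=trace.arm,
        perspective=perspective,
        discount_rate=r,
        discounted_cost=discounted_sum(cost_stream, r),
        discounted_life_years=discounted_sum(ly_stream, r),
        discounted_qaly=discounted_sum(qaly_stream, r),
        undiscounted_cost=discounted_sum(cost_stream, 0.0),
        undiscounted_life_years=discounted_sum(ly_stream, 0.0),
        undiscounted_qaly=discounted_sum(qaly_stream, 0.0),
    )


@dataclass(frozen=True)
class CEAResult:
    incremental_cost: float
    incremental_life_years: float
    incremental_qaly: float
    icer: float | None          # euros per QALY; None when dQALY ~ 0
    cost_per_ly: float | None   # euros per life year
    dominance: str              # none | intervention_dominant | intervention_dominated
    perspective: str
    discount_rate: float


def compare(intervention: ArmResult, comparator: ArmResult) -> CEAResult:
    """Incremental results, intervention minus comparator."""
    if intervention.perspective != comparator.perspective:
        raise ValueError("arms evaluated under different perspectives")
    if intervention.discount_rate != comparator.discount_rate:
        raise ValueError("arms evaluated under different discount rates")
    d_cost = intervention.discounted_cost - comparator.discounted_cost
    d_ly = intervention.discounted_life_years - comparator.discounted_life_years
    d_q = intervention.discounted_qaly - comparator.discounted_qaly
    icer = d_cost / d_q if abs(d_q) > _ICER_EPS else None
    cost_per_ly = d_cost / d_ly if abs(d_ly) > _ICER_EPS else None
    if d_cost < 0 and d_q > 0:
        dominance = "intervention_dominant"
    elif d_cost > 0 and d_q < 0:
        dominance = "intervention_dominated"
    else:
        dominance = "none"
    return CEAResult(
        incremental_cost=d_cost,
        incremental_life_years=d_ly,
        incremental_qaly=d_q,
        icer=icer,
        cost_per_ly=cost_per_ly,
        dominance=dominance,
        perspective=intervention.perspective,
        discount_rate=intervention.discount_rate,
    )


def evaluate(params: ParameterSet, life_table,
             perspective: str = "societal") -> tuple[ArmResult, ArmResult, CEAResult]:
    """Run both arms and compare: (shunt, natural history, incremental)."""
    from .markov import run_cohort

    shunt = accumulate(run_cohort("shunt", params, life_table), params, perspective)
    nh = accumulate(run_cohort("natural_history", params, life_table), params, perspective)
    return shunt, nh, compare(shunt, nh)
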