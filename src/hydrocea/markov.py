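"""Markov cohort engine: transition matrices and occupancy traces.

Two arms share one cycle structure (annual cycles from the starting age to
the horizon). The treated arm passes through a surgery year (cycle 0, the
printed first-year outcome split, with the unallocated residual assigned to
perioperative death and no separate background mortality) and thereafter
moves between Improved, Complication (a one-cycle tunnel: survivors either
recover or deteriorate) and Deteriorated. The untreated arm has a single
living state. Death is absorbing.

Within a cycle, death is resolved first and the among-living transition
probabilities apply to survivors.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .demography import LifeTable
from .parameters import ParameterSet

__all__ = [
    "State",
    "ARM_STATES",
    "CohortTrace",
    "annual_death_prob",
    "build_transition_matrix",
    "run_cohort",
]

_ROW_TOL = 1e-12
_MASS_TOL = 1e-10


class State(str, Enum):
    SURGERY = "surgery"  # treated arm, cycle 0 only (the operation year)
    IMPROVED = "improved"
    COMPLICATION = "complication"
    DETERIORATED = "deteriorated"
    NATURAL = "natural_history"
    DEAD = "dead"


ARM_STATES = {
    "shunt": (State.SURGERY, State.IMPROVED, State.COMPLICATION,
              State.DETERIORATED, State.DEAD),
    "natural_history": (State.NATURAL, State.DEAD),
}

LIVING_STATES = frozenset(State) - {State.DEAD}


def annual_death_prob(age: int, state: State, life_table: LifeTable,
                      params: ParameterSet) -> float:
    """Annual probability of death by state at an attained age.

    Living states carry the general-population probability raised on the
    hazard scale by ``mort_multiplier``; Deteriorated and Natural history add
    the excess risk, by default on the probability scale (``additive``), or
    as an independent competing risk (``independent``).
    """
    if state is State.DEAD:
        return 1.0
    if state is State.SURGERY:
        # Perioperative mortality is the residual of the first-year split.
        return 1.0 - (params.p_improved_y1 + params.p_complication_y1
                      + params.p_deteriorated_y1)
    q = life_table.q_at(age)
    q_star = 1.0 - (1.0 - q) ** params.mort_multiplier
    if state in (State.IMPROVED, State.COMPLICATION):
        return q_star
    if state in (State.DETERIORATED, State.NATURAL):
        e = params.excess_mort_deteriorated
        if params.excess_mode == "additive":
            return min(q_star + e, 1.0)
        return 1.0 - (1.0 - q_star) * (1.0 - e)
    raise ValueError(f"unknown state {state!r}")


def _check_rows(matrix: np.ndarray, arm: str) -> np.ndarray:
    if np.any(matrix < -_ROW_TOL) or np.any(matrix > 1.0 + _ROW_TOL):
        raise ValueError(f"{arm}: transition probability outside [0, 1]")
    rows = matrix.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-9):
        raise ValueError(f"{arm}: transition rows do not sum to 1 ({rows})")
    return np.clip(matrix, 0.0, 1.0)


def build_transition_matrix(cycle: int, age: int, arm: str,
                            life_table: LifeTable, params: ParameterSet) -> np.ndarray:
    """One-cycle transition matrix for an arm at an attained age.

    Rows/columns follow ``ARM_STATES[arm]``. The surgery row applies the
    printed first-year split regardless of age; it is only ever occupied at
    cycle 0.
    """
    if arm == "shunt":
        p1, p2, p3 = (params.p_improved_y1, params.p_complication_y1,
                      params.p_deteriorated_y1)
        resid = 1.0 - (p1 + p2 + p3)
        d_imp = annual_death_prob(age, State.IMPROVED, life_table, params)
        d_det = annual_death_prob(age, State.DETERIORATED, life_table, params)
        pc, pd_ = params.p_complication, params.p_deteriorated
        stay = 1.0 - pc - pd_
        pic = params.p_improved_after_complication
        m = np.array([
            [0.0, p1, p2, p3, resid],
            [0.0, (1 - d_imp) * stay, (1 - d_imp) * pc, (1 - d_imp) * pd_, d_imp],
            [0.0, (1 - d_imp) * pic, 0.0, (1 - d_imp) * (1 - pic), d_imp],
            [0.0, 0.0, 0.0, 1 - d_det, d_det],
            [0.0, 0.0, 0.0, 0.0, 1.0],
        ])
        return _check_rows(m, arm)
    if arm == "natural_history":
        d = annual_death_prob(age, State.NATURAL, life_table, params)
        m = np.array([[1 - d, d], [0.0, 1.0]])
        return _check_rows(m, arm)
    raise ValueError(f"unknown arm {arm!r}")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy (cohort fractions) with attained age."""

    arm: str
    states: tuple
    ages: np.ndarray       # attained age at each cycle, length n_cycles + 1
    occupancy: np.ndarray  # (n_cycles + 1, n_states)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, float)
        if np.any(occ < -_MASS_TOL):
            raise ValueError("negative occupancy")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > _MASS_TOL):
            raise ValueError("occupancy does not conserve cohort mass")
        dead = occ[:, self.states.index(State.DEAD)]
        if np.any(np.diff(dead) < -_MASS_TOL):
            raise ValueError("dead fraction decreased")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def living(self) -> np.ndarray:
        dead_col = self.states.index(State.DEAD)
        mask = np.ones(len(self.states), bool)
        mask[dead_col] = False
        return self.occupancy[:, mask].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy,
                          columns=[s.value for s in self.states])
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(self.ages)))
        return df


def run_cohort(arm: str, params: ParameterSet, life_table: LifeTable,
               min_living: float = 1e-9) -> CohortTrace:
    """Propagate the cohort from the start age to the horizon.

    Iteration stops at the horizon (one cycle past ``max_age``) or as soon as
    the living mass falls below ``min_living``.
    """
    states = ARM_STATES[arm]
    n_ages = params.max_age - params.start_age + 1
    occ = [np.zeros(len(states))]
    start_state = State.SURGERY if arm == "shunt" else State.NATURAL
    occ[0][states.index(start_state)] = 1.0
    dead_col = states.index(State.DEAD)
    for t in range(n_ages):
        age = params.start_age + t
        m = build_transition_matrix(t, age, arm, life_table, params)
        nxt = occ[-1] @ m
        occ.append(nxt)
        if 1.0 - nxt[dead_col] < min_living:
            break
    occupancy = np.vstack(occ)
    ages = params.start_age + np.arange(occupancy.shape[0])
    return CohortTrace(arm=arm, states=states, ages=ages, occupancy=occupancy)
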