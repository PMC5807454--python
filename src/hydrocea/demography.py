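"""General-population mortality: a parametric life table with calibration.

The published analysis drew background mortality from national statistics and
never printed it. Here the life table is a Gompertz–Makeham fixture,

    hazard(age) = makeham + level * exp(slope * age),

with the slope held at a literature-typical 0.095 per year of age, no
Makeham term, and the level calibrated so that the untreated (natural-history)
arm of the Markov model reproduces a target discounted life expectancy. All
downstream outputs of the treated arm are then genuine model predictions.

Also provides an optional age-dependent population utility norm (a linear
decline fixture, off by default) for multiplicative adjustment of the state
utility weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .parameters import ParameterSet

__all__ = [
    "GompertzParams",
    "LifeTable",
    "gompertz_life_table",
    "calibrate_mortality",
    "CalibrationError",
    "population_utility_norm",
]

DEFAULT_SLOPE = 0.095  # log-hazard increase per year of age


class CalibrationError(RuntimeError):
    """Target life expectancy not achievable within the search bracket."""


@dataclass(frozen=True)
class GompertzParams:
    level: float
    slope: float = DEFAULT_SLOPE
    makeham: float = 0.0

    def __post_init__(self) -> None:
        for name in ("level", "slope", "makeham"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.level <= 0:
            raise ValueError("level must be positive")
        if self.slope < 0 or self.makeham < 0:
            raise ValueError("negative hazard component")

    def hazard(self, age):
        return self.makeham + self.level * np.exp(self.slope * np.asarray(age, float))


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(age) on a contiguous integer age grid."""

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, int)
        q = np.asarray(self.q, float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        if ages.shape != q.shape:
            raise ValueError("ages and q must have the same length")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be contiguous integers")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("death probabilities outside [0, 1]")
        if q[-1] != 1.0:
            raise ValueError("terminal death probability must be 1")

    def q_at(self, age: int) -> float:
        idx = int(age) - int(self.ages[0])
        if idx < 0 or idx >= len(self.ages):
            raise KeyError(f"age {age} outside life table [{self.ages[0]}, {self.ages[-1]}]")
        return float(self.q[idx])

    def survival(self) -> np.ndarray:
        """S(a) from the first age, S(first) = 1; length len(ages) + 1."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.q)])

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.ages, self.q])
        np.savetxt(path, arr, fmt=["%d", "%.12g"], delimiter=",",
                   header="age,q", comments="")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0].astype(int), arr[:, 1])


def gompertz_life_table(params: GompertzParams, start_age: int, max_age: int) -> LifeTable:
    """Closed-form annual death probabilities from a Gompertz–Makeham hazard.

    q(a) = 1 - exp(-H(a)) with H(a) the hazard integrated over [a, a+1);
    the terminal q at ``max_age`` is forced to 1 so the horizon closes.
    """
    if start_age >= max_age:
        raise ValueError("start_age must be below max_age")
    ages = np.arange(start_age, max_age + 1)
    if params.slope == 0.0:
        cum = params.level * np.ones_like(ages, dtype=float)
    else:
        cum = (params.level / params.slope) * (
            np.exp(params.slope * (ages + 1.0)) - np.exp(params.slope * ages)
        )
    cum += params.makeham
    q = 1.0 - np.exp(-cum)
    q[-1] = 1.0
    return LifeTable(ages, q)


def _natural_history_discounted_ly(level: float, params: ParameterSet,
                                   slope: float, makeham: float) -> float:
    from .economics import accumulate
    from .markov import run_cohort

    lt = gompertz_life_table(
        GompertzParams(level=level, slope=slope, makeham=makeham),
        params.start_age, params.max_age,
    )
    trace = run_cohort("natural_history", params, lt)
    return accumulate(trace, params).discounted_life_years


def calibrate_mortality(
    target_discounted_le: float,
    params: ParameterSet,
    slope: float = DEFAULT_SLOPE,
    makeham: float = 0.0,
    bracket: tuple[float, float] = (1e-9, 5e-2),
    tol: float = 1e-4,
) -> GompertzParams:
    """Find the Gompertz level at which the natural-history arm's discounted
    life expectancy equals ``target_discounted_le``.

    The natural-history arm is run with the full mortality model (hazard
    multiplier and excess risk, discounting per ``params``); only the level is
    searched, by bisection within ``bracket``. Achieved LE is within
    5e-3 years of the target (far tighter in practice).
    """

    def gap(level: float) -> float:
        return _natural_history_discounted_ly(level, params, slope, makeham) - target_discounted_le

    lo, hi = bracket
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise CalibrationError(
            f"target {target_discounted_le} outside achievable range "
            f"[{target_discounted_le + g_hi:.3f}, {target_discounted_le + g_lo:.3f}] "
            f"for levels in {bracket}"
        )
    level = brentq(gap, lo, hi, xtol=1e-14, rtol=8.9e-16)
    achieved = target_discounted_le + gap(level)
    if abs(achieved - target_discounted_le) > 5e-3:
        raise CalibrationError(
            f"calibration achieved {achieved:.4f}, target {target_discounted_le}"
        )
    return GompertzParams(level=level, slope=slope, makeham=makeham)


def population_utility_norm(age, anchor_age: int = 70) -> np.ndarray:
    """Relative population utility norm, linear-decline fixture.

    Returns norm(age) / norm(anchor_age) for multiplicative adjustment of
    state utilities; the fixture declines 0.4% of the anchor value per year of
    age (synthetic stand-in for unpublished national age norms; off by
    default in the model).
    """
    age = np.asarray(age, float)
    rel = 1.0 - 0.004 * (age - anchor_age)
    return np.clip(rel, 0.0, None)
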