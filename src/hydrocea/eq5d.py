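"""EQ-5D-3L utility scoring with the UK time-trade-off tariff.

A health profile is five dimension levels (mobility, self-care, usual
activities, pain/discomfort, anxiety/depression), each 1 (no problems) to
3 (extreme problems). The UK tariff maps a profile to a utility index by
subtracting, from full health (1.0): a constant for any departure from full
health, per-dimension level decrements, and an extra "N3" decrement if any
dimension is at level 3. The worst profile (3,3,3,3,3) scores -0.594.

The coefficients are packaged as data (``data/uk_tto_coefficients.csv``);
alternative value sets can be supplied by file path.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = ["EQ5DProfile", "load_tariff", "eq5d_index_uk", "enumerate_value_set"]

DIMENSIONS = ("mobility", "selfcare", "usualact", "pain", "anxiety")


@dataclass(frozen=True)
class EQ5DProfile:
    mobility: int
    selfcare: int
    usualact: int
    pain: int
    anxiety: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in (1, 2, 3):
                raise ValueError(f"{dim}: level {level!r} outside {{1, 2, 3}}")

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, dim) for dim in DIMENSIONS)

    @classmethod
    def from_levels(cls, levels) -> "EQ5DProfile":
        return cls(*(int(v) for v in levels))

    def __str__(self) -> str:
        return "".join(str(v) for v in self.levels)


@lru_cache(maxsize=4)
def load_tariff(path: str | None = None) -> dict[str, float]:
    """Read a value-set coefficient table (term, value CSV)."""
    if path is None:
        text = resources.files("hydrocea.data").joinpath(
            "uk_tto_coefficients.csv"
        ).read_text()
        lines = text.splitlines()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    rows = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    coeffs = {}
    for row in csv.DictReader(rows):
        coeffs[row["term"]] = float(row["value"])
    missing = {"constant", "n3"} | {
        f"{d}_{lvl}" for d in DIMENSIONS for lvl in (2, 3)
    }
    missing -= set(coeffs)
    if missing:
        raise ValueError(f"tariff table lacks terms: {sorted(missing)}")
    return coeffs


def eq5d_index_uk(profile: EQ5DProfile, tariff: dict[str, float] | None = None) -> float:
    """Utility index of a profile under the UK TTO tariff.

    Full health (1,1,1,1,1) returns exactly 1.0.
    """
    if not isinstance(profile, EQ5DProfile):
        profile = EQ5DProfile.from_levels(profile)
    coeffs = tariff if tariff is not None else load_tariff()
    levels = profile.levels
    if all(lvl == 1 for lvl in levels):
        return 1.0
    value = 1.0 - coeffs["constant"]
    for dim, lvl in zip(DIMENSIONS, levels):
        if lvl > 1:
            value -= coeffs[f"{dim}_{lvl}"]
    if any(lvl == 3 for lvl in levels):
        value -= coeffs["n3"]
    return value


def enumerate_value_set(tariff: dict[str, float] | None = None) -> dict[str, float]:
    """Index values for all 243 profiles, keyed by the 5-digit code."""
    out = {}
    for levels in itertools.product((1, 2, 3), repeat=5):
        p = EQ5DProfile(*levels)
        out[str(p)] = eq5d_index_uk(p, tariff)
    return out
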