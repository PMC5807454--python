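"""Model parameters, validation, and sampling distributions.

A :class:`ParameterSet` is the single source of truth for one model run: all
transition probabilities, unit costs (annual, in euros), utility weights, the
discount rate, cohort settings and willingness-to-pay thresholds, plus the
model conventions (half-cycle correction, how the excess mortality of
untreated/deteriorated patients combines with background mortality).

For probabilistic sensitivity analysis each uncertain parameter carries a
:class:`DistributionSpec` (beta for probabilities and utilities, gamma for
costs, uniform for the observed support proportions) whose mean equals the
base-case value and whose printed range — mean ± 20% throughout — is read as a
95% interval by default.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, fields
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "ParameterSet",
    "DistributionSpec",
    "ParameterError",
    "load_parameters",
    "default_distribution_specs",
    "concretize_distribution",
    "distribution_mean",
    "sample_distribution",
]


class ParameterError(ValueError):
    """Raised when a configuration value fails validation."""


_PROBABILITY_FIELDS = (
    "p_improved_y1",
    "p_complication_y1",
    "p_deteriorated_y1",
    "p_complication",
    "p_improved_after_complication",
    "p_deteriorated",
    "excess_mort_deteriorated",
    "p_residential_shunt",
    "p_homeservice_shunt",
    "p_informal_shunt",
    "p_residential_nh",
    "p_daycare_nh",
    "u_improved",
    "u_poor",
)

_COST_FIELDS = (
    "c_surgery",
    "c_inpatient",
    "c_outpatient",
    "c_residential",
    "c_homeservice_shunt",
    "c_homeservice_nh",
    "c_daycare_nh",
    "c_informal_shunt",
    "c_informal_nh",
)


@dataclass(frozen=True)
class ParameterSet:
    # First-year transition probabilities (cycle 0, surgery year)
    p_improved_y1: float = 0.73
    p_complication_y1: float = 0.15
    p_deteriorated_y1: float = 0.10
    # Transition probabilities after the first year
    p_complication: float = 0.02
    p_improved_after_complication: float = 0.70
    p_deteriorated: float = 0.10
    # Mortality: hazard multiplier vs the general population (all living
    # states) and the additional annual risk for Deteriorated/Natural history
    excess_mort_deteriorated: float = 0.10
    mort_multiplier: float = 2.5
    # Support mix observed after surgery (patient survey, n = 30)
    p_residential_shunt: float = 0.07
    p_homeservice_shunt: float = 0.23
    p_informal_shunt: float = 0.60
    # Support mix of the untreated (dementia-report) cohort
    p_residential_nh: float = 0.42
    p_daycare_nh: float = 0.06
    # Annual costs, euros
    c_surgery: float = 10_200.0
    c_inpatient: float = 3_900.0
    c_outpatient: float = 1_700.0
    c_residential: float = 60_600.0
    c_homeservice_shunt: float = 5_200.0
    c_homeservice_nh: float = 6_900.0
    c_daycare_nh: float = 9_900.0
    c_informal_shunt: float = 6_600.0
    c_informal_nh: float = 10_500.0
    # Utility weights
    u_improved: float = 0.71
    u_poor: float = 0.57
    # Run settings
    discount_rate: float = 0.03
    cohort_size: int = 1000
    start_age: int = 70
    max_age: int = 105
    wtp_lower: float = 22_150.0
    wtp_upper: float = 33_220.0
    # Unit prices behind the informal/formal care valuations
    rate_homehelp_hour: float = 38.0
    rate_informal_hour: float = 15.0
    leisure_fraction: float = 0.35
    hours_homecare_nh_daily: float = 0.5
    hours_informal_nh_daily: float = 1.9
    # Model conventions (documented in docs/methods.md)
    half_cycle_correction: bool = True
    excess_mode: str = "additive"  # or "independent"
    sd_rule: str = "ci95"  # or "range4": SD = (high - low) / 4
    age_adjust_utilities: bool = False

    @property
    def p_ownhome_nh(self) -> float:
        """Fraction of untreated patients living in their own home (derived)."""
        return 1.0 - self.p_residential_nh

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ParameterError(f"{name}: not a finite number ({v!r})")
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}: probability {v} outside [0, 1]")
        for name in _COST_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ParameterError(f"{name}: not a finite number ({v!r})")
            if v < 0:
                raise ParameterError(f"{name}: negative cost {v}")
        tri = self.p_improved_y1 + self.p_complication_y1 + self.p_deteriorated_y1
        if tri > 1.0 + 1e-12:
            raise ParameterError(
                f"first-year probabilities sum to {tri:.4f} > 1 "
                "(p_improved_y1 + p_complication_y1 + p_deteriorated_y1)"
            )
        if self.p_complication + self.p_deteriorated > 1.0 + 1e-12:
            raise ParameterError("p_complication + p_deteriorated exceeds 1")
        if not 0.0 <= self.discount_rate <= 0.10:
            raise ParameterError(
                f"discount_rate: {self.discount_rate} outside [0, 0.10]"
            )
        if self.mort_multiplier < 1.0:
            raise ParameterError(
                f"mort_multiplier: {self.mort_multiplier} below 1"
            )
        if self.start_age >= self.max_age:
            raise ParameterError("start_age must be below max_age")
        if self.excess_mode not in ("additive", "independent"):
            raise ParameterError(f"excess_mode: unknown mode {self.excess_mode!r}")
        if self.sd_rule not in ("ci95", "range4"):
            raise ParameterError(f"sd_rule: unknown rule {self.sd_rule!r}")

    def replace(self, **overrides: object) -> "ParameterSet":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _read_config(config_source) -> dict:
    if config_source is None:
        return {}
    if isinstance(config_source, Mapping):
        return dict(config_source)
    if isinstance(config_source, io.IOBase):
        text = config_source.read()
    else:
        with open(config_source, "r", encoding="utf-8") as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParameterError("configuration must be a mapping of key: value")
    return data


def packaged_defaults() -> dict:
    """The packaged base-case configuration (every field, YAML)."""
    text = resources.files("hydrocea.data").joinpath("base_case.yaml").read_text()
    return yaml.safe_load(text)


def load_parameters(config_source=None, overrides: Mapping | None = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet`.

    ``config_source`` may be a path, an open text stream, a mapping or None;
    absent keys fall back to the packaged base-case values. Unknown keys are
    rejected. ``overrides`` (e.g. from ``--param key=value`` flags) are applied
    last.
    """
    data = _read_config(config_source)
    if overrides:
        data.update(overrides)
    valid = {f.name for f in fields(ParameterSet)}
    unknown = set(data) - valid
    if unknown:
        raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
    try:
        return ParameterSet(**data)
    except TypeError as exc:  # malformed value type
        raise ParameterError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Sampling distributions for probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain parameter: family, mean and printed range."""

    parameter_name: str
    family: str  # beta | gamma | uniform | fixed
    mean: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "uniform", "fixed"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if not self.low <= self.mean <= self.high:
            raise ParameterError(
                f"{self.parameter_name}: need low <= mean <= high, "
                f"got {self.low}, {self.mean}, {self.high}"
            )


# (field, family); the printed ranges are mean ± 20% for every row.
_PSA_FAMILIES = (
    ("p_improved_y1", "beta"),
    ("p_complication_y1", "beta"),
    ("p_deteriorated_y1", "beta"),
    ("p_complication", "beta"),
    ("p_improved_after_complication", "beta"),
    ("p_deteriorated", "beta"),
    ("excess_mort_deteriorated", "beta"),
    ("p_residential_shunt", "uniform"),
    ("p_homeservice_shunt", "uniform"),
    ("p_informal_shunt", "uniform"),
    ("p_residential_nh", "uniform"),
    ("p_daycare_nh", "uniform"),
    ("c_surgery", "gamma"),
    ("c_inpatient", "gamma"),
    ("c_outpatient", "gamma"),
    ("c_residential", "gamma"),
    ("c_homeservice_shunt", "gamma"),
    ("c_homeservice_nh", "gamma"),
    ("c_daycare_nh", "gamma"),
    ("c_informal_shunt", "gamma"),
    ("c_informal_nh", "gamma"),
    ("u_improved", "beta"),
    ("u_poor", "beta"),
)


def default_distribution_specs(params: ParameterSet) -> list[DistributionSpec]:
    """The packaged uncertain-parameter list: ±20% ranges around the base case.

    Draws are consumed in exactly this order, which makes PSA replicates
    reproducible for a given seed.
    """
    specs = []
    for name, family in _PSA_FAMILIES:
        mean = float(getattr(params, name))
        specs.append(
            DistributionSpec(name, family, mean, 0.8 * mean, 1.2 * mean)
        )
    return specs


def _spec_sd(spec: DistributionSpec, sd_rule: str) -> float:
    if sd_rule == "ci95":
        return (spec.high - spec.mean) / 1.959963984540054
    if sd_rule == "range4":
        return (spec.high - spec.low) / 4.0
    raise ParameterError(f"unknown sd_rule {sd_rule!r}")


def concretize_distribution(spec: DistributionSpec, sd_rule: str = "ci95") -> dict:
    """Turn a (mean, range) pair into family-specific parameters.

    The analytic mean always equals ``spec.mean``. For beta/gamma the SD is
    set from the range (95% interval by default, method of moments); a
    degenerate range returns a point mass.
    """
    if spec.family == "fixed":
        raise ParameterError("fixed parameters have no distribution")
    if spec.high == spec.low:
        return {"family": "point", "value": spec.mean}
    if spec.family == "uniform":
        return {"family": "uniform", "low": spec.low, "high": spec.high}
    sd = _spec_sd(spec, sd_rule)
    if spec.family == "gamma":
        shape = (spec.mean / sd) ** 2
        return {"family": "gamma", "shape": shape, "scale": spec.mean / shape}
    if spec.family == "beta":
        if not 0.0 < spec.mean < 1.0:
            raise ParameterError(
                f"{spec.parameter_name}: beta mean {spec.mean} outside (0, 1)"
            )
        # Method of moments; variance must stay below mean(1-mean).
        var = sd * sd
        nu = spec.mean * (1.0 - spec.mean) / var - 1.0
        if nu <= 0:
            raise ParameterError(
                f"{spec.parameter_name}: range too wide for a beta with this mean"
            )
        return {"family": "beta", "a": spec.mean * nu, "b": (1.0 - spec.mean) * nu}
    raise ParameterError(f"unknown family {spec.family!r}")


def distribution_mean(params: dict) -> float:
    """Analytic mean of a concretized distribution."""
    fam = params["family"]
    if fam == "point":
        return params["value"]
    if fam == "uniform":
        return 0.5 * (params["low"] + params["high"])
    if fam == "gamma":
        return params["shape"] * params["scale"]
    if fam == "beta":
        return params["a"] / (params["a"] + params["b"])
    raise ParameterError(f"unknown family {fam!r}")


def sample_distribution(params: dict, rng, size=None):
    """Draw from a concretized distribution with a numpy Generator."""
    fam = params["family"]
    if fam == "point":
        import numpy as np

        return params["value"] if size is None else np.full(size, params["value"])
    if fam == "uniform":
        return rng.uniform(params["low"], params["high"], size)
    if fam == "gamma":
        return rng.gamma(params["shape"], params["scale"], size)
    if fam == "beta":
        return rng.beta(params["a"], params["b"], size)
    raise ParameterError(f"unknown family {fam!r}")
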