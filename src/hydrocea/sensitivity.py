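"""One-way scenario analysis and probabilistic sensitivity analysis.

One-way scenarios substitute single parameter values (or the perspective, or
the discount rate) into the base case and re-run the full two-arm pipeline on
the fixed calibrated life table. The packaged scenario list varies the excess
mortality of untreated/deteriorated patients (0.08/0.12), the residential-care
and untreated informal-care costs (±20%), both utility weights (±20%), the
perspective, and the discount rate (0%/5%).

The PSA draws every uncertain parameter independently from its assigned
distribution (beta for probabilities and utilities, gamma for costs, uniform
for support proportions; ranges ±20% around the mean), re-evaluates the model
per replicate, and summarises cost-effectiveness as the fraction of replicates
with non-negative net monetary benefit at a willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import CEAResult, evaluate
from .parameters import (
    DistributionSpec,
    ParameterSet,
    concretize_distribution,
    default_distribution_specs,
    sample_distribution,
)

__all__ = [
    "ScenarioOverride",
    "PSAResultSet",
    "default_one_way_scenarios",
    "run_scenario",
    "one_way_table",
    "psa_draw",
    "run_psa",
    "acceptability",
    "ceac",
]

_FIRST_YEAR_TRIPLE = ("p_improved_y1", "p_complication_y1", "p_deteriorated_y1")
_UTILITY_FIELDS = ("u_improved", "u_poor")


@dataclass(frozen=True)
class ScenarioOverride:
    name: str
    overrides: dict = field(default_factory=dict)
    perspective: str | None = None


def default_one_way_scenarios() -> list[ScenarioOverride]:
    """The packaged scenario list (13 rows)."""
    return [
        ScenarioOverride("excess mortality 8%", {"excess_mort_deteriorated": 0.08}),
        ScenarioOverride("excess mortality 12%", {"excess_mort_deteriorated": 0.12}),
        ScenarioOverride("residential care -20%", {"c_residential": 48_480.0}),
        ScenarioOverride("residential care +20%", {"c_residential": 72_720.0}),
        ScenarioOverride("informal care (untreated) -20%", {"c_informal_nh": 8_400.0}),
        ScenarioOverride("informal care (untreated) +20%", {"c_informal_nh": 12_600.0}),
        ScenarioOverride("utility improved -20%", {"u_improved": 0.57}),
        ScenarioOverride("utility improved +20%", {"u_improved": 0.85}),
        ScenarioOverride("utility deteriorated -20%", {"u_poor": 0.45}),
        ScenarioOverride("utility deteriorated +20%", {"u_poor": 0.69}),
        ScenarioOverride("healthcare perspective", {}, perspective="healthcare"),
        ScenarioOverride("discount rate 0%", {"discount_rate": 0.0}),
        ScenarioOverride("discount rate 5%", {"discount_rate": 0.05}),
    ]


def run_scenario(base: ParameterSet, override: ScenarioOverride,
                 life_table) -> CEAResult:
    """Full two-arm comparison under substituted parameters.

    The life table stays fixed: mortality overrides change only the excess or
    multiplier, never the calibration.
    """
    params = base.replace(**override.overrides)
    perspective = override.perspective or "societal"
    _, _, cea = evaluate(params, life_table, perspective)
    return cea


def one_way_table(base: ParameterSet, scenarios: list[ScenarioOverride],
                  life_table) -> pd.DataFrame:
    """One row per scenario (base case first), Table-style columns."""
    rows = []
    for sc in [ScenarioOverride("base case", {})] + list(scenarios):
        cea = run_scenario(base, sc, life_table)
        rows.append({
            "scenario": sc.name,
            "incremental_cost": cea.incremental_cost,
            "incremental_qaly": cea.incremental_qaly,
            "incremental_life_years": cea.incremental_life_years,
            "icer": cea.icer,
            "perspective": cea.perspective,
        })
    return pd.DataFrame(rows)


def psa_draw(base: ParameterSet, specs: list[DistributionSpec], rng) -> ParameterSet:
    """One random parameter set.

    Draws are consumed in the order of ``specs`` (one per spec, even for
    fixed parameters nothing is consumed), so replicate streams are
    reproducible. The first-year outcome split is renormalised if the drawn
    probabilities sum above 1 (the perioperative-death residual then becomes
    0); utilities are clamped to [0, 1].
    """
    values = {}
    for spec in specs:
        if spec.family == "fixed":
            values[spec.parameter_name] = spec.mean
            continue
        conc = concretize_distribution(spec, base.sd_rule)
        v = float(sample_distribution(conc, rng))
        if spec.parameter_name in _UTILITY_FIELDS:
            v = min(max(v, 0.0), 1.0)
        values[spec.parameter_name] = v
    tri = [values.get(k, getattr(base, k)) for k in _FIRST_YEAR_TRIPLE]
    s = sum(tri)
    if s > 1.0:
        for k, v in zip(_FIRST_YEAR_TRIPLE, tri):
            values[k] = v / s
    # Transitions out of Improved must leave a non-negative stay probability.
    pc = values.get("p_complication", base.p_complication)
    pd_ = values.get("p_deteriorated", base.p_deteriorated)
    s2 = pc + pd_
    if s2 > 1.0:
        values["p_complication"] = pc / s2
        values["p_deteriorated"] = pd_ / s2
    return base.replace(**values)


@dataclass(frozen=True)
class PSAResultSet:
    replicates: pd.DataFrame  # columns: incremental_cost, incremental_qaly
    seed: int
    n: int

    def __post_init__(self) -> None:
        if len(self.replicates) != self.n:
            raise ValueError("replicate count does not match n")


def run_psa(base: ParameterSet, specs: list[DistributionSpec] | None,
            n: int, seed: int, life_table,
            perspective: str = "societal") -> PSAResultSet:
    """Monte Carlo uncertainty analysis: n full-model evaluations."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if specs is None:
        specs = default_distribution_specs(base)
    rng = np.random.default_rng(seed)
    rows = np.empty((n, 3))
    for i in range(n):
        drawn = psa_draw(base, specs, rng)
        _, _, cea = evaluate(drawn, life_table, perspective)
        rows[i] = (cea.incremental_cost, cea.incremental_qaly,
                   cea.incremental_life_years)
    df = pd.DataFrame(rows, columns=["incremental_cost", "incremental_qaly",
                                     "incremental_life_years"])
    df.insert(0, "replicate", np.arange(n))
    return PSAResultSet(replicates=df, seed=seed, n=n)


def acceptability(results: PSAResultSet, wtp: float) -> float:
    """Probability of cost-effectiveness at a willingness-to-pay threshold.

    Net-monetary-benefit rule: the fraction of replicates with
    wtp * dQALY - dCost >= 0.
    """
    df = results.replicates
    nmb = wtp * df["incremental_qaly"].to_numpy() - df["incremental_cost"].to_numpy()
    return float(np.mean(nmb >= 0.0))


def ceac(results: PSAResultSet, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    if wtp_grid is None:
        wtp_grid = np.arange(0, 50_001, 1_000)
    return pd.DataFrame({
        "wtp": wtp_grid,
        "probability_cost_effective": [acceptability(results, w) for w in wtp_grid],
    })
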