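"""Lifelong cost-utility analysis of shunt surgery in idiopathic normal
pressure hydrocephalus: a Markov cohort model with calibrated background
mortality, EQ-5D-3L utility scoring, one-way and probabilistic sensitivity
analysis, and a synthetic patient-survey generator."""

from .demography import (
    CalibrationError,
    GompertzParams,
    LifeTable,
    calibrate_mortality,
    gompertz_life_table,
)
from .economics import (
    ArmResult,
    CEAResult,
    accumulate,
    compare,
    discounted_sum,
    evaluate,
    first_cycle_cost,
    state_annual_cost,
)
from .eq5d import EQ5DProfile, enumerate_value_set, eq5d_index_uk
from .markov import CohortTrace, State, annual_death_prob, build_transition_matrix, run_cohort
from .parameters import (
    DistributionSpec,
    ParameterError,
    ParameterSet,
    concretize_distribution,
    default_distribution_specs,
    load_parameters,
)
from .sensitivity import (
    PSAResultSet,
    ScenarioOverride,
    acceptability,
    ceac,
    default_one_way_scenarios,
    one_way_table,
    psa_draw,
    run_psa,
    run_scenario,
)
from .survey import (
    PatientRecord,
    SurveyGeneratorConfig,
    estimate_support_probabilities,
    estimate_utilities,
    generate_patients,
    value_informal_care,
)

__version__ = "0.1.0"

#: Discounted life years of the untreated arm used as the calibration anchor.
CALIBRATION_TARGET_LY = 4.42


def calibrated_life_table(params: ParameterSet | None = None,
                          target: float = CALIBRATION_TARGET_LY) -> LifeTable:
    """Calibrate the Gompertz fixture and return the resulting life table."""
    if params is None:
        params = ParameterSet()
    gp = calibrate_mortality(target, params)
    return gompertz_life_table(gp, params.start_age, params.max_age)
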