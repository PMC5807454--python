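# Methods

## Model structure

The model is a discrete-time Markov cohort simulation with annual cycles,
run from age 70 to a horizon of age 105 (36 cycles; survivorship beyond is
negligible, and the terminal death probability is forced to 1 so the horizon
closes). Two arms are compared per patient:

* **Shunt arm**, states: Surgery year → {Improved, Complication,
  Deteriorated, Dead}. Cycle 0 is the operation year: the cohort leaves the
  surgery state according to the first-year outcome split (0.73 / 0.15 /
  0.10), and the unallocated residual (0.02) is treated as perioperative
  death; background mortality is not applied a second time in that cycle.
  From Improved, each later year: death first, then surviving patients move
  to Complication (0.02) or Deteriorated (0.10) or stay. Complication is a
  one-cycle tunnel: survivors recover to Improved (0.70) or deteriorate
  (0.30). Deteriorated patients stay until death.
* **Natural-history arm**: one living state plus Dead.

Death is resolved before among-living transitions within each cycle
(a convention that must be fixed; it is applied uniformly to both arms).

## Mortality

Background mortality is a Gompertz fixture `h(a) = level · exp(0.095·a)`
(no Makeham term). Annual probabilities come from the closed-form hazard
integral, `q(a) = 1 − exp(−∫ h)`. The level is calibrated by bisection so the
natural-history arm's discounted life expectancy equals 4.42 years; the
calibrated level is 2.90e−5, giving q(70) = 0.023 — close to Nordic
general-population values, which is a useful sanity check on the fixture.
Calibration is performed once on the base case; scenario and PSA runs reuse
the fixed life table.

All living states carry a 2.5× mortality multiplier applied on the hazard
scale, `q* = 1 − (1 − q)^2.5`. Deteriorated and natural-history patients add
a further 10-point annual risk. Two compositions of that excess are
implemented:

* `additive` (default): `q_det = min(q* + 0.10, 1)`;
* `independent`: `q_det = 1 − (1 − q*)(1 − 0.10)`.

The additive reading is the default because, with everything else held at
the base case, it reproduces the published incremental life years (2.25
modelled vs 2.17 printed) where the independent composition falls short
(1.77); it is also the plainer reading of "an additional 10% risk of
mortality".

## Counting conventions

Costs, life years and QALYs are accumulated with a half-cycle correction:
state membership in cycle t is the average of the occupancies at the cycle's
start and end, discounted by `(1+r)^−t` with r = 0.03 for both costs and
effects. The one-off surgical episode is a point cost at t = 0 and is not
halved. Half-cycle correction is the default because the printed two-arm
results are matched closely under it (shunt arm 6.67 LY / 4.34 QALY / EUR
173,221 modelled vs 6.60 / 4.25 / 173,000 printed) and systematically
undershot without it; cycle-start counting remains available
(`half_cycle_correction: false`).

## Costs

Annual euro costs per state are composed from the care mix and unit costs:

| state | composition | base value |
|---|---|---|
| Natural history, Deteriorated, Surgery year | 0.42·60,600 + 0.58·(6,900 + 10,500) + 0.06·9,900 | 36,138 |
| Improved | 0.07·60,600 + 0.23·5,200 + 0.60·6,600 + 3,900 + 1,700 | 14,998 |
| Complication | Improved + 10,200 (revision episode) | 25,198 |

plus a one-off surgery-year episode of 10,200 + 3,900 + 1,700 = 15,800 in
cycle 0 of the shunt arm. Three compositional choices deserve note, since
the published unit costs do not uniquely determine the state costs:

* the inpatient (3,900) and outpatient (1,700) costs are annual follow-up
  costs of shunt-treated patients (they were measured as annual costs in the
  patient survey), so Improved carries them every year;
* a complication year adds one revision episode valued at the surgery cost —
  complications were defined as events needing intervention;
* during the surgery year the cohort still requires its pre-treatment
  (natural-history) level of formal and informal support; improvement takes
  effect from cycle 1.

Together these reproduce the published lifetime totals; costing the
complication year or the surgery year more leanly pushes the incremental
cost well below the printed value (to the point of making surgery
cost-saving), which the published totals rule out.

The **societal perspective** (default) counts everything above. The
**healthcare perspective** removes informal care only (the 0.58·10,500 term
of the untreated mix and the 0.60·6,600 term of the post-surgery mix),
keeping publicly financed residential care, home service and day care: this
inclusion set reproduces the published healthcare-perspective increment
(EUR 8,435 modelled vs 7,400 printed); dropping municipal formal care as well
would leave the increment at least the full surgical episode (≥ 15,800),
which that result excludes.

## Utilities

State utilities are flat EQ-5D-3L means: 0.71 for Improved, 0.57 for every
other living state (surgery year included). With flat weights the
natural-history arm's QALYs are exactly 0.57 × discounted LY, consistent
with the published arithmetic. An optional multiplicative age adjustment
(`age_adjust_utilities`) scales utilities by a linear-decline population-norm
fixture (−0.4%/year relative to age 70, a synthetic stand-in for national
age norms); it is off by default because the flat weights already reproduce
the published results.

The scorer implements the UK time-trade-off value set as data
(`data/uk_tto_coefficients.csv`): 1 minus a constant for any departure from
full health, per-dimension level decrements, and an N3 term when any
dimension is at level 3; range [−0.594, 1].

## Sensitivity analysis

One-way scenarios substitute single values (excess mortality 0.08/0.12,
residential and untreated informal-care costs ±20%, both utilities ±20%,
healthcare perspective, discount 0%/5%) and re-run the full pipeline on the
fixed life table. The residential-care and untreated-informal-care rows of
the published scenario table imply mutually inconsistent deteriorated-state
exposures under any linear accounting, so for the cost rows the package's
tests assert direction and the ICER identity rather than point values; the
healthcare-perspective and 0%-discount rows are reproduced numerically.

The PSA draws all 23 uncertain parameters independently, in a fixed
documented order from one seeded generator (numpy PCG64), so replicate *i*
is reproducible:

* beta for probabilities and utilities, gamma for costs — method of moments
  with SD = (high − mean)/1.96, i.e. the ±20% range read as a 95% interval
  (alternative `sd_rule: range4` uses SD = range/4);
* uniform on [0.8·mean, 1.2·mean] for the observed support proportions;
* the first-year outcome triple is renormalised when a draw sums above 1
  (the perioperative residual then becomes 0), and utilities are clamped to
  [0, 1]. The 2.5× multiplier and the discount rate are fixed in the PSA
  (no distribution is assigned to them).

Acceptability at a willingness-to-pay threshold is the fraction of
replicates with non-negative net monetary benefit, `wtp·ΔQALY − ΔC ≥ 0`,
which handles dominant and dominated quadrants coherently. The default run
uses 5,000 replicates (≈ 8 s on one core).

## Synthetic survey generator

`hydrocea.survey` emulates the 30-patient survey that produced the support
mix, care hours and utility inputs: ages 65–89 with median 71 (truncated
exponential), support category multinomial (2/30 residential, 7/30 home
service, 18/30 informal support, remainder none), gamma-distributed care
hours whose means are back-solved from the printed annual costs (≈ 2.6
h/week home service at EUR 38/h, ≈ 8.5 h/week informal care at EUR 15/h;
untreated patients correspond to 0.5 h/day formal and 1.9 h/day informal
care), HRQoL improvement in 83%, and EQ-5D profiles chosen by drawing a
target utility from a winsorised normal (means 0.57 pre / 0.71 post) and
picking uniformly among the 243 legal profiles with the nearest tariff
index, constrained to not-worse (not-better) post-operative profiles for
improved (non-improved) patients. Six-month totals are annualised by
doubling.

The generator matches the survey's marginal summaries; it does not model
covariance between age, utility and care need, sex, or instrument scores
(MMSE, iNPH scale), so passing round-trip tests demonstrates estimator
correctness on data with the published structure, not validity on real
patients.

## Numerical choices and degenerate inputs

* Transition-matrix rows are validated to sum to 1 within 1e−9; occupancy
  mass is conserved within 1e−10; dead fraction is non-decreasing.
* Cohort propagation stops early once living mass falls below 1e−9.
* The ICER is reported as undefined when |ΔQALY| ≤ 1e−9.
* Calibration brackets the Gompertz level in [1e−9, 5e−2] and reports the
  achievable range when the target lies outside it; the achieved life
  expectancy is within 5e−3 years of the target.
* Degenerate PSA ranges (high = low) are point masses; a beta whose ±20%
  range is infeasible for its mean raises an error rather than silently
  truncating.

## Problem sizes

Default runs use 36 annual cycles per arm, 5,000 PSA replicates, and
n = 5,000 synthetic patients for generator round-trip checks; the full test
suite completes in well under a minute on one core.

## Known limitations

* The two cost-scenario rows noted above cannot both be matched by any
  linear cost model; the package reproduces their directions.
* The complication-state cost is constrained, not pinned, by the published
  totals; it is built only from printed unit costs and is varied through
  them in the PSA.
* The life table and age-norm fixtures are parametric stand-ins, not
  national statistics; all mortality-dependent outputs are conditional on
  the 4.42-year calibration anchor.
* PSA parameters are sampled independently (no Dirichlet joint for the
  first-year triple, no cost correlations).
* Caregiver utilities and patient production losses are out of scope
  (retired cohort).
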