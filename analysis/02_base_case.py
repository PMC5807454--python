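#!/usr/bin/env python
"""Deterministic base case: lifetime costs, life years, QALYs and the ICER.

Runs both arms (shunt surgery vs untreated natural history) on the calibrated
life table from age 70 with 3% annual discounting and a societal perspective,
and writes the two-arm results table to results/base_case.csv.
"""

from pathlib import Path

import pandas as pd

from hydrocea import ParameterSet, calibrated_life_table, evaluate

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = ParameterSet()
    lt = calibrated_life_table(params)
    shunt, nh, cea = evaluate(params, lt)
    df = pd.DataFrame([
        {"option": "shunt", "cost_eur": shunt.discounted_cost,
         "life_years": shunt.discounted_life_years, "qaly": shunt.discounted_qaly},
        {"option": "natural_history", "cost_eur": nh.discounted_cost,
         "life_years": nh.discounted_life_years, "qaly": nh.discounted_qaly},
    ])
    df.round(2).to_csv(OUT / "base_case.csv", index=False)
    print(df.round(2).to_string(index=False))
    print(f"\nincremental cost      : {cea.incremental_cost:10,.0f} EUR")
    print(f"incremental life years: {cea.incremental_life_years:10.2f}")
    print(f"incremental QALYs     : {cea.incremental_qaly:10.2f}")
    print(f"ICER                  : {cea.icer:10,.0f} EUR/QALY")
    print(f"cost per life year    : {cea.cost_per_ly:10,.0f} EUR/LY")
    print(f"\nwrote {OUT / 'base_case.csv'}")


if __name__ == "__main__":
    main()
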