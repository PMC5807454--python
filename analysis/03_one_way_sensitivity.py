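#!/usr/bin/env python
"""One-way sensitivity analysis.

Re-runs the base case substituting one assumption at a time: the excess
mortality of untreated/deteriorated patients (8%/12%), residential-care and
untreated informal-care costs (+-20%), the two utility weights (+-20%), a
healthcare perspective (informal care excluded), and 0%/5% discounting.
Writes results/one_way.csv.
"""

from pathlib import Path

from hydrocea import ParameterSet, calibrated_life_table
from hydrocea.sensitivity import default_one_way_scenarios, one_way_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = ParameterSet()
    lt = calibrated_life_table(params)
    table = one_way_table(params, default_one_way_scenarios(), lt)
    table.round(2).to_csv(OUT / "one_way.csv", index=False)
    show = table[["scenario", "incremental_cost", "incremental_qaly", "icer"]].round(
        {"incremental_cost": 0, "incremental_qaly": 2, "icer": 0})
    print(show.to_string(index=False))
    print(f"\nwrote {OUT / 'one_way.csv'}")


if __name__ == "__main__":
    main()
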