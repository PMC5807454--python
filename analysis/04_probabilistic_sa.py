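#!/usr/bin/env python
"""Probabilistic sensitivity analysis.

Draws every uncertain parameter from its assigned distribution (beta for
probabilities/utilities, gamma for costs, uniform for support proportions;
all ranges +-20%) and re-evaluates the model 5,000 times. Writes the
cost-effectiveness plane points, the acceptability curve over willingness to
pay, and the acceptability at the two published thresholds.
"""

import argparse
from pathlib import Path

from hydrocea import ParameterSet, calibrated_life_table
from hydrocea.sensitivity import acceptability, ceac, run_psa

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--n", type=int, default=5000)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    OUT.mkdir(exist_ok=True)
    params = ParameterSet()
    lt = calibrated_life_table(params)
    res = run_psa(params, None, args.n, args.seed, lt)
    res.replicates.round(4).to_csv(OUT / "ce_plane.csv", index=False)
    ceac(res).round(4).to_csv(OUT / "ceac.csv", index=False)
    lo = acceptability(res, params.wtp_lower)
    hi = acceptability(res, params.wtp_upper)
    print(f"n = {args.n}, seed = {args.seed}")
    print(f"mean incremental cost : {res.replicates['incremental_cost'].mean():10,.0f} EUR")
    print(f"mean incremental QALY : {res.replicates['incremental_qaly'].mean():10.2f}")
    print(f"P(cost-effective) at {params.wtp_lower:,.0f} EUR/QALY: {lo:.1%}")
    print(f"P(cost-effective) at {params.wtp_upper:,.0f} EUR/QALY: {hi:.1%}")
    print(f"\nwrote {OUT / 'ce_plane.csv'} and {OUT / 'ceac.csv'}")


if __name__ == "__main__":
    main()
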