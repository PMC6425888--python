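#!/usr/bin/env python
"""Sweep site marginality and measure between-provenance differentiation.

Holding the provenance list and climate fixed, the trial is re-simulated
along a 5-point marginality grid; for each point the full chain
(detrend → prewhiten → pairwise PCGA → rank-sum) is run and the fraction
of significantly separated provenance pairs recorded.  The resulting curve
is the package's central claim in one table: differentiation is
non-increasing in marginality.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dendroprov.experiments import marginality_scores, scenario_scores


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-seeds", type=int, default=10)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    grid = (0.0, 0.25, 0.5, 0.75, 1.0)
    seeds = [args.seed + 1000 * i for i in range(args.n_seeds)]
    scores = marginality_scores(grid, seeds)
    df = pd.DataFrame({"marginality": grid, "differentiation_score": scores})
    df.to_csv(args.out / "marginality_sweep.csv", index=False)
    print(df.to_string(index=False))
    mono = np.all(np.diff(scores) <= 1e-9)
    print(f"non-increasing along the grid: {bool(mono)}")

    wins = 0
    for s in seeds:
        sc = scenario_scores(s)
        wins += sc["uniform-marginal"] < sc["divergent-mild"]
    print(f"marginal < mild in {wins}/{len(seeds)} paired seeds")


if __name__ == "__main__":
    main()
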