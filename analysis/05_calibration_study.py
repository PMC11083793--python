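#!/usr/bin/env python
"""Replicated simulation study: bias, RMSE and CrI coverage of the contrasts.

Simulates 20-study 4-treatment binary networks at known truth
(d = 0, log 1.5, log 0.8 against the reference; tau = 0.1), refits each with
a reduced-length chain, and tabulates per-contrast bias, RMSE and 95% CrI
coverage.  The skeptical prior makes coverage conservative (expected in the
90-99% range) and biases small relative to the effect sizes.

Writes results/calibration/recovery.csv.
"""

import argparse
import math
from pathlib import Path

from armnma import SamplerConfig, SimulationTruth, recovery_experiment

OUT = Path(__file__).resolve().parent.parent / "results" / "calibration"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=100)
    ap.add_argument("--reps", type=int, default=50)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C")]
    truth = SimulationTruth(
        treatments=["A", "B", "C", "D"],
        d_true=[0.0, math.log(1.5), math.log(0.8)],
        tau_true=0.1,
        designs=[(pairs[i % 4], (300, 300)) for i in range(20)],
        baseline_beta=(30.0, 170.0),
        seed=args.seed,
    )
    cfg = SamplerConfig(iterations=2000, burn_in=700, thin=2, chains=1,
                        seed=args.seed + 1)
    tab = recovery_experiment(truth, n_reps=args.reps, cfg=cfg)
    tab.to_csv(OUT / "recovery.csv", index=False)
    print(tab.to_string(index=False))
    d_rows = tab[tab.parameter.str.startswith("d")]
    print(f"\nmax |bias| {d_rows.bias.abs().max():.3f} log-RR; "
          f"coverage range {d_rows.coverage.min():.2f}-{d_rows.coverage.max():.2f} "
          f"over {args.reps} replicates")


if __name__ == "__main__":
    main()
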