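#!/usr/bin/env python
"""Generate synthetic outcome networks on the fixture geometry.

The trial-level event counts behind the published league tables were never
released, so downstream fitting runs on synthetic networks drawn from the
hierarchical model on the same 10-trial geometry, with baseline risks
emulating the published per-group crude rates (anastomotic leak ~1.2%,
severe complications ~6%, in-hospital mortality ~0.3%) and null treatment
contrasts, which is what the published analysis concluded.

Writes results/simulated_data/<outcome>.csv plus truth.json.
"""

import argparse
import json
from pathlib import Path

from armnma import trial_network_truth, simulate_network, write_network

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated_data"

# outcome -> beta hyper-prior of the per-study baseline risk (mean ~ crude rate)
OUTCOMES = {
    "anastomotic_leak": (1.5, 120.0),
    "severe_complications": (3.0, 47.0),
    "in_hospital_mortality": (0.6, 150.0),
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20240423)
    ap.add_argument("--tau", type=float, default=0.1)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    manifest = {}
    for i, (name, beta) in enumerate(OUTCOMES.items()):
        truth = trial_network_truth(
            seed=args.seed % (2**31) + i, tau_true=args.tau,
            baseline_beta=beta, outcome_name=name,
        )
        ds = simulate_network(truth)
        write_network(ds, OUT / f"{name}.csv")
        crude = {
            g: round(100.0 * sum(a.events for a in ds.arms if a.treatment == g)
                     / sum(a.total for a in ds.arms if a.treatment == g), 2)
            for g in truth.treatments
        }
        manifest[name] = {
            "seed": truth.seed, "tau_true": truth.tau_true,
            "d_true": list(truth.d_true), "baseline_beta": beta,
            "crude_rates_pct": crude,
        }
        print(f"{name}: crude per-group rates {crude}")
    (OUT / "truth.json").write_text(json.dumps(manifest, indent=2))
    print(f"\nwrote {len(OUTCOMES)} arm tables under {OUT}")


if __name__ == "__main__":
    main()
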