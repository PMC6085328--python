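#!/usr/bin/env python
"""Simulate paired flash-photolysis experiments at 445 and 605 nm.

Generates one pmf-off (uncoupled: 0 mV, 0 pH) and one pmf-on (energized
vesicle: 100 mV, 0.4 pH units) synthetic experiment with the default scheme
and σ = 0.002 ΔA noise, and writes the four traces plus their ground truth
under results/traces/.  The on-condition trace pair is where the story lives:
at 445 nm the slow (~5 ms) decay loses the catalytic-site contribution and
the trace stays elevated after 10 ms, while at 605 nm (heme a) the two
conditions nearly coincide.
"""

import argparse
import json
from pathlib import Path

from flowflash import FlashTraceConfig, generate_paired_condition_traces

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=Path,
                        default=ROOT / "results" / "traces")
    args = parser.parse_args()

    pairs = generate_paired_condition_traces(FlashTraceConfig(),
                                             replicates=1, seed=args.seed)
    args.outdir.mkdir(parents=True, exist_ok=True)
    for condition in ("off", "on"):
        for wl, trace in pairs[condition][0].items():
            truth = trace.metadata.pop("ground_truth")
            name = f"trace_{condition}_{int(wl)}nm"
            trace.to_csv(args.outdir / f"{name}.csv")
            with open(args.outdir / f"{name}.truth.json", "w") as fh:
                json.dump(truth, fh, indent=2)
            late = trace.values[trace.times >= 1e-2]
            print(f"{name}: ΔA(10 ms..) mean = {late.mean():+.4f} "
                  f"(τ_F_R->O = {truth['taus_s']['F_R->O'] * 1e3:.2f} ms)")
    print(f"wrote 4 traces + ground truth to {args.outdir}")


if __name__ == "__main__":
    main()
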