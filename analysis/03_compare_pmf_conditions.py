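#!/usr/bin/env python
"""Measure the pmf-induced decrease of the 5-ms component amplitude.

Runs ten seeded replicate pairs of the paired flash experiment at each
wavelength, fits three exponentials, and compares the 5-ms component
amplitudes between the pmf-off and pmf-on conditions.  The expected outcome:
a ~14% decrease at 445 nm — matching the coefficient arithmetic
100·10/(60+10) = 14.3% for a cycle that terminates in F_R — against only a
~5% decrease at 605 nm, where heme a dominates and the catalytic site
contributes just ~5% of the heme-a signal.  That contrast is the evidence
that the membrane potential blocks the final proton uptake (F_R → O) but not
electron transfer to the site (F → F_R).
"""

import argparse
import json
from pathlib import Path

from flowflash import expected_amplitude_decrease, paired_amplitude_comparison

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--replicates", type=int, default=10)
    parser.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    args.outdir.mkdir(parents=True, exist_ok=True)
    summary = {"expected_decrease_445_percent":
               expected_amplitude_decrease(60.0, 10.0)}
    # components per wavelength follow the resolvable phases: 445 nm shows a
    # merged fast phase, the 100-µs phase and the 5-ms phase; at 605 nm only
    # the fast and 5-ms phases carry amplitude
    for wl, n_components in ((445.0, 3), (605.0, 2)):
        res = paired_amplitude_comparison(replicates=args.replicates,
                                          seed=args.seed, wavelength=wl,
                                          n_components=n_components)
        res.table.to_csv(args.outdir / f"amplitude_comparison_{int(wl)}nm.csv",
                         index=False)
        summary[f"mean_decrease_{int(wl)}nm_percent"] = res.mean_decrease
        summary[f"sd_decrease_{int(wl)}nm_percent"] = res.sd_decrease
        print(f"{int(wl)} nm: 5-ms amplitude decrease = "
              f"{res.mean_decrease:.1f} ± {res.sd_decrease:.1f}% "
              f"({args.replicates} replicate pairs)")
    print(f"coefficient arithmetic predicts "
          f"{summary['expected_decrease_445_percent']:.1f}% at 445 nm")
    with open(args.outdir / "amplitude_comparison_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    print(f"wrote tables + summary to {args.outdir}")


if __name__ == "__main__":
    main()
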