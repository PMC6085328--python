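# flowflash

Kinetic and spectroscopic analysis of the reaction of reduced cytochrome *c*
oxidase (CytcO) with O₂ in energized membranes — for bioenergeticists who
want to ask, quantitatively, which step of the catalytic cycle a
transmembrane proton-motive force (pmf) blocks.

In the flow-flash experiment the CO-blocked, four-electron-reduced enzyme is
mixed with O₂ and the reaction is started by laser photolysis; absorbance at
445 nm (hemes *a* + *a*₃) and 605 nm (mainly heme *a*) then tracks the
oxidative burst

    R → A → P_R → F → F_R → O
      10 µs·(1mM/[O₂])  30 µs  100 µs  5 ms  0.5 ms

Each step is first order; electrogenic steps are attenuated by the pmf
Δp = ΔΨ + 59.16·ΔpH (mV) through k = k₀·exp(−q·F·Δp/RT). With q = 1 on
F_R → O only, an energized membrane (ΔΨ ≈ 100 mV, ΔpH ≈ 0.4) stretches the
F_R lifetime from 0.5 ms to ~62 ms: electrons still reach the catalytic site
on the 5-ms time scale (F → F_R), but the final proton uptake (F_R → O) is
blocked. The observable consequence — and the analysis this package
automates — is that the 5-ms kinetic component at 445 nm loses the
catalytic-site contribution, 100·ε_site/(ε_heme_a + ε_site) =
100·10/(60+10) ≈ 14%, while at 605 nm (site share only ~5% of heme *a*) the
amplitude barely changes.

The package provides:

* `flowflash.cycle_kinetics` — reaction scheme, pmf arithmetic, rate-matrix
  assembly, exact master-equation propagation (+ an independent ODE oracle);
* `flowflash.spectral_model` — per-state absorption-coefficient tables and
  Beer–Lambert projection to ΔA traces;
* `flowflash.trace_fitting` — seeded, multistart, separable least-squares
  multi-exponential fitting; component naming by nominal τ; amplitude
  comparisons;
* `flowflash.potential_calibration` — Nernst potentials, dye-calibration
  lines, potential estimation, O₂-electrode slopes and respiratory control
  ratio (RCR);
* `flowflash.synthetic_data` — seeded generators for every input (flash
  trace pairs, calibration ladders, O₂ traces) with ground-truth sidecars;
* `flowflash.workflows` — the end-to-end paired-condition protocols;
* a `flowflash` CLI (`simulate`, `fit`, `compare`, `calibrate`, `nernst`,
  `rcr`).

## Worked example

```python
from flowflash import (FlashTraceConfig, expected_amplitude_decrease,
                       paired_amplitude_comparison, pmf, scale_rate_for_pmf)

# the driving force and the blocked step
dp = pmf(100.0, 0.4)                        # 123.66 mV
k = scale_rate_for_pmf(2000.0, 1.0, dp)     # 16.24 1/s
print(f"F_R lifetime under pmf: {1e3 / k:.1f} ms")

# the coefficient arithmetic ...
print(f"predicted 5-ms amplitude loss: "
      f"{expected_amplitude_decrease(60.0, 10.0):.1f} %")

# ... versus the full simulated experiment: 10 paired replicates,
# 3-exponential fits, 5-ms component amplitudes
res = paired_amplitude_comparison(replicates=10, seed=1)
print(f"measured: {res.mean_decrease:.1f} ± {res.sd_decrease:.1f} %")
```

prints

```
F_R lifetime under pmf: 61.6 ms
predicted 5-ms amplitude loss: 14.3 %
measured: 14.9 ± 2.1 %
```

i.e. the end-to-end pipeline (simulate → project → fit → compare) recovers
the ~14% amplitude decrease that the absorption-coefficient ratio predicts
for a cycle that terminates in F_R instead of O.

The numbered drivers under `analysis/` narrate the same story over files:

```sh
python analysis/01_simulate_flash_traces.py    # paired 445/605-nm traces
python analysis/02_fit_flash_components.py     # per-trace components table
python analysis/03_compare_pmf_conditions.py   # the 14%-vs-5% contrast
python analysis/04_dye_calibration_and_rcr.py  # Nernst ladder, RCR ~1.3
```

with tables and JSON summaries written under `results/`.

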