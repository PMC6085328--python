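# Methods

## The kinetic model

The oxidative half of the cytochrome *c* oxidase (CytcO) catalytic cycle is
modelled as an irreversible linear chain of microstates,

    R → A → P_R → F → F_R → O,

propagated by the linear master equation dp/dt = K·p, where K is the
probability-conserving rate generator (off-diagonal entries are the step
rates, columns sum to zero). The states are: fully reduced enzyme (R), the
oxy complex after O₂ binding to heme a₃ (A), the "peroxy" ferryl formed on
O–O bond cleavage (P_R), the ferryl after proton uptake to the catalytic
site (F), the ferryl with Cu_B reduced by the fourth electron (F_R), and the
fully oxidized enzyme (O). Treating each step as unidirectional is adequate
for the single-turnover flow-flash experiment, where each step is strongly
downhill; reverse transitions are representable in the scheme type but
unused by default.

Default base rates (and the time constants they encode):

| step    | base rate            | τ                         | electrogenic q |
|---------|----------------------|---------------------------|----------------|
| R → A   | 1.0·10⁸ M⁻¹s⁻¹ ·[O₂] | 10 µs at 1 mM, 20 µs at 0.5 mM | 0        |
| A → P_R | 3.33·10⁴ s⁻¹         | 30 µs                     | 0              |
| P_R → F | 1.0·10⁴ s⁻¹          | 100 µs                    | 0              |
| F → F_R | 200 s⁻¹              | 5 ms (membrane-bound value) | 0            |
| F_R → O | 2000 s⁻¹             | 0.5 ms                    | 1              |

F_R → O must be faster than F → F_R so that, without a membrane potential,
the two slow steps appear as a single ~5-ms phase (decay of F_R faster than
its formation); the 10× factor is a modelling choice exposed in the scheme
configuration.

O₂ binding is pseudo-first-order: k = k₂·[O₂], with [O₂] = 0.5 mM by default
(1:1 stopped-flow mixing of an ~1.2 mM O₂-saturated buffer).

### Proton-motive-force dependence

The proton-motive force is Δp = ΔΨ + Z·ΔpH with Z = ln10·RT/F (59.16 mV at
298.15 K). Electrogenic steps — charge movement with a component
perpendicular to the membrane — are attenuated by a single-parameter
Boltzmann factor

    k(Δp) = k₀ · exp(−q·F·Δp / RT),

where q is an effective dimensionless charge per transition that lumps
transfer coefficient and dielectric distance (no separate values for these
are available). This one-parameter form is the standard minimal model for
voltage-dependent charge-translocation kinetics. Defaults assign q = 1 to
F_R → O only: electron transfer from heme a/Cu_A to the catalytic site runs
parallel to the membrane plane and is treated as potential-insensitive,
while the final proton uptake (plus pumping) spans the dielectric. With the
default energized condition ΔΨ = 100 mV, ΔpH = 0.4 (Δp = 123.7 mV), the
F_R → O rate falls from 2000 s⁻¹ to 16.2 s⁻¹, i.e. the F_R lifetime grows to
~62 ms — consistent with the observation that the post-burst absorbance
level stays unchanged for at least 50 ms. Whether proton loading occurs
during F → F_R or F_R → O cannot be distinguished by this experiment; users
studying the alternative assignment can move q to F → F_R in the scheme
config.

### Propagation and the numerical cross-check

`solve_populations` uses the eigendecomposition of K (exact for distinct
rates; if the eigenvector basis is ill-conditioned, cond(V) ≥ 1e10, it falls
back to matrix-exponential stepping). `solve_populations_ode` integrates the
same generator with LSODA at rtol 1e-10/atol 1e-12 and exists purely as an
independent oracle; the two agree to ≤1e-6 absolute occupancy on randomized
chains in the test suite. Occupancies are clipped of sub-1e-12 negative
round-off and renormalized; conservation holds to 1e-9 at every output time.
The default output grid is logarithmic, 1 µs–100 ms, 400 points, with t = 0
at the photolysis flash.

## The observable model

Traces are Beer–Lambert projections ΔA(t) = l·c·Σ_s ε(s,λ)·p_s(t) relative
to the oxidized state (ε(O) ≡ 0), with path length l = 1.00 cm and enzyme
concentration c = 1 µM (0.001 mM) by default, so the fully reduced enzyme
gives ΔA = 0.15 at 445 nm.

Per-state coefficients are assembled from component values because only
component values are known: at 445 nm, heme a contributes
ε = 60 mM⁻¹cm⁻¹ and is 40% of the reduced-minus-oxidized total (so the
total is 150 and heme a₃ carries 90); the catalytic site in F adds
10 mM⁻¹cm⁻¹ relative to O. At 605 nm only shares are known, so values sit on
a relative scale with R = 100: heme a is 80 (80% of the total) and the
site-F term is 4 (5% of heme a).

Defaults per state, with f_a the fraction of the fourth electron visible on
heme a during P_R/F/F_R (default 1.0):

| state | ε(445) mM⁻¹cm⁻¹ | ε(605) rel. |
|-------|------------------|-------------|
| R     | 150              | 100         |
| A     | 80               | 85          |
| P_R   | f_a·60 + 20      | f_a·80 + 4  |
| F     | f_a·60 + 10      | f_a·80 + 4  |
| F_R   | 10 (configurable)| 4           |
| O     | 0                | 0           |

The A and P_R entries are shape choices constrained qualitatively: the A
entry makes O₂ binding the dominant fast decay at 445 nm, and the P_R site
term of 20 makes the P_R → F proton-uptake step a small (−10 of 150)
change — the near-plateau observed in the 200–500 µs range — while leaving
the 100-µs phase just resolvable by fitting. ε(F_R) may in reality differ
from ε(F) because of the extra electron on Cu_B; it is a separate config
parameter defaulting to the F site value. Cu_A and Cu_B are assigned zero
visible absorbance.

With f_a = 1 the slow-phase arithmetic reads: completing F → O at 445 nm
moves 70 units (60 heme a + 10 site); stopping at F_R moves only 60, a
100·10/70 = 14.3% amplitude deficit (`expected_amplitude_decrease(60, 10)`).
At 605 nm the same termination change is (84−80)/84 ≈ 4.8%. The f_a = 1
default sits in tension with the observation of only fractional Cu_A → heme a
electron transfer in membranes; it is kept because the 60 + 10 amplitude
arithmetic above assumes full heme-a participation, and f_a is exposed for
sensitivity analysis rather than resolved here.

## Trace fitting

Traces are fit with ΔA(t) = offset + Σ aᵢ·exp(−t/τᵢ) by separable
(variable-projection-style) least squares: amplitudes and offset are solved
by linear least squares at fixed {τᵢ}, and only log-τ is optimized
(`scipy.optimize.least_squares`, bounded), with multistart — one log-evenly
spaced start plus seeded uniform draws (24 restarts by default) — to cover
components spanning four decades of τ. Fits are bit-reproducible per seed.
Only post-flash (t > 0), non-blanked samples inside the analysis window are
used. Optional per-point 1/σ weights and a residual-resampling bootstrap
(for parameter spreads) are provided; fits are unweighted by default.

Protocol choices that matter:

* **Analysis window 0–10 ms** for slow-phase comparisons. The oxidative
  burst is complete by ~10 ms in the uncoupled enzyme, while under a pmf the
  F_R state persists for tens of ms; including the 10–100 ms region would
  feed the slow F_R → O tail (τ ≈ 62 ms) into a 3-exponential fit and bias
  the 5-ms amplitude upward in the energized condition.
* **Components per wavelength follow the resolvable phases.** At 445 nm
  three: the merged fast phase (O₂ binding at 20 µs and P_R formation at
  30 µs are not separable at realistic noise; the merged component fits at
  ~19 µs), the 100-µs F-formation phase, and the 5-ms phase. At 605 nm two:
  only the fast phase and the 5-ms phase carry amplitude there. Overfitting
  (one extra component) produces the classic degenerate pair of
  near-identical τ with huge opposite amplitudes; choosing the component
  count by the resolvable structure avoids it.
* **Component identity by τ window.** "The 5-ms component" is the unique
  fitted component with τ within 3× of nominal; zero or multiple matches
  raise an ambiguity error rather than guessing. Whether the experimental
  amplitude was a fitted amplitude or a level difference is not knowable;
  the fitted-amplitude reading is primary and `level_difference` exists as a
  fit-free sensitivity check.

## Synthetic data

No measured traces are publicly deposited, so the generators stand in for
the instrument with known ground truth. `generate_flash_traces` adds i.i.d.
Gaussian noise (σ = 0.002 ΔA by default, chosen to emulate the visual
quality of 10–20-trace averages; real averaged traces have correlated noise
that is not modelled) and blanks the laser-artifact window (default
0–2 µs) with NaN. `generate_paired_condition_traces` draws independent noise
per replicate and condition from seeds spawned deterministically off one
master seed. The calibration generator uses the six-point K⁺ ladder
(2.5–50 mM outside, 0.5 mM inside) and a linear dye response (default
1 mΔA/mV); the oxygen-electrode generator produces a two-phase linear
decline (defaults 0.10/0.13 µM s⁻¹, RCR 1.30) from air saturation (240 µM)
at 1 Hz with σ = 0.5 µM. Passing recovery tests on these data demonstrates
the estimators are unbiased under the stated noise model at these problem
sizes; they do not probe correlated noise, baseline drift, dye saturation,
instrument response, or re-reduction of the oxidized enzyme by ascorbate,
all of which affect real traces.

## Potential calibration and RCR

The dye model is strictly linear in potential over the calibrated range
(possible oxonol saturation at high potential is flagged in curve metadata,
not modelled). Potentials use concentrations, not activities, and no
junction-potential correction. The RCR is uncoupled/coupled rate (≥ 1 for a
coupled membrane); rates are |slope| of [O₂] vs t by least squares within
user windows. ΔpH is a model *input* throughout (default 0.4 pH units for
the energized condition); no ACMA-quench quantitation is attempted.

## Problem sizes and determinism

Default study sizes: 400-point traces, 10 replicate pairs for the paired
comparison, 10 seeds for τ recovery, 50 seeds for calibration-recovery
statistics, 100 random chains for the solver cross-check. All stochastic
paths take explicit integer seeds; derived seeds are generated with
`numpy.random.SeedSequence` and kept below 2³¹.

## Known limitations

* Single-turnover oxidative phase only: no reductive phase, no steady-state
  multi-turnover kinetics, no Cu_A ↔ heme a sub-equilibrium kinetics (its
  spectroscopic effect is lumped into f_a), no ATP-synthase model.
* The q parameters are effective lumped charges; they are not decomposable
  into transfer coefficients or dielectric distances.
* The 580-nm P/F band and full-spectrum analysis are out of scope; only
  445 and 605 nm are tabulated by default (the table type supports others).
* A 3-exponential fit cannot return the nominal 30-µs P_R-formation τ from
  0.5 mM O₂ traces, because the 20-µs O₂-binding phase (7× the amplitude)
  merges with it; the merged component sits at ~19 µs. Separating them would
  require lower noise or a different [O₂], not a different fitter.
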