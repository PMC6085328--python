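"""Seeded synthetic stand-ins for the stopped-flow/flow-flash instrument.

The original measurements are not publicly deposited, so every input the
analysis consumes is generated here with known ground truth:

* two-wavelength (445/605 nm) flash-photolysis ΔA trace pairs following the
  R → A → P_R → F → F_R → O scheme, with additive i.i.d. Gaussian noise and
  a blanked laser-artifact window at the flash origin;
* oxonol-dye calibration series obeying the Nernst equation over the
  K⁺-gradient ladder (2.5–50 mM outside vs 0.5 mM inside);
* coupled/uncoupled Clark-electrode O₂ time courses with a fixed slope
  ratio.

Every generator is a pure function of (config, seed), and ground-truth
parameters travel with the data in metadata so recovery tests are
self-contained.  The defaults emulate the study conditions: 0.5 mM O₂ after
1:1 mixing of an ~1.2 mM O₂-saturated buffer, 1.00 cm path, and a noise σ of
0.002 ΔA chosen for realistic averaged-trace quality (the real instrument's
noise statistics are not reported; correlated noise is not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cycle_kinetics import (DEFAULT_O2_CONC, PmfState, ReactionScheme,
                             build_rate_matrix, default_scheme,
                             default_time_grid, scale_rate_for_pmf,
                             solve_populations)
from .errors import ConfigurationError
from .potential_calibration import CalibrationSeries, OxygenTrace, nernst_potential
from .spectral_model import (EpsilonTable, Trace, default_epsilon_table,
                             populations_to_absorbance)

__all__ = [
    "FlashTraceConfig",
    "METHODS_K_OUT_MM",
    "generate_flash_traces",
    "generate_paired_condition_traces",
    "generate_calibration_series",
    "generate_oxygen_trace",
]

#: External K⁺ ladder of the dye calibration (mM); 0.5 mM inside.
METHODS_K_OUT_MM = (2.5, 5.0, 10.0, 20.0, 40.0, 50.0)


@dataclass(frozen=True)
class FlashTraceConfig:
    """Everything needed to synthesize one flash-photolysis trace pair."""

    scheme: ReactionScheme = field(default_factory=default_scheme)
    pmf: PmfState = field(default_factory=PmfState)
    epsilon: EpsilonTable = field(default_factory=default_epsilon_table)
    o2_conc: float = DEFAULT_O2_CONC      # M
    enzyme_conc: float = 1e-3             # mM
    path: float = 1.0                     # cm
    wavelengths: tuple[float, ...] = (445.0, 605.0)
    times: np.ndarray = field(default_factory=default_time_grid)
    noise_sd: float = 0.002               # ΔA
    blank_window: tuple[float, float] = (0.0, 2e-6)  # s, laser artifact
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.o2_conc <= 0 or self.enzyme_conc <= 0 or self.path <= 0:
            raise ConfigurationError("concentrations and path must be > 0")
        lo, hi = self.blank_window
        if lo > hi:
            raise ConfigurationError("blank_window must be ordered")

    def ground_truth(self) -> dict:
        """True model parameters, for sidecar metadata."""
        dp = self.pmf.pmf
        rates = {}
        for tr in self.scheme.transitions:
            k = tr.k0 * (self.o2_conc if tr.o2_dependent else 1.0)
            k = scale_rate_for_pmf(k, tr.q, dp, self.pmf.temperature)
            rates[f"{tr.source}->{tr.target}"] = k
        return {
            "rates_s": rates,
            "taus_s": {step: 1.0 / k for step, k in rates.items()},
            "o2_conc_M": self.o2_conc,
            "delta_psi_mV": self.pmf.delta_psi,
            "delta_ph": self.pmf.delta_ph,
            "temperature_K": self.pmf.temperature,
            "enzyme_conc_mM": self.enzyme_conc,
            "path_cm": self.path,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


def generate_flash_traces(config: FlashTraceConfig,
                          seed: int | None = None) -> dict[float, Trace]:
    """Simulate one flash experiment: noise-free model + Gaussian noise.

    Returns one :class:`Trace` per configured wavelength.  Samples inside the
    blank window are replaced by NaN (the truncated laser artifact).  With
    ``noise_sd = 0`` the output equals the deterministic Beer–Lambert
    projection exactly.  Deterministic per seed (``seed`` overrides the
    config's).
    """
    if seed is not None:
        config = replace(config, seed=seed)
    rm = build_rate_matrix(config.scheme, config.o2_conc, config.pmf)
    traj = solve_populations(rm, times=config.times)
    rng = np.random.default_rng(config.seed)
    truth = config.ground_truth()
    traces = {}
    for wl in config.wavelengths:
        trace = populations_to_absorbance(traj, config.epsilon, wl,
                                          config.enzyme_conc, config.path)
        if config.noise_sd > 0:
            trace.values = trace.values + rng.normal(
                0.0, config.noise_sd, trace.values.shape)
        lo, hi = config.blank_window
        blank = (trace.times >= lo) & (trace.times < hi)
        trace.values[blank] = np.nan
        trace.metadata.update({"noise_sd": config.noise_sd,
                               "seed": config.seed,
                               "ground_truth": truth})
        traces[wl] = trace
    return traces


def generate_paired_condition_traces(
        config: FlashTraceConfig,
        pmf_off: PmfState | None = None,
        pmf_on: PmfState | None = None,
        replicates: int = 1,
        seed: int = 0) -> dict[str, list[dict[float, Trace]]]:
    """Paired pmf-off/pmf-on experiments with independent noise per replicate.

    The two conditions mirror the experiment with (coupled, ATP-energized)
    and without (valinomycin + FCCP) a transmembrane electrochemical
    potential; defaults: off = (0 mV, 0 pH), on = (100 mV, 0.4 pH).
    Returns ``{"off": [trace-pair, ...], "on": [...]}`` with ``replicates``
    entries per condition; kinetics are identical within a condition, noise
    draws are independent.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if pmf_off is None:
        pmf_off = PmfState(0.0, 0.0, config.pmf.temperature)
    if pmf_on is None:
        pmf_on = PmfState(100.0, 0.4, config.pmf.temperature)
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * replicates)
    out: dict[str, list] = {"off": [], "on": []}
    for i in range(replicates):
        for j, (label, ps) in enumerate((("off", pmf_off), ("on", pmf_on))):
            cfg = replace(config, pmf=ps,
                          seed=int(child_seeds[2 * i + j] % (2**31 - 1)))
            out[label].append(generate_flash_traces(cfg))
    return out


def generate_calibration_series(slope: float = 1e-3, intercept: float = 0.0,
                                k_out_list=METHODS_K_OUT_MM,
                                k_in: float = 0.5, sigma: float = 0.0,
                                seed: int = 0, charge: int = 1,
                                temperature: float = 298.15) -> CalibrationSeries:
    """Dye-calibration ladder: ΔA = slope·E_Nernst + intercept + noise.

    ``slope`` in ΔA/mV, ``sigma`` the Gaussian ΔA noise.  Ground truth is
    recorded in the series metadata.
    """
    k_out = np.asarray(k_out_list, dtype=float)
    if (k_out <= 0).any() or k_in <= 0:
        raise ValueError("concentrations must be > 0")
    pots = np.array([nernst_potential(c, k_in, charge, temperature)
                     for c in k_out])
    rng = np.random.default_rng(seed)
    da = slope * pots + intercept
    if sigma > 0:
        da = da + rng.normal(0.0, sigma, da.shape)
    return CalibrationSeries(
        c_out=k_out, c_in=np.full_like(k_out, k_in), delta_a=da,
        metadata={"true_slope_da_per_mv": slope,
                  "true_intercept_da": intercept,
                  "sigma": sigma, "seed": seed, "charge": charge,
                  "temperature_K": temperature})


def generate_oxygen_trace(rate_coupled: float = 0.10,
                          rate_uncoupled: float = 0.13,
                          switch_time: float = 60.0,
                          sigma: float = 0.0, seed: int = 0,
                          duration: float = 120.0,
                          sample_rate: float = 1.0,
                          o2_start: float = 240.0) -> OxygenTrace:
    """Two-phase Clark-electrode trace: coupled slope, then uncoupled.

    [O₂] declines at ``rate_coupled`` µM/s until the uncoupler addition at
    ``switch_time``, then at ``rate_uncoupled``; Gaussian noise σ in µM.
    Default slopes give RCR = 1.3, the coupling level of the vesicle
    preparation this emulates; ``o2_start`` defaults to air saturation.
    """
    if rate_coupled < 0 or rate_uncoupled < 0:
        raise ValueError("rates must be >= 0")
    if not (0 < switch_time < duration):
        raise ValueError("switch_time must lie inside the trace")
    t = np.arange(0.0, duration + 0.5 / sample_rate, 1.0 / sample_rate)
    o2 = np.where(
        t <= switch_time,
        o2_start - rate_coupled * t,
        o2_start - rate_coupled * switch_time
        - rate_uncoupled * (t - switch_time))
    rng = np.random.default_rng(seed)
    if sigma > 0:
        o2 = o2 + rng.normal(0.0, sigma, o2.shape)
    return OxygenTrace(
        times=t, o2_um=o2,
        additions=(("smp", 0.0), ("uncoupler", float(switch_time))),
        metadata={"true_rate_coupled_um_s": rate_coupled,
                  "true_rate_uncoupled_um_s": rate_uncoupled,
                  "sigma_um": sigma, "seed": seed})
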