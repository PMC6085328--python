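"""Multi-exponential fitting of flash-photolysis ΔA traces.

The observable of the sequential cycle is a sum of exponentials, so traces
are fit with

    ΔA(t) = offset + Σᵢ aᵢ · exp(−t/τᵢ),

using a separable (variable-projection-style) least-squares scheme: at fixed
time constants the amplitudes and offset are solved by linear least squares,
and only the log-τ values are optimized, with multistart over the τ range to
cope with components spanning four decades.  Fits are deterministic for a
given seed.

Component identity follows the field's naming-by-τ convention ("the 5-ms
component"): :func:`component_amplitude` selects the unique component whose
fitted τ falls within a multiplicative window of the nominal value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import AmbiguousComponentError, FitFailureError
from .spectral_model import Trace

__all__ = [
    "ExponentialComponent",
    "FitResult",
    "fit_multiexponential",
    "component_amplitude",
    "amplitude_change",
    "level_difference",
    "bootstrap_fit",
]


@dataclass(frozen=True)
class ExponentialComponent:
    amplitude: float   # ΔA units, signed
    tau: float         # s


@dataclass
class FitResult:
    """Outcome of a multi-exponential fit; components sorted by ascending τ."""

    components: tuple[ExponentialComponent, ...]
    offset: float
    rss: float
    residual_sd: float
    n_points: int
    converged: bool
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        taus = [c.tau for c in self.components]
        if len(taus) < 1 or any(t <= 0 for t in taus):
            raise ValueError("need >=1 component with strictly positive tau")
        if taus != sorted(taus):
            raise ValueError("components must be sorted by ascending tau")
        if self.rss < 0 or self.residual_sd < 0:
            raise ValueError("residual statistics must be >= 0")

    @property
    def taus(self) -> np.ndarray:
        return np.array([c.tau for c in self.components])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.components])

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        out = np.full_like(t, self.offset)
        for c in self.components:
            out += c.amplitude * np.exp(-t / c.tau)
        return out

    # ------------------------------------------------------------------ I/O
    def to_json(self, path=None):
        doc = {
            "components": [{"amplitude": c.amplitude, "tau_s": c.tau}
                           for c in self.components],
            "offset": self.offset,
            "rss": self.rss,
            "residual_sd": self.residual_sd,
            "n_points": self.n_points,
            "converged": self.converged,
            "seed": self.seed,
            "metadata": self.metadata,
        }
        if path is None:
            return json.dumps(doc, indent=2)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
        return None

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            doc = json.load(fh)
        comps = tuple(ExponentialComponent(c["amplitude"], c["tau_s"])
                      for c in doc["components"])
        return cls(components=comps, offset=doc["offset"], rss=doc["rss"],
                   residual_sd=doc["residual_sd"], n_points=doc["n_points"],
                   converged=doc["converged"], seed=doc.get("seed"),
                   metadata=doc.get("metadata", {}))


def _clean_window(trace: Trace, window):
    """Post-flash, non-blanked samples inside the analysis window."""
    t = trace.times
    v = trace.values
    lo, hi = (0.0, math.inf) if window is None else window
    lo = max(lo, 0.0)
    mask = np.isfinite(v) & (t > lo)
    if hi is not None and math.isfinite(hi):
        mask &= t <= hi
    return t[mask], v[mask]


def _solve_amplitudes(t, y, taus, weights=None):
    X = np.column_stack([np.exp(-t[:, None] / np.asarray(taus)[None, :]),
                         np.ones_like(t)])
    if weights is not None:
        Xw = X * weights[:, None]
        yw = y * weights
    else:
        Xw, yw = X, y
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    return coef, X


def fit_multiexponential(trace: Trace, n_components: int,
                         tau_bounds: tuple[float, float] | None = None,
                         restarts: int = 24, seed: int = 0,
                         window: tuple[float, float] | None = None,
                         weights=None) -> FitResult:
    """Fit offset + Σ aᵢ·exp(−t/τᵢ) to a trace by separable least squares.

    Parameters
    ----------
    trace
        Input ΔA trace; only finite values at t inside ``window`` (default:
        all t > 0, excluding the flash at the origin) are used.
    n_components
        Number of exponentials, 1–5.
    tau_bounds
        (τ_min, τ_max) search interval in s; defaults to twice the first
        positive sample time up to twice the window span.
    restarts
        Multistart count: the first start is log-evenly spaced, the rest are
        seeded uniform draws in log-τ.
    seed
        Seeds the restart draws; identical inputs + seed give bit-identical
        results.
    weights
        Optional per-point 1/σ weights aligned with the trace samples.

    Raises
    ------
    FitFailureError
        If the trace is degenerate (constant or too short) or no restart
        converges; carries the best attempt when one exists.
    """
    if not (1 <= n_components <= 5):
        raise ValueError("n_components must be in 1..5")
    t, y = _clean_window(trace, window)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != trace.times.shape:
            raise ValueError("weights must align with the trace samples")
        lo = max(window[0], 0.0) if window else 0.0
        hi = window[1] if window and window[1] is not None else math.inf
        m = np.isfinite(trace.values) & (trace.times > lo) & (trace.times <= hi)
        weights = weights[m]
    if t.size < 5 * n_components:
        raise FitFailureError(
            f"need >= {5 * n_components} usable points, got {t.size}")
    if np.ptp(y) == 0:
        raise FitFailureError("degenerate (constant) trace")

    if tau_bounds is None:
        tau_bounds = (2.0 * t[0], 2.0 * (t[-1] - t[0]))
    tau_lo, tau_hi = tau_bounds
    if not (0 < tau_lo < tau_hi):
        raise ValueError("tau_bounds must satisfy 0 < lo < hi")
    llo, lhi = math.log(tau_lo), math.log(tau_hi)

    def residual(log_taus):
        coef, X = _solve_amplitudes(t, y, np.exp(log_taus), weights)
        r = X @ coef - y
        return r * weights if weights is not None else r

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, restarts)):
        if r == 0:
            x0 = np.linspace(llo + 0.5, lhi - 0.5, n_components)
        else:
            x0 = np.sort(rng.uniform(llo, lhi, n_components))
        try:
            sol = least_squares(residual, x0, bounds=(llo, lhi))
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError("all restarts failed")

    taus = np.exp(best.x)
    coef, X = _solve_amplitudes(t, y, taus, weights)
    resid = X @ coef - y
    rss = float(resid @ resid)
    dof = max(1, t.size - (2 * n_components + 1))
    order = np.argsort(taus)
    comps = tuple(ExponentialComponent(float(coef[i]), float(taus[i]))
                  for i in order)
    result = FitResult(
        components=comps, offset=float(coef[-1]), rss=rss,
        residual_sd=math.sqrt(rss / dof), n_points=int(t.size),
        converged=bool(best.success), seed=seed,
        metadata={"wavelength_nm": trace.wavelength,
                  "tau_bounds_s": [tau_lo, tau_hi],
                  "restarts": restarts})
    if not best.success:
        raise FitFailureError("optimizer did not converge", best_attempt=result)
    return result


def component_amplitude(fit: FitResult, nominal_tau: float,
                        tolerance_factor: float = 3.0) -> float:
    """Amplitude of the unique component with τ within a factor of nominal.

    Raises :class:`AmbiguousComponentError` when no component, or more than
    one, falls inside [nominal/factor, nominal·factor].
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if nominal_tau <= 0 or tolerance_factor <= 1:
        raise ValueError("need nominal_tau > 0 and tolerance_factor > 1")
    lo, hi = nominal_tau / tolerance_factor, nominal_tau * tolerance_factor
    matches = [c for c in fit.components if lo <= c.tau <= hi]
    if len(matches) != 1:
        raise AmbiguousComponentError(
            f"{len(matches)} components match tau ~ {nominal_tau:g} s "
            f"(window [{lo:g}, {hi:g}] s; fitted taus "
            f"{[f'{c.tau:g}' for c in fit.components]})")
    return matches[0].amplitude


def amplitude_change(reference: float, test: float) -> float:
    """Percent decrease from reference to test (increase comes out negative)."""
    if reference == 0:
        raise ValueError("reference amplitude must be nonzero")
    return 100.0 * (reference - test) / reference


def level_difference(trace: Trace, pre_window: tuple[float, float],
                     post_window: tuple[float, float]) -> float:
    """Mean-level drop across a kinetic phase, a fit-free amplitude reading.

    Averages ΔA inside the two windows (e.g. the plateau before and the level
    after the 5-ms phase) and returns pre − post.  Useful as a sensitivity
    check on the fitted-amplitude reading of a component.
    """
    def mean_in(win):
        lo, hi = win
        m = np.isfinite(trace.values) & (trace.times >= lo) & (trace.times <= hi)
        if not m.any():
            raise ValueError(f"no usable samples in window {win}")
        return float(trace.values[m].mean())

    return mean_in(pre_window) - mean_in(post_window)


def bootstrap_fit(trace: Trace, fit: FitResult, n_boot: int = 50,
                  seed: int = 0, **fit_kwargs) -> dict:
    """Residual-resampling bootstrap spread of τ and amplitude estimates.

    Refits ``n_boot`` synthetic traces built from the fitted model plus
    resampled residuals; returns standard deviations keyed by parameter.
    """
    window = fit_kwargs.get("window")
    t, y = _clean_window(trace, window)
    resid = y - fit.predict(t)
    rng = np.random.default_rng(seed)
    taus, amps = [], []
    n_comp = len(fit.components)
    for b in range(n_boot):
        y_b = fit.predict(t) + rng.choice(resid, size=resid.size, replace=True)
        boot_trace = Trace(wavelength=trace.wavelength, times=t, values=y_b,
                           path=trace.path)
        try:
            fb = fit_multiexponential(
                boot_trace, n_comp,
                seed=int(rng.integers(0, 2**31 - 1)),
                **{k: v for k, v in fit_kwargs.items() if k != "window"})
        except FitFailureError:
            continue
        taus.append(fb.taus)
        amps.append(fb.amplitudes)
    if not taus:
        raise FitFailureError("every bootstrap refit failed")
    return {
        "tau_sd": np.std(np.array(taus), axis=0, ddof=1),
        "amplitude_sd": np.std(np.array(amps), axis=0, ddof=1),
        "n_successful": len(taus),
    }
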