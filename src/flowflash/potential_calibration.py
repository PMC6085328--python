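"""Membrane-potential calibration and respiratory-control utilities.

A potentiometric dye (oxonol VI) reports the membrane electrical potential of
inside-out vesicles.  Calibration imposes known potentials via K⁺ gradients
in the presence of valinomycin: each external/internal K⁺ pair defines a
Nernst potential

    E = (R·T / z·F) · ln(c_out / c_in),

and the dye ΔA is regressed linearly on E.  The fitted line inverts dye
responses into potentials (the linearity over the calibrated 0–120 mV range
is an assumption of the method and is recorded in curve metadata).

The respiratory control ratio (RCR) quantifies membrane coupling from
Clark-electrode O₂ time courses: RCR = (uncoupled rate)/(coupled rate) ≥ 1
for an intact membrane.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cycle_kinetics import (DEFAULT_TEMPERATURE, FARADAY, GAS_CONSTANT,
                             _read_metadata)
from .errors import ConfigurationError, DegenerateFitError

__all__ = [
    "CalibrationSeries",
    "CalibrationCurve",
    "OxygenTrace",
    "nernst_potential",
    "fit_calibration",
    "estimate_potential",
    "rcr",
    "extract_o2_rate",
]


def nernst_potential(c_out: float, c_in: float, charge: int = 1,
                     temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Nernst potential (R·T/z·F)·ln(c_out/c_in) in mV.

    Concentrations in any common unit (only the ratio matters); ``charge``
    is the ion valence z.
    """
    if not (math.isfinite(c_out) and math.isfinite(c_in)):
        raise ValueError("concentrations must be finite")
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be > 0")
    if charge == 0:
        raise ValueError("charge must be nonzero")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return (GAS_CONSTANT * temperature / (charge * FARADAY)
            * math.log(c_out / c_in) * 1e3)


@dataclass
class CalibrationSeries:
    """Dye response vs imposed K⁺ gradient: (c_out [mM], c_in [mM], ΔA)."""

    c_out: np.ndarray
    c_in: np.ndarray
    delta_a: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        co = np.asarray(self.c_out, dtype=float)
        ci = np.asarray(self.c_in, dtype=float)
        da = np.asarray(self.delta_a, dtype=float)
        if not (co.shape == ci.shape == da.shape) or co.ndim != 1:
            raise ValueError("c_out, c_in, delta_a must be matching 1-D arrays")
        if (co <= 0).any() or (ci <= 0).any():
            raise ValueError("concentrations must be > 0")
        self.c_out, self.c_in, self.delta_a = co, ci, da

    def __len__(self) -> int:
        return self.c_out.size

    def potentials(self, charge: int = 1,
                   temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
        return np.array([nernst_potential(o, i, charge, temperature)
                         for o, i in zip(self.c_out, self.c_in)])

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"k_out_mM": self.c_out, "k_in_mM": self.c_in,
                           "delta_a": self.delta_a})
        with open(path, "w") as fh:
            for key, value in self.metadata.items():
                fh.write(f"# {key} = {value}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationSeries":
        meta = _read_metadata(path)
        df = pd.read_csv(path, comment="#")
        need = {"k_out_mM", "k_in_mM", "delta_a"}
        if not need <= set(df.columns):
            raise ConfigurationError(f"{path}: need columns {sorted(need)}")
        return cls(c_out=df["k_out_mM"].to_numpy(),
                   c_in=df["k_in_mM"].to_numpy(),
                   delta_a=df["delta_a"].to_numpy(), metadata=meta)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear dye-response model ΔA = slope·E + intercept (E in mV)."""

    slope: float           # ΔA per mV
    intercept: float       # ΔA
    residual_sd: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (math.isfinite(self.slope) and self.slope != 0):
            raise ValueError("slope must be finite and nonzero")

    def to_json(self, path=None):
        doc = {"slope_da_per_mv": self.slope, "intercept_da": self.intercept,
               "residual_sd": self.residual_sd, "metadata": self.metadata}
        if path is None:
            return json.dumps(doc, indent=2)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
        return None

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(slope=doc["slope_da_per_mv"], intercept=doc["intercept_da"],
                   residual_sd=doc["residual_sd"],
                   metadata=doc.get("metadata", {}))


def fit_calibration(series: CalibrationSeries, charge: int = 1,
                    temperature: float = DEFAULT_TEMPERATURE) -> CalibrationCurve:
    """Ordinary least-squares line of dye ΔA against the Nernst potential."""
    if len(series) < 2:
        raise DegenerateFitError("need at least 2 calibration points")
    pots = series.potentials(charge, temperature)
    if np.ptp(pots) == 0:
        raise DegenerateFitError("all calibration potentials identical")
    res = stats.linregress(pots, series.delta_a)
    resid = series.delta_a - (res.slope * pots + res.intercept)
    dof = max(1, len(series) - 2)
    return CalibrationCurve(
        slope=float(res.slope), intercept=float(res.intercept),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
        metadata={"n_points": len(series), "charge": charge,
                  "temperature_K": temperature,
                  "linearity_note": ("linear dye response assumed over the "
                                     "calibrated potential range")})


def estimate_potential(delta_a: float, curve: CalibrationCurve) -> float:
    """Invert the calibration line: E = (ΔA − intercept)/slope, in mV."""
    if not math.isfinite(delta_a):
        raise ValueError("delta_a must be finite")
    return (delta_a - curve.intercept) / curve.slope


def rcr(rate_coupled: float, rate_uncoupled: float) -> float:
    """Respiratory control ratio = uncoupled / coupled O₂-reduction rate."""
    if not (rate_coupled > 0 and rate_uncoupled > 0):
        raise ValueError("rates must be > 0")
    return rate_uncoupled / rate_coupled


@dataclass
class OxygenTrace:
    """Clark-electrode time course: dissolved [O₂] (µM) vs time (s).

    ``additions`` annotates events, e.g. [("smp", 0.0), ("fccp", 60.0)].
    """

    times: np.ndarray
    o2_um: np.ndarray
    additions: tuple = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        o = np.asarray(self.o2_um, dtype=float)
        if t.ndim != 1 or o.shape != t.shape:
            raise ValueError("times and o2_um must be matching 1-D arrays")
        if (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        self.times, self.o2_um = t, o
        self.additions = tuple((str(lbl), float(at)) for lbl, at in self.additions)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_s": self.times, "o2_uM": self.o2_um})
        with open(path, "w") as fh:
            fh.write(f"# additions = {json.dumps(list(self.additions))}\n")
            for key, value in self.metadata.items():
                fh.write(f"# {key} = {value}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "OxygenTrace":
        meta = _read_metadata(path)
        additions = tuple(tuple(a) for a in meta.pop("additions", []))
        df = pd.read_csv(path, comment="#")
        if not {"time_s", "o2_uM"} <= set(df.columns):
            raise ConfigurationError(f"{path}: need columns time_s, o2_uM")
        return cls(times=df["time_s"].to_numpy(), o2_um=df["o2_uM"].to_numpy(),
                   additions=additions, metadata=meta)


def extract_o2_rate(trace: OxygenTrace, window: tuple[float, float]) -> float:
    """|slope| of [O₂] vs t (µM s⁻¹) by least squares inside a time window."""
    lo, hi = window
    if not (trace.times[0] <= lo < hi <= trace.times[-1]):
        raise ValueError("window must lie within the trace span")
    mask = (trace.times >= lo) & (trace.times <= hi)
    if mask.sum() < 3:
        raise ValueError("need at least 3 points inside the window")
    res = stats.linregress(trace.times[mask], trace.o2_um[mask])
    return abs(float(res.slope))
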