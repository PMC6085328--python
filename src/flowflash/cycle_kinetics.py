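"""Oxidative-phase catalytic cycle of cytochrome c oxidase (CytcO).

After flash photolysis of the CO-blocked, four-electron reduced enzyme in the
presence of O₂, the enzyme runs through a sequence of intermediates

    R → A → P_R → F → F_R → O

(fully reduced; oxy; "peroxy" ferryl; ferryl after proton uptake; ferryl with
Cu_B reduced by the fourth electron; fully oxidized).  Each step is modelled
as an irreversible first-order transition; the O₂-binding step R → A is
pseudo-first-order in dissolved O₂.  Steps that move charge perpendicular to
the membrane (proton uptake and pumping) are slowed by the proton-motive
force Δp through a single-parameter Boltzmann factor,

    k(Δp) = k₀ · exp(−q · F · Δp / (R·T)),

with an effective, dimensionless charge q per transition.  In the default
scheme only F_R → O is electrogenic (q = 1): electron transfer between heme a
and the catalytic site runs parallel to the membrane plane and is taken to be
potential-insensitive.

State populations follow the linear master equation dp/dt = K p, which is
propagated exactly by eigendecomposition of the rate generator K (with an
independent stiff-ODE solver provided as a cross-check).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants as _const
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, NumericalFailureError

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "DEFAULT_TEMPERATURE",
    "Transition",
    "ReactionScheme",
    "PmfState",
    "RateMatrix",
    "PopulationTrajectory",
    "pmf",
    "nernst_slope",
    "scale_rate_for_pmf",
    "pseudo_first_order_rate",
    "build_rate_matrix",
    "solve_populations",
    "solve_populations_ode",
    "default_scheme",
    "default_time_grid",
    "load_config",
]

GAS_CONSTANT = _const.R          # J mol⁻¹ K⁻¹
FARADAY = _const.value("Faraday constant")  # C mol⁻¹
DEFAULT_TEMPERATURE = 298.15     # K; standard lab temperature

#: Default dissolved O₂ after 1:1 mixing with an O₂-saturated (~1.2 mM) buffer.
DEFAULT_O2_CONC = 0.5e-3  # M


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def nernst_slope(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Return Z = ln(10)·R·T/F in mV (≈59.16 mV at 298.15 K)."""
    temperature = _require_finite("temperature", temperature)
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return math.log(10.0) * GAS_CONSTANT * temperature / FARADAY * 1e3


def pmf(delta_psi: float, delta_ph: float,
        temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Proton-motive force Δp = ΔΨ + Z·ΔpH in mV.

    ``delta_psi`` in mV, ``delta_ph`` in pH units (positive = interior acidic
    for the inside-out vesicle sign convention used throughout).
    """
    delta_psi = _require_finite("delta_psi", delta_psi)
    delta_ph = _require_finite("delta_ph", delta_ph)
    return delta_psi + nernst_slope(temperature) * delta_ph


def scale_rate_for_pmf(k0: float, q: float, pmf_mv: float,
                       temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Boltzmann scaling of an electrogenic rate by the proton-motive force.

    Returns k₀·exp(−q·F·Δp/(R·T)); Δp is supplied in mV.  q = 0 leaves the
    rate untouched, and Δp = 0 returns k₀ for any q.
    """
    k0 = _require_finite("k0", k0)
    q = _require_finite("q", q)
    pmf_mv = _require_finite("pmf_mv", pmf_mv)
    if k0 <= 0:
        raise ValueError("k0 must be > 0")
    if q < 0:
        raise ValueError("q must be >= 0")
    temperature = _require_finite("temperature", temperature)
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    volt = pmf_mv * 1e-3
    return k0 * math.exp(-q * FARADAY * volt / (GAS_CONSTANT * temperature))


def pseudo_first_order_rate(k2: float, o2_conc: float) -> float:
    """Pseudo-first-order O₂-binding rate k₂·[O₂] in s⁻¹ (k₂ in M⁻¹s⁻¹)."""
    k2 = _require_finite("k2", k2)
    o2_conc = _require_finite("o2_conc", o2_conc)
    if k2 <= 0:
        raise ValueError("k2 must be > 0")
    if o2_conc <= 0:
        raise ValueError("o2_conc must be > 0")
    return k2 * o2_conc


@dataclass(frozen=True)
class Transition:
    """One first-order step of the cycle.

    ``k0`` is in s⁻¹, or in M⁻¹s⁻¹ when ``o2_dependent`` is set (the rate is
    then multiplied by [O₂]).  ``q`` is the effective electrogenic charge
    entering the Boltzmann factor.
    """

    source: str
    target: str
    k0: float
    o2_dependent: bool = False
    q: float = 0.0

    def __post_init__(self):
        if self.source == self.target:
            raise ConfigurationError(
                f"transition {self.source}->{self.target} must connect two "
                "distinct states")
        if not (math.isfinite(self.k0) and self.k0 > 0):
            raise ConfigurationError(
                f"transition {self.source}->{self.target}: base rate must be "
                f"strictly positive, got {self.k0!r}")
        if not (math.isfinite(self.q) and self.q >= 0):
            raise ConfigurationError(
                f"transition {self.source}->{self.target}: q must be >= 0, "
                f"got {self.q!r}")


@dataclass(frozen=True)
class ReactionScheme:
    """Ordered microstates plus the transitions connecting them."""

    states: tuple[str, ...]
    transitions: tuple[Transition, ...]

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise ConfigurationError("duplicate state labels in scheme")
        for tr in self.transitions:
            for s in (tr.source, tr.target):
                if s not in self.states:
                    raise ConfigurationError(
                        f"transition references undeclared state {s!r}")

    def index(self, state: str) -> int:
        return self.states.index(state)

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "transitions": [
                {"from": t.source, "to": t.target, "k0": t.k0,
                 "o2_dependent": t.o2_dependent, "q": t.q}
                for t in self.transitions
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ReactionScheme":
        allowed = {"states", "transitions"}
        _reject_unknown_keys(data, allowed, "scheme")
        try:
            states = tuple(str(s) for s in data["states"])
            raw = data["transitions"]
        except KeyError as exc:
            raise ConfigurationError(f"scheme missing key {exc}") from exc
        transitions = []
        for entry in raw:
            _reject_unknown_keys(
                entry, {"from", "to", "k0", "o2_dependent", "q"},
                "scheme transition")
            try:
                transitions.append(Transition(
                    source=str(entry["from"]), target=str(entry["to"]),
                    k0=float(entry["k0"]),
                    o2_dependent=bool(entry.get("o2_dependent", False)),
                    q=float(entry.get("q", 0.0))))
            except KeyError as exc:
                raise ConfigurationError(
                    f"scheme transition missing key {exc}") from exc
        return cls(states=states, transitions=tuple(transitions))


@dataclass(frozen=True)
class PmfState:
    """Transmembrane driving force: ΔΨ [mV], ΔpH [pH units], T [K]."""

    delta_psi: float = 0.0
    delta_ph: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        _require_finite("delta_psi", self.delta_psi)
        _require_finite("delta_ph", self.delta_ph)
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError("temperature must be finite and > 0 K")

    @property
    def pmf(self) -> float:
        """Proton-motive force Δp in mV."""
        return pmf(self.delta_psi, self.delta_ph, self.temperature)


@dataclass(frozen=True)
class RateMatrix:
    """Probability-conserving generator K of the master equation dp/dt = K p.

    Column convention: ``matrix[j, i]`` is the rate from state i to state j
    (s⁻¹); each column sums to zero.
    """

    matrix: np.ndarray
    states: tuple[str, ...]
    o2_conc: float
    pmf_state: PmfState

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.states):
            raise ConfigurationError("rate matrix must be square over the states")
        off = m - np.diag(np.diag(m))
        if (off < 0).any():
            raise ConfigurationError("off-diagonal rates must be non-negative")
        if not np.allclose(m.sum(axis=0), 0.0, atol=1e-8 * max(1.0, np.abs(m).max())):
            raise ConfigurationError("generator columns must sum to zero")
        object.__setattr__(self, "matrix", m)


def default_scheme() -> ReactionScheme:
    """Oxidative-phase scheme with base rates for CytcO in SMP membranes.

    τ values: R→A 10 µs at 1 mM O₂ (k₂ = 1e8 M⁻¹s⁻¹), A→P_R ≈30 µs,
    P_R→F 100 µs, F→F_R 5 ms (the slowed membrane value), F_R→O 0.5 ms so
    that without a pmf the two slow steps merge into a single ~5-ms phase.
    Only F_R→O carries charge (q = 1).
    """
    return ReactionScheme(
        states=("R", "A", "P_R", "F", "F_R", "O"),
        transitions=(
            Transition("R", "A", 1.0e8, o2_dependent=True),
            Transition("A", "P_R", 1.0 / 30e-6),
            Transition("P_R", "F", 1.0e4),
            Transition("F", "F_R", 200.0),
            Transition("F_R", "O", 2000.0, q=1.0),
        ),
    )


def default_time_grid(t_min: float = 1e-6, t_max: float = 0.1,
                      n: int = 400) -> np.ndarray:
    """Logarithmic sampling grid in s; t = 0 is the photolysis flash."""
    if not (t_min > 0 and t_max > t_min and n >= 2):
        raise ValueError("need 0 < t_min < t_max and n >= 2")
    return np.logspace(math.log10(t_min), math.log10(t_max), n)


def build_rate_matrix(scheme: ReactionScheme, o2_conc: float,
                      pmf_state: PmfState | None = None) -> RateMatrix:
    """Assemble the master-equation generator for a scheme under given Δp."""
    if pmf_state is None:
        pmf_state = PmfState()
    o2_conc = _require_finite("o2_conc", o2_conc)
    if o2_conc <= 0:
        raise ValueError("o2_conc must be > 0")
    n = len(scheme.states)
    K = np.zeros((n, n))
    dp = pmf_state.pmf
    for tr in scheme.transitions:
        try:
            i = scheme.index(tr.source)
            j = scheme.index(tr.target)
        except ValueError as exc:
            raise ConfigurationError(str(exc)) from exc
        k = pseudo_first_order_rate(tr.k0, o2_conc) if tr.o2_dependent else tr.k0
        k = scale_rate_for_pmf(k, tr.q, dp, pmf_state.temperature)
        K[j, i] += k
        K[i, i] -= k
    return RateMatrix(matrix=K, states=scheme.states, o2_conc=o2_conc,
                      pmf_state=pmf_state)


@dataclass
class PopulationTrajectory:
    """State occupancy fractions on a time grid.

    ``occupancies`` has shape (n_times, n_states); rows sum to 1.
    """

    times: np.ndarray
    occupancies: np.ndarray
    states: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.occupancies, dtype=float)
        if t.ndim != 1 or (np.diff(t) <= 0).any() or (t < 0).any():
            raise ValueError("times must be 1-D, non-negative, strictly increasing")
        if p.shape != (t.size, len(self.states)):
            raise ValueError("occupancies must be (n_times, n_states)")
        # tolerate eigen-solver round-off at the 1e-9 level
        if (p < -1e-9).any() or (p > 1 + 1e-9).any():
            raise ValueError("occupancies must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("occupancies must sum to 1 at every time")
        self.times = t
        self.occupancies = np.clip(p, 0.0, 1.0)

    def occupancy(self, state: str) -> np.ndarray:
        return self.occupancies[:, self.states.index(state)]

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """CSV with '#'-prefixed metadata, then time_s + one column per state."""
        df = pd.DataFrame(self.occupancies, columns=list(self.states))
        df.insert(0, "time_s", self.times)
        with open(path, "w") as fh:
            for key, value in self.metadata.items():
                fh.write(f"# {key} = {value}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "PopulationTrajectory":
        meta = _read_metadata(path)
        df = pd.read_csv(path, comment="#")
        if "time_s" not in df.columns:
            raise ConfigurationError(f"{path}: missing time_s column")
        states = tuple(c for c in df.columns if c != "time_s")
        return cls(times=df["time_s"].to_numpy(),
                   occupancies=df[list(states)].to_numpy(),
                   states=states, metadata=meta)


def _trajectory_metadata(rate_matrix: RateMatrix) -> dict:
    ps = rate_matrix.pmf_state
    return {
        "o2_conc_M": rate_matrix.o2_conc,
        "delta_psi_mV": ps.delta_psi,
        "delta_ph": ps.delta_ph,
        "temperature_K": ps.temperature,
    }


def _check_initial(initial, n: int) -> np.ndarray:
    p0 = np.asarray(initial, dtype=float)
    if p0.shape != (n,):
        raise ValueError(f"initial occupancy must have length {n}")
    if (p0 < 0).any() or not math.isclose(p0.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("initial occupancies must be non-negative and sum to 1")
    return p0


def solve_populations(rate_matrix: RateMatrix, initial=None,
                      times=None) -> PopulationTrajectory:
    """Propagate dp/dt = K p exactly via eigendecomposition of K.

    Defaults: all population in the first state at t = 0, on the standard
    logarithmic grid.  Falls back to matrix-exponential stepping when the
    eigenvector basis is ill-conditioned (near-degenerate rates).
    """
    K = rate_matrix.matrix
    n = K.shape[0]
    if initial is None:
        initial = np.eye(n)[0]
    if times is None:
        times = default_time_grid()
    p0 = _check_initial(initial, n)
    t = np.asarray(times, dtype=float)

    lam, V = np.linalg.eig(K)
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(V)
    if np.isfinite(cond) and cond < 1e10:
        c = np.linalg.solve(V, p0)
        occ = np.real((V * c) @ np.exp(np.outer(lam, t))).T
    else:  # defective/near-degenerate generator: step with expm
        from scipy.linalg import expm
        occ = np.empty((t.size, n))
        p = p0.copy()
        prev = 0.0
        for i, ti in enumerate(t):
            p = expm(K * (ti - prev)) @ p
            occ[i] = p
            prev = ti
    if not np.isfinite(occ).all():
        raise NumericalFailureError(
            f"eigen propagation produced non-finite occupancies "
            f"(cond(V)={cond:.3g})")
    occ = np.clip(occ, 0.0, 1.0)
    occ /= occ.sum(axis=1, keepdims=True)
    return PopulationTrajectory(times=t, occupancies=occ,
                                states=rate_matrix.states,
                                metadata=_trajectory_metadata(rate_matrix))


def solve_populations_ode(rate_matrix: RateMatrix, initial=None,
                          times=None) -> PopulationTrajectory:
    """Independent stiff-ODE propagation of the same master equation.

    Exists as a cross-check oracle for :func:`solve_populations`; uses LSODA
    with an analytic Jacobian at tight tolerances.
    """
    K = rate_matrix.matrix
    n = K.shape[0]
    if initial is None:
        initial = np.eye(n)[0]
    if times is None:
        times = default_time_grid()
    p0 = _check_initial(initial, n)
    t = np.asarray(times, dtype=float)
    t_eval = t if t[0] == 0 else np.concatenate([[0.0], t])
    sol = solve_ivp(lambda _t, p: K @ p, (0.0, t[-1]), p0, t_eval=t_eval,
                    method="LSODA", jac=lambda _t, _p: K,
                    rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise NumericalFailureError(f"ODE integration failed: {sol.message}")
    occ = sol.y.T
    if t[0] != 0:
        occ = occ[1:]
    occ = np.clip(occ, 0.0, 1.0)
    occ /= occ.sum(axis=1, keepdims=True)
    return PopulationTrajectory(times=t, occupancies=occ,
                                states=rate_matrix.states,
                                metadata=_trajectory_metadata(rate_matrix))


# --------------------------------------------------------------- config I/O

def _reject_unknown_keys(mapping, allowed: set, where: str) -> None:
    if not isinstance(mapping, dict):
        raise ConfigurationError(f"{where}: expected a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"{where}: unknown keys {sorted(unknown)} (allowed: {sorted(allowed)})")


def _read_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line.lstrip("# ").partition("=")
                value = value.strip()
                try:
                    parsed = json.loads(value)
                except json.JSONDecodeError:
                    parsed = value
                meta[key.strip()] = parsed
    return meta


def load_config(path) -> dict:
    """Load a flat JSON config with scheme/pmf/o2 sections, rejecting unknown keys.

    Returns a dict with keys ``scheme`` (:class:`ReactionScheme`), ``pmf``
    (:class:`PmfState`) and ``o2_conc`` (M); every section is optional and
    defaults to the package defaults.
    """
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    _reject_unknown_keys(raw, {"scheme", "pmf", "o2_conc_m"}, "config")
    scheme = (ReactionScheme.from_dict(raw["scheme"]) if "scheme" in raw
              else default_scheme())
    if "pmf" in raw:
        _reject_unknown_keys(raw["pmf"],
                             {"delta_psi_mv", "delta_ph", "temperature_k"},
                             "config pmf")
        try:
            pmf_state = PmfState(
                delta_psi=float(raw["pmf"].get("delta_psi_mv", 0.0)),
                delta_ph=float(raw["pmf"].get("delta_ph", 0.0)),
                temperature=float(raw["pmf"].get("temperature_k",
                                                 DEFAULT_TEMPERATURE)))
        except ValueError as exc:
            raise ConfigurationError(f"config pmf: {exc}") from exc
    else:
        pmf_state = PmfState()
    o2 = float(raw.get("o2_conc_m", DEFAULT_O2_CONC))
    if o2 <= 0:
        raise ConfigurationError("config o2_conc_m must be > 0")
    return {"scheme": scheme, "pmf": pmf_state, "o2_conc": o2}
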