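"""Nucleation–elongation kinetics and a pyrene-assay observation model.

This module generates synthetic actin-polymerization trajectories with the
structure that pyrene-fluorescence experiments assume: a slow nucleation
phase, a log (elongation) phase, and a steady state at the critical
concentration, optionally perturbed by mid-run addition of a nucleator
(e.g. an intrinsically disordered titin PEVK fragment).

The kinetic scheme is a minimal Oosawa-type nucleation–elongation model.
With ``m`` the free-monomer concentration (µM), ``c_f`` the polymerized
concentration (µM) and ``N`` the filament number concentration (µM):

    dN/dt   = k_nuc * m**n_c + k_seed * P * m**s_c
    dc_f/dt = n_c * dN/dt + (k_plus * m - k_minus) * N
    dm/dt   = -dc_f/dt

where ``P`` is the nucleator concentration (nM).  Each new nucleus books
``n_c`` monomers into the polymer pool at creation, so mass is conserved
exactly (``m + c_f = actin_total``).  The steady-state free monomer is the
critical concentration ``Cc = k_minus / k_plus``, independent of either
nucleation pathway — which is precisely the property the critical
concentration analysis downstream tests.

The observation model converts polymer mass into pyrene-like fluorescence:

    F(t) = baseline + gain * labeled_fraction * c_f(t) * exp(-k_bleach * E(t)) + ε

with ``E(t)`` the cumulative illuminated exposure under the configured
schedule (continuous, or intermittent windows for photobleaching-sparing
protocols) and ε i.i.d. Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .cc import SteadyStateSeries

__all__ = [
    "ValidationError",
    "IntegrationError",
    "SteadyStateError",
    "KineticParams",
    "AdditionEvent",
    "KineticState",
    "IlluminationSchedule",
    "ObservationParams",
    "FluorescenceTrace",
    "simulate_polymerization",
    "observe_fluorescence",
    "simulate_dose_series",
    "simulate_cc_series",
    "write_traces",
    "read_traces",
    "params_from_dict",
    "observation_from_dict",
]


class ValidationError(ValueError):
    """Raised when input parameters violate their documented invariants."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to meet the requested tolerance."""


class SteadyStateError(RuntimeError):
    """Raised when a trajectory has not reached steady state by t_end."""


# Solver tolerances (stiff-safe; dense output resampled onto the user grid).
RTOL = 1e-8
ATOL = 1e-10
# Magnitude below which tiny solver-noise negatives are snapped to zero.
_SNAP = 1e-9
# Smooth depolymerization floor (µM): net-negative elongation is scaled by
# c_f/(c_f + _CF_FLOOR) so sub-critical runs cannot drive c_f below zero.
# The scale is far below any observable polymer signal but wide enough that
# sub-critical trajectories stay non-stiff.
_CF_FLOOR = 1e-3


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Rate constants and composition for one polymerization run.

    Units: concentrations in µM (actin) and nM (nucleator); ``k_plus`` in
    µM⁻¹ s⁻¹, ``k_minus`` in s⁻¹, ``k_nuc`` in µM^(1−n_c) s⁻¹, ``k_seed``
    in nM⁻¹ µM^(−s_c) s⁻¹.  Defaults are literature-typical barbed-end
    values (k_plus 11.6 µM⁻¹ s⁻¹, k_minus 1.4 s⁻¹, hence Cc ≈ 0.121 µM)
    with nucleation constants chosen so a 4 µM assay reaches steady state
    within a 2000 s measurement window.
    """

    k_plus: float = 11.6
    k_minus: float = 1.4
    k_nuc: float = 2e-8
    n_c: int = 3
    k_seed: float = 1e-7
    s_c: int = 1
    nucleator_conc: float = 0.0
    actin_total: float = 4.0
    labeled_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in ("k_plus", "k_minus", "k_nuc", "k_seed",
                     "nucleator_conc", "actin_total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_c < 2:
            raise ValidationError(f"n_c must be >= 2, got {self.n_c}")
        if self.s_c < 1:
            raise ValidationError(f"s_c must be >= 1, got {self.s_c}")
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValidationError("labeled_fraction must lie in [0, 1]")

    @property
    def critical_concentration(self) -> float:
        """Cc = k_minus / k_plus (µM); inf when k_plus == 0."""
        return self.k_minus / self.k_plus if self.k_plus > 0 else float("inf")


@dataclass(frozen=True)
class AdditionEvent:
    """Instantaneous addition of nucleator at a given time (no dead time)."""

    time: float
    delta_nucleator: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError("event time must be >= 0")
        if self.delta_nucleator < 0:
            raise ValidationError("delta_nucleator must be >= 0")


@dataclass
class KineticState:
    """Trajectory of the simulator: the assay's ground truth.

    Attributes
    ----------
    t : time grid (s)
    m : free monomer (µM)
    c_f : polymerized actin (µM)
    N : filament number concentration (µM)
    params : the parameters used (with any events applied over time)
    """

    t: np.ndarray
    m: np.ndarray
    c_f: np.ndarray
    N: np.ndarray
    params: KineticParams
    final_nucleator: float = 0.0


@dataclass(frozen=True)
class IlluminationSchedule:
    """Continuous illumination, or intermittent measurement windows.

    Intermittent: the sample is illuminated for ``window_s`` seconds at the
    start of every ``period_s`` seconds (default one 10 s reading every
    10 min, the photobleaching-sparing protocol).
    """

    mode: str = "continuous"
    window_s: float = 10.0
    period_s: float = 600.0

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "intermittent"):
            raise ValidationError(f"unknown schedule mode {self.mode!r}")
        if self.mode == "intermittent" and not 0 < self.window_s < self.period_s:
            raise ValidationError("intermittent schedule requires period > window > 0")

    def exposure(self, t: np.ndarray) -> np.ndarray:
        """Cumulative illuminated time E(t) in seconds."""
        t = np.asarray(t, dtype=float)
        if self.mode == "continuous":
            return t.copy()
        n_full = np.floor(t / self.period_s)
        rem = t - n_full * self.period_s
        return n_full * self.window_s + np.minimum(rem, self.window_s)

    def illuminated(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask of times at which a sample is being measured."""
        t = np.asarray(t, dtype=float)
        if self.mode == "continuous":
            return np.ones_like(t, dtype=bool)
        rem = t - np.floor(t / self.period_s) * self.period_s
        return rem <= self.window_s


@dataclass(frozen=True)
class ObservationParams:
    """Fluorometer model: gain, baseline, photobleaching, noise, schedule."""

    gain: float = 100.0
    baseline: float = 5.0
    k_bleach: float = 0.0
    noise_sd: float = 0.0
    schedule: IlluminationSchedule = field(default_factory=IlluminationSchedule)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValidationError("gain must be > 0")
        if self.k_bleach < 0:
            raise ValidationError("k_bleach must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class FluorescenceTrace:
    """A time/intensity series with its condition and schedule metadata."""

    t: np.ndarray
    F: np.ndarray
    condition: str = ""
    schedule: IlluminationSchedule = field(default_factory=IlluminationSchedule)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.shape != self.F.shape:
            raise ValidationError("t and F must have the same length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValidationError("t must be strictly increasing")


# --------------------------------------------------------------------------
# ODE integration
# --------------------------------------------------------------------------

def _rhs(t: float, y: np.ndarray, p: KineticParams, nucleator: float):
    m, N = y
    m_eff = m if m > 0.0 else 0.0
    cf = p.actin_total - m
    cf_eff = cf if cf > 0.0 else 0.0
    J = p.k_nuc * m_eff ** p.n_c + p.k_seed * nucleator * m_eff ** p.s_c
    growth = p.k_plus * m_eff - p.k_minus
    if growth < 0.0:
        growth *= cf_eff / (cf_eff + _CF_FLOOR)
    dcf = p.n_c * J + growth * N
    return (-dcf, J)


def simulate_polymerization(
    params: KineticParams,
    t_grid: Sequence[float],
    events: Sequence[AdditionEvent] = (),
) -> KineticState:
    """Integrate the nucleation–elongation scheme on a user time grid.

    ``events`` are instantaneous nucleator additions; at each event time the
    nucleator concentration in the seeding term steps up by
    ``delta_nucleator``.  The nucleator acts catalytically (it is not
    consumed).

    Raises
    ------
    ValidationError
        for an invalid grid or unsorted events.
    IntegrationError
        if the stiff solver fails, or the solution leaves the physical
        region by more than the solver tolerance.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValidationError("t_grid must be a 1-D grid with at least 2 points")
    if t_grid[0] != 0.0:
        raise ValidationError("t_grid must start at 0")
    if np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be strictly increasing")
    events = list(events)
    if any(events[i].time > events[i + 1].time for i in range(len(events) - 1)):
        raise ValidationError("events must be sorted by time")

    t_end = float(t_grid[-1])
    nucleator = params.nucleator_conc
    # events at t == 0 fold into the initial nucleator concentration
    pending = []
    for ev in events:
        if ev.time == 0.0:
            nucleator += ev.delta_nucleator
        elif ev.time < t_end:
            pending.append(ev)

    boundaries = [0.0] + [ev.time for ev in pending] + [t_end]
    deltas = [ev.delta_nucleator for ev in pending] + [0.0]

    m = np.empty_like(t_grid)
    N = np.empty_like(t_grid)
    y = np.array([params.actin_total, 0.0])
    for (t0, t1), delta in zip(zip(boundaries[:-1], boundaries[1:]), deltas):
        sel = (t_grid >= t0) & (t_grid <= t1)
        t_eval = np.unique(np.concatenate([t_grid[sel], [t0, t1]]))
        sol = solve_ivp(
            _rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
            rtol=RTOL, atol=ATOL, args=(params, nucleator),
        )
        if not sol.success:
            raise IntegrationError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
        keep = np.isin(sol.t, t_grid[sel])
        m[sel] = sol.y[0][keep]
        N[sel] = sol.y[1][keep]
        y = sol.y[:, -1]
        nucleator += delta

    c_f = params.actin_total - m
    for name, arr in (("m", m), ("c_f", c_f), ("N", N)):
        if arr.min() < -_SNAP:
            raise IntegrationError(
                f"{name} became negative ({arr.min():.3e}) beyond solver tolerance"
            )
    np.clip(m, 0.0, None, out=m)
    np.clip(c_f, 0.0, None, out=c_f)
    np.clip(N, 0.0, None, out=N)
    return KineticState(t=t_grid.copy(), m=m, c_f=c_f, N=N,
                        params=params, final_nucleator=nucleator)


def polymerization_rate(state: KineticState, index: int = -1) -> float:
    """dc_f/dt (µM/s) evaluated from the rate law at one grid point."""
    y = (state.m[index], state.N[index])
    dm, _ = _rhs(state.t[index], y, state.params, state.final_nucleator)
    return -dm


# --------------------------------------------------------------------------
# Observation model
# --------------------------------------------------------------------------

def _intensity(cf: np.ndarray, exposure: np.ndarray, labeled_fraction: float,
               obs: ObservationParams) -> np.ndarray:
    return obs.baseline + obs.gain * labeled_fraction * cf * np.exp(
        -obs.k_bleach * exposure)


def observe_fluorescence(state: KineticState, obs: ObservationParams,
                         condition: str = "") -> FluorescenceTrace:
    """Convert a trajectory into a pyrene-like fluorescence trace.

    For intermittent schedules samples are emitted only at illuminated
    times; the photobleaching exposure E(t) accumulates only while the
    sample is illuminated, so intermittent readings bleach less than
    continuous ones.  Noise is i.i.d. Gaussian, reproducible under
    ``obs.rng_seed``.
    """
    illum = obs.schedule.illuminated(state.t)
    t = state.t[illum]
    cf = state.c_f[illum]
    E = obs.schedule.exposure(t)
    F = _intensity(cf, E, state.params.labeled_fraction, obs)
    if obs.noise_sd > 0:
        rng = np.random.default_rng(obs.rng_seed)
        F = F + rng.normal(0.0, obs.noise_sd, size=F.shape)
    return FluorescenceTrace(t=t, F=F, condition=condition, schedule=obs.schedule)


def simulate_dose_series(
    base: KineticParams,
    nucleator_concs: Sequence[float],
    t_grid: Sequence[float],
    obs: ObservationParams,
    events: Sequence[AdditionEvent] = (),
) -> list[FluorescenceTrace]:
    """One trace per nucleator concentration, all other parameters shared.

    Noise seeds are per-trace (``obs.rng_seed + index``) so replicate
    series are independent yet fully reproducible.
    """
    concs = list(nucleator_concs)
    if not concs:
        raise ValidationError("nucleator_concs must be nonempty")
    if any(c < 0 for c in concs):
        raise ValidationError("nucleator concentrations must be >= 0")
    traces = []
    for i, conc in enumerate(concs):
        params = dataclasses.replace(base, nucleator_conc=conc)
        state = simulate_polymerization(params, t_grid, events)
        obs_i = dataclasses.replace(obs, rng_seed=obs.rng_seed + i)
        traces.append(observe_fluorescence(state, obs_i,
                                           condition=f"nucleator_{conc:g}nM"))
    return traces


def simulate_cc_series(
    base: KineticParams,
    actin_concs: Sequence[float],
    t_end: float,
    obs: ObservationParams,
    steady_tol: float = 1e-5,
    condition: str = "",
    n_grid: int = 400,
) -> SteadyStateSeries:
    """Steady-state intensity vs total actin concentration.

    Each concentration is integrated to ``t_end``; the run errors out,
    naming the offending concentration, if |dc_f/dt| at t_end exceeds
    ``steady_tol`` (µM/s).  The intensity is the observation model
    evaluated at exactly t_end with the schedule's accumulated exposure
    (default schedule: intermittent, one reading per 10 min).
    """
    concs = list(actin_concs)
    if not concs:
        raise ValidationError("actin_concs must be nonempty")
    if any(c < 0 for c in concs):
        raise ValidationError("actin concentrations must be >= 0")
    order = np.argsort(concs)
    t_grid = np.linspace(0.0, float(t_end), n_grid)
    intensities = np.empty(len(concs))
    rng = np.random.default_rng(obs.rng_seed)
    for i in order:
        params = dataclasses.replace(base, actin_total=concs[i])
        state = simulate_polymerization(params, t_grid)
        rate = polymerization_rate(state)
        if abs(rate) > steady_tol:
            raise SteadyStateError(
                f"steady state not reached at actin {concs[i]:g} µM: "
                f"|dc_f/dt| = {abs(rate):.3e} µM/s > {steady_tol:g} at t_end={t_end:g} s"
            )
        E_end = float(obs.schedule.exposure(np.array([t_end]))[0])
        F = float(_intensity(np.array([state.c_f[-1]]), np.array([E_end]),
                             params.labeled_fraction, obs)[0])
        if obs.noise_sd > 0:
            F += rng.normal(0.0, obs.noise_sd)
        intensities[i] = F
    conc_sorted = np.asarray(concs, dtype=float)[order]
    return SteadyStateSeries(actin_conc=conc_sorted, intensity=intensities[order],
                             condition=condition)


# --------------------------------------------------------------------------
# Tabular I/O and config
# --------------------------------------------------------------------------

def write_traces(traces: Sequence[FluorescenceTrace], path) -> None:
    """Long-format CSV: time_s,intensity_au,condition,schedule."""
    frames = []
    for tr in traces:
        sched = tr.schedule.mode
        if tr.schedule.mode == "intermittent":
            sched = f"intermittent:{tr.schedule.window_s:g}/{tr.schedule.period_s:g}"
        frames.append(pd.DataFrame({
            "time_s": tr.t, "intensity_au": tr.F,
            "condition": tr.condition, "schedule": sched,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list[FluorescenceTrace]:
    """Read the trace CSV dialect written by :func:`write_traces`."""
    df = pd.read_csv(path)
    required = {"time_s", "intensity_au", "condition"}
    if not required.issubset(df.columns):
        raise ValidationError(f"trace file must have columns {sorted(required)}")
    traces = []
    for cond, grp in df.groupby("condition", sort=False):
        sched = IlluminationSchedule()
        if "schedule" in grp.columns:
            tag = str(grp["schedule"].iloc[0])
            if tag.startswith("intermittent"):
                try:
                    window, period = tag.split(":")[1].split("/")
                    sched = IlluminationSchedule("intermittent",
                                                 float(window), float(period))
                except (IndexError, ValueError):
                    sched = IlluminationSchedule("intermittent")
        traces.append(FluorescenceTrace(
            t=grp["time_s"].to_numpy(), F=grp["intensity_au"].to_numpy(),
            condition=str(cond), schedule=sched))
    return traces


def params_from_dict(d: dict) -> KineticParams:
    """Build KineticParams from a (YAML/JSON) mapping; unknown keys error."""
    known = {f.name for f in dataclasses.fields(KineticParams)}
    extra = set(d) - known
    if extra:
        raise ValidationError(f"unknown kinetic parameter(s): {sorted(extra)}")
    return KineticParams(**d)


def observation_from_dict(d: dict) -> ObservationParams:
    """Build ObservationParams from a mapping; 'schedule' may be a sub-dict."""
    d = dict(d)
    sched = d.pop("schedule", None)
    known = {f.name for f in dataclasses.fields(ObservationParams)} - {"schedule"}
    extra = set(d) - known
    if extra:
        raise ValidationError(f"unknown observation parameter(s): {sorted(extra)}")
    if sched is not None:
        d["schedule"] = IlluminationSchedule(**sched)
    return ObservationParams(**d)
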