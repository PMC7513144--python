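"""Deterministic and stochastic dynamics of a cascade, and cycle timing.

Two integrators share one reaction network:

* :func:`simulate_ode` — mass-action rate equations solved with a
  stiff-capable adaptive method (LSODA, rtol 1e-8).
* :func:`simulate_stochastic` — Gillespie's direct method on molecule
  counts obtained by scaling concentrations with the system size Omega
  (``spec.volume_scale``); exact, event-driven, reproducible per seed.

On top of a trajectory, :func:`extract_timing` reads off the two phases of a
signalling cycle: the activation transient tau_j (time for the active
concentration to first reach a fraction of its peak excess over baseline)
and the recovery tau_-j (time from there until the excess has decayed below
a small fraction of the peak).  tau_-j is stored negative; the sign encodes
the direction of the half-cycle, and the cycle duration is tau_j - tau_-j.

:func:`synthetic_pulse_trajectory` generates the stereotyped single-cycle
time course seen in phosphorylation assays — a fast rise followed by a much
slower recovery — as a double-exponential pulse per step.  It is the study
condition for the entropy-coding analyses, where the recovery phase is
postulated to be far slower than the activation phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .cascade_model import CascadeSpec, CascadeState, CascadeValidationError

logger = logging.getLogger(__name__)

FWD = "fwd"
REV = "rev"


class IntegrationError(RuntimeError):
    """The ODE solver failed; message carries the solver's diagnostic."""


class TimingUndefinedError(ValueError):
    """No usable transient (flat trajectory or unfinished recovery)."""


class Event(NamedTuple):
    """One stochastic reaction firing: time, 1-based step, direction."""

    time: float
    step: int
    direction: str


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed cascade concentrations, deterministic or stochastic.

    ``X`` and ``Xstar`` are ``(n_times, n_steps)`` arrays.  ``A`` tracks the
    mediator concentration (constant under the chemostat).  ``event_log`` is
    populated only by the stochastic simulator.
    """

    times: np.ndarray
    X: np.ndarray
    Xstar: np.ndarray
    kind: str
    A: np.ndarray | None = None
    mrna: np.ndarray | None = None
    seed: int | None = None
    event_log: tuple[Event, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise CascadeValidationError("times must be strictly increasing, length >= 2")
        object.__setattr__(self, "times", t)
        for name in ("X", "Xstar"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape[0] != t.size:
                raise CascadeValidationError(f"{name} rows must match times")
            object.__setattr__(self, name, v)
        if self.event_log is not None:
            object.__setattr__(self, "event_log", tuple(Event(*e) for e in self.event_log))

    @property
    def n_steps(self) -> int:
        return self.Xstar.shape[1]

    def state_at(self, i: int) -> CascadeState:
        return CascadeState(time=self.times[i], X=self.X[i], Xstar=self.Xstar[i])


class TimingEntry(NamedTuple):
    """Cycle timing of one step: tau_fwd > 0, tau_rev <= 0."""

    tau_fwd: float
    tau_rev: float

    @property
    def cycle_duration(self) -> float:
        return self.tau_fwd - self.tau_rev


@dataclass(frozen=True)
class TimingProfile:
    """Per-step activation/recovery durations extracted from one trajectory."""

    tau_fwd: np.ndarray
    tau_rev: np.ndarray

    def __post_init__(self) -> None:
        tf = np.atleast_1d(np.asarray(self.tau_fwd, dtype=float))
        tr = np.atleast_1d(np.asarray(self.tau_rev, dtype=float))
        if tf.shape != tr.shape:
            raise CascadeValidationError("tau_fwd and tau_rev must match in length")
        if np.any(tf <= 0):
            raise CascadeValidationError("tau_fwd must be positive")
        if np.any(tr > 0):
            raise CascadeValidationError("tau_rev must be nonpositive (sign convention)")
        object.__setattr__(self, "tau_fwd", tf)
        object.__setattr__(self, "tau_rev", tr)

    @property
    def cycle_duration(self) -> np.ndarray:
        return self.tau_fwd - self.tau_rev


def _rhs_factory(
    spec: CascadeSpec, atp_mode: str, atp_drain_rate: float, ligand: float | None = None
):
    n = spec.n_steps
    k_on_L = spec.k_on * (spec.ligand if ligand is None else ligand)

    def rhs(t, y):
        xstar = y[:n]
        A = max(y[n], 0.0) if atp_mode != "chemostat" else spec.A0
        x = spec.X0 - xstar
        dx = np.empty(n + 2)
        dx[0] = k_on_L * x[0] - spec.k_off * xstar[0]
        v_fwd_sum = 0.0
        for i in range(n - 1):
            v_fwd = spec.k_fwd[i] * A * xstar[i] * x[i + 1]
            v_rev = spec.k_rev[i] * spec.Ph[i + 1] * xstar[i + 1]
            dx[i + 1] = v_fwd - v_rev
            v_fwd_sum += v_fwd
        if spec.k_out > 0:
            dx[n - 1] -= spec.k_out * xstar[n - 1]
        if atp_mode == "chemostat":
            dx[n] = 0.0
        elif atp_mode == "drain":
            dx[n] = -atp_drain_rate
        elif atp_mode == "consume":
            dx[n] = -v_fwd_sum
        else:
            raise ValueError(f"unknown atp_mode {atp_mode!r}")
        dx[n + 1] = spec.k_out * xstar[n - 1]
        return dx

    return rhs


def simulate_ode(
    spec: CascadeSpec,
    stimulus: float = 0.0,
    t_grid: Sequence[float] | None = None,
    *,
    t_max: float | None = None,
    n_points: int = 401,
    atp_mode: str = "chemostat",
    atp_drain_rate: float = 0.0,
    xstar0: Sequence[float] | None = None,
    ligand_pulse: tuple[float, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> Trajectory:
    """Integrate the cascade rate equations.

    Parameters
    ----------
    stimulus
        Initial active fraction of step 1 (the receptor), in [0, 1].  With
        ``spec.ligand == 0`` this produces a transient pulse that the cascade
        relays downstream and then recovers from; with a sustained ligand the
        trajectory converges to the kinetic steady state.
    t_grid
        Strictly increasing output times; alternatively give ``t_max`` (and
        optionally ``n_points``) for a uniform grid starting at 0.
    atp_mode
        ``"chemostat"`` (default) holds A at ``spec.A0``; ``"drain"`` removes
        A at ``atp_drain_rate`` per unit time; ``"consume"`` couples A loss to
        the summed forward activation flux (one mediator per activation).
    xstar0
        Full initial active-concentration vector; overrides ``stimulus``
        (useful for starting at a steady state).
    ligand_pulse
        ``(L_value, t_off)``: hold the ligand at ``L_value`` until ``t_off``,
        then return it to the spec's baseline level.  Combined with
        ``xstar0`` at the resting steady state this produces the stereotyped
        stimulus-and-recovery cycle.
    """
    if not 0 <= stimulus <= 1:
        raise CascadeValidationError("stimulus must lie in [0, 1]")
    if t_grid is None:
        if t_max is None:
            raise ValueError("provide t_grid or t_max")
        t_grid = np.linspace(0.0, float(t_max), n_points)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise CascadeValidationError("t_grid must be strictly increasing")

    n = spec.n_steps
    y0 = np.zeros(n + 2)
    if xstar0 is not None:
        xs0 = np.asarray(xstar0, dtype=float)
        if xs0.shape != (n,) or np.any(xs0 < 0) or np.any(xs0 > spec.X0):
            raise CascadeValidationError("xstar0 must lie in [0, X0] per step")
        y0[:n] = xs0
    else:
        y0[0] = stimulus * spec.X0[0]
    y0[n] = spec.A0

    def _segment(y_init, t_lo, t_hi, t_eval, ligand):
        rhs = _rhs_factory(spec, atp_mode, atp_drain_rate, ligand)
        sol = solve_ivp(
            rhs, (t_lo, t_hi), y_init, t_eval=t_eval,
            method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed at t={sol.t[-1] if sol.t.size else t_lo}: "
                f"{sol.message}"
            )
        return sol

    if ligand_pulse is not None and t_grid[0] < ligand_pulse[1] < t_grid[-1]:
        L_val, t_off = float(ligand_pulse[0]), float(ligand_pulse[1])
        first = t_grid[t_grid <= t_off]
        second = t_grid[t_grid > t_off]
        sol_a = _segment(y0, t_grid[0], t_off, first, L_val)
        sol_b = _segment(sol_a.y[:, -1], t_off, t_grid[-1], second, None)
        times = np.concatenate([sol_a.t[: first.size], sol_b.t])
        ys = np.concatenate([sol_a.y[:, : first.size], sol_b.y], axis=1)
    else:
        ligand = ligand_pulse[0] if ligand_pulse is not None else None
        sol = _segment(y0, t_grid[0], t_grid[-1], t_grid, ligand)
        times, ys = sol.t, sol.y
    xstar = np.clip(ys[:n].T, 0.0, spec.X0)
    return Trajectory(
        times=times,
        X=spec.X0 - xstar,
        Xstar=xstar,
        A=ys[n],
        mrna=ys[n + 1] if spec.k_out > 0 else None,
        kind="deterministic",
    )


def simulate_stochastic(
    spec: CascadeSpec,
    stimulus: float = 0.0,
    t_max: float = 10.0,
    seed: int = 0,
    *,
    n_points: int = 256,
    atp_consume: bool = False,
    max_events: int = 10_000_000,
) -> Trajectory:
    """Exact event-driven simulation (Gillespie direct method).

    Concentrations are converted to counts with Omega = ``spec.volume_scale``;
    propensities are the Omega-scaled mass-action rates.  The event log records
    every firing as ``(time, step, direction)`` where ``direction`` is ``fwd``
    for an activation of the step and ``rev`` for its deactivation.  Runs are
    reproducible for a fixed seed.
    """
    if not 0 <= stimulus <= 1:
        raise CascadeValidationError("stimulus must lie in [0, 1]")
    n = spec.n_steps
    omega = spec.volume_scale
    totals = np.round(omega * spec.X0).astype(np.int64)
    if np.any(totals < 1):
        raise CascadeValidationError("volume_scale * X0 must be >= 1 for every step")
    n_star = np.zeros(n, dtype=np.int64)
    n_star[0] = int(round(totals[0] * stimulus))
    A = spec.A0
    k_on_L = spec.k_on * spec.ligand

    rng = np.random.default_rng(seed)
    t_grid = np.linspace(0.0, float(t_max), n_points)
    rec_X = np.empty((n_points, n), dtype=float)
    rec_S = np.empty((n_points, n), dtype=float)
    rec_A = np.empty(n_points, dtype=float)
    grid_i = 0
    events: list[Event] = []
    mrna = 0

    # propensities: [act_1, deact_1, act_2, deact_2, ..., act_n, deact_n(, out)]
    prop = np.zeros(2 * n + (1 if spec.k_out > 0 else 0))
    t = 0.0
    n_events = 0
    while True:
        prop[0] = k_on_L * (totals[0] - n_star[0])
        prop[1] = spec.k_off * n_star[0]
        for i in range(n - 1):
            prop[2 * i + 2] = spec.k_fwd[i] * A * n_star[i] * (totals[i + 1] - n_star[i + 1]) / omega
            prop[2 * i + 3] = spec.k_rev[i] * spec.Ph[i + 1] * n_star[i + 1]
        if spec.k_out > 0:
            prop[2 * n] = spec.k_out * n_star[n - 1]
        total_prop = prop.sum()
        if total_prop <= 0:
            logger.info("zero total propensity at t=%g; trajectory ends early", t)
            break
        t_next = t + rng.exponential(1.0 / total_prop)
        if t_next > t_max or n_events >= max_events:
            break
        while grid_i < n_points and t_grid[grid_i] <= t_next:
            rec_S[grid_i] = n_star / omega
            rec_X[grid_i] = (totals - n_star) / omega
            rec_A[grid_i] = A
            grid_i += 1
        r = int(np.searchsorted(np.cumsum(prop), rng.random() * total_prop))
        t = t_next
        n_events += 1
        if r < 2 * n:
            step = r // 2 + 1
            if r % 2 == 0:
                n_star[step - 1] += 1
                if step > 1 and atp_consume:
                    A = max(A - 1.0 / omega, 0.0)
                events.append(Event(t, step, FWD))
            else:
                n_star[step - 1] -= 1
                events.append(Event(t, step, REV))
        else:
            n_star[n - 1] -= 1
            mrna += 1
            events.append(Event(t, n, REV))
    while grid_i < n_points:
        rec_S[grid_i] = n_star / omega
        rec_X[grid_i] = (totals - n_star) / omega
        rec_A[grid_i] = A
        grid_i += 1
    return Trajectory(
        times=t_grid,
        X=rec_X,
        Xstar=rec_S,
        A=rec_A,
        mrna=None,
        kind="stochastic",
        seed=seed,
        event_log=tuple(events),
    )


def extract_timing(
    traj: Trajectory,
    j: int,
    rise_fraction: float = 0.95,
    recovery_fraction: float = 0.05,
) -> TimingEntry:
    """Activation and recovery durations of step ``j`` (1-based).

    The active-form excess over its initial baseline defines the transient.
    ``tau_fwd`` is the time from trajectory start until the excess first
    reaches ``rise_fraction`` of its peak; ``tau_rev`` is minus the time from
    that crossing until the excess first falls to ``recovery_fraction`` of the
    peak.  First crossings are resolved at the earliest grid time.
    """
    if not 1 <= j <= traj.n_steps:
        raise CascadeValidationError(f"step index j={j} out of range 1..{traj.n_steps}")
    if not 0 < recovery_fraction <= rise_fraction <= 1:
        raise CascadeValidationError(
            "need 0 < recovery_fraction <= rise_fraction <= 1"
        )
    y = traj.Xstar[:, j - 1]
    excess = y - y[0]
    peak = float(excess.max())
    scale = max(float(np.abs(y).max()), 1.0)
    if peak <= 1e-12 * scale:
        raise TimingUndefinedError(f"step {j}: flat trajectory, no transient to time")
    rise_idx = np.flatnonzero(excess >= rise_fraction * peak)
    i_rise = int(rise_idx[0])
    tau_fwd = float(traj.times[i_rise] - traj.times[0])
    if tau_fwd <= 0:
        raise TimingUndefinedError(f"step {j}: transient already risen at t=0")
    after = excess[i_rise + 1:]
    rec_idx = np.flatnonzero(after <= recovery_fraction * peak)
    if rec_idx.size == 0:
        raise TimingUndefinedError(
            f"step {j}: excess never recovers below "
            f"{recovery_fraction:.0%} of peak within the trajectory"
        )
    i_rec = i_rise + 1 + int(rec_idx[0])
    tau_rev = -float(traj.times[i_rec] - traj.times[i_rise])
    return TimingEntry(tau_fwd=tau_fwd, tau_rev=tau_rev)


def timing_profile(
    traj: Trajectory,
    rise_fraction: float = 0.95,
    recovery_fraction: float = 0.05,
    steps: Sequence[int] | None = None,
) -> TimingProfile:
    """Timing of every requested step (default: all) of one trajectory."""
    steps = range(1, traj.n_steps + 1) if steps is None else steps
    entries = [extract_timing(traj, j, rise_fraction, recovery_fraction) for j in steps]
    return TimingProfile(
        tau_fwd=np.array([e.tau_fwd for e in entries]),
        tau_rev=np.array([e.tau_rev for e in entries]),
    )


def synthetic_pulse_trajectory(
    rise_rates: Sequence[float],
    recovery_rates: Sequence[float],
    amplitudes: Sequence[float] | float = 0.8,
    onsets: Sequence[float] | float = 0.0,
    baseline: float = 0.0,
    X0: float = 1.0,
    t_max: float | None = None,
    n_points: int = 4001,
) -> Trajectory:
    """Stereotyped signalling pulses: fast activation, slow recovery.

    Each step's active concentration follows a double-exponential pulse

        Xstar_j(t) = baseline + a_j * (exp(-g_j (t - s_j)) - exp(-r_j (t - s_j)))

    normalised so the peak excess equals ``amplitudes[j]``, with rise rate
    ``r_j`` much larger than recovery rate ``g_j`` in the regime of interest.
    Peaks plus baseline must stay below ``X0`` so the binary-code conservation
    per step holds.
    """
    r = np.atleast_1d(np.asarray(rise_rates, dtype=float))
    g = np.atleast_1d(np.asarray(recovery_rates, dtype=float))
    n = r.size
    if g.size != n:
        raise CascadeValidationError("rise_rates and recovery_rates must match")
    if np.any(r <= 0) or np.any(g <= 0):
        raise CascadeValidationError("rates must be strictly positive")
    if np.any(g >= r):
        raise CascadeValidationError("recovery_rates must be slower than rise_rates")
    amp = np.broadcast_to(np.asarray(amplitudes, float), (n,))
    s = np.broadcast_to(np.asarray(onsets, float), (n,))
    if np.any(amp + baseline > X0):
        raise CascadeValidationError("amplitude + baseline must not exceed X0")
    if t_max is None:
        t_max = float(np.max(s + 6.0 / g))
    t = np.linspace(0.0, t_max, n_points)
    dt = np.clip(t[:, None] - s[None, :], 0.0, None)
    raw = np.exp(-g[None, :] * dt) - np.exp(-r[None, :] * dt)
    t_peak = np.log(r / g) / (r - g)
    peak = np.exp(-g * t_peak) - np.exp(-r * t_peak)
    xstar = baseline + raw * (amp / peak)[None, :]
    return Trajectory(times=t, X=X0 - xstar, Xstar=xstar, kind="deterministic")
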