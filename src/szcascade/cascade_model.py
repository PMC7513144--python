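"""Static specification, kinetics and steady states of a signalling cascade.

A cascade is an ordered chain of activation/inactivation cycles.  Step ``j``
holds a signalling molecule in an inactive form ``X_j`` and an active
(e.g. phosphorylated) form ``X_j*`` whose sum is a conserved total ``X_j^0``.
The active molecule of step ``j`` catalyses, fuelled by a mediator such as
ATP (concentration ``A``), the activation of step ``j+1``; a phosphatase
(concentration ``Ph_{j+1}``) reverts it:

    forward  (j -> j+1):   v_j   = k_j  * A * X_j* * X_{j+1}
    reverse  (j+1 -> j):   v_-j  = k_-j * Ph_{j+1} * X_{j+1}*

The first step is a receptor activated by an extracellular ligand ``L``
(rate ``k_on * L * X_1``) and deactivated unimolecularly (rate
``k_off * X_1*``), which keeps every cycle in the same mass-action shape.

Around the homeostatic point the cascade sits at a detailed balance

    p(j|j+1) * v_-j = p(j+1|j) * v_j,

where the transition probabilities ``p(j+1|j)``, ``p(j|j+1)`` weight the two
directions; they default to 1 (pure rate balance) and are exposed as free
parameters.  Solving the balance with the conservation law gives the
steady-state partition of step ``j+1``:

    X_{j+1}^st  = b / (a + b) * X_{j+1}^0
    X_{j+1}^st* = a / (a + b) * X_{j+1}^0

with ``a = k_j p(j+1|j) A X_j^st*`` and ``b = k_-j p(j|j+1) Ph_{j+1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np


class CascadeValidationError(ValueError):
    """A cascade specification or state violates a structural invariant."""


class DegenerateCascadeError(ValueError):
    """Both the forward and reverse drives of a step vanish."""


def _as_positive_array(value, name: str, length: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1 and length != 1:
        arr = np.full(length, float(arr[0]))
    if arr.shape != (length,):
        raise CascadeValidationError(
            f"{name} must have length {length}, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise CascadeValidationError(f"{name} must be strictly positive and finite")
    return arr


@dataclass(frozen=True)
class CascadeSpec:
    """Static parameters of an ``n``-step cascade.

    Parameters
    ----------
    step_names
        Unique identifier per step, upstream to downstream.
    X0
        Total concentration per step (active + inactive), length ``n``.
    k_fwd, k_rev
        Kinetic coefficients of the ``n - 1`` inter-step transitions;
        ``k_fwd[i]`` drives activation of step ``i + 2`` by step ``i + 1``
        (1-based transition ``j = i + 1``).
    Ph
        Phosphatase concentration per step.  ``Ph[0]`` is unused: the
        receptor deactivates through ``k_off``.
    A0
        Mediator (ATP) concentration; held by a chemostat unless a finite-ATP
        simulation mode says otherwise.
    temperature_kBT
        Energy unit k_B*T; 1 keeps every thermodynamic output dimensionless.
    volume_scale
        Omega, converting concentrations to molecule counts
        (``count = round(Omega * concentration)``) for stochastic simulation.
    ligand, k_on, k_off
        Receptor drive: ligand concentration (may be zero = unstimulated)
        and the receptor on/off kinetic coefficients.
    k_out
        Optional irreversible pseudo-first-order drain on the terminal active
        molecule (transcription step); its product is tracked only as a
        cumulative counter.
    """

    step_names: tuple[str, ...]
    X0: np.ndarray
    k_fwd: np.ndarray
    k_rev: np.ndarray
    Ph: np.ndarray
    A0: float = 1.0
    temperature_kBT: float = 1.0
    volume_scale: float = 1.0
    ligand: float = 0.0
    k_on: float = 1.0
    k_off: float = 1.0
    k_out: float = 0.0

    def __post_init__(self) -> None:
        names = tuple(str(s) for s in self.step_names)
        if len(names) < 1:
            raise CascadeValidationError("cascade needs at least one step")
        if len(set(names)) != len(names):
            raise CascadeValidationError("step_names must be unique")
        n = len(names)
        object.__setattr__(self, "step_names", names)
        object.__setattr__(self, "X0", _as_positive_array(self.X0, "X0", n))
        object.__setattr__(self, "Ph", _as_positive_array(self.Ph, "Ph", n))
        n_trans = max(n - 1, 0)
        if n_trans:
            object.__setattr__(
                self, "k_fwd", _as_positive_array(self.k_fwd, "k_fwd", n_trans)
            )
            object.__setattr__(
                self, "k_rev", _as_positive_array(self.k_rev, "k_rev", n_trans)
            )
        else:
            object.__setattr__(self, "k_fwd", np.empty(0))
            object.__setattr__(self, "k_rev", np.empty(0))
        for name in ("A0", "temperature_kBT", "volume_scale", "k_on", "k_off"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise CascadeValidationError(f"{name} must be strictly positive")
            object.__setattr__(self, name, v)
        for name in ("ligand", "k_out"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise CascadeValidationError(f"{name} must be nonnegative")
            object.__setattr__(self, name, v)

    @property
    def n_steps(self) -> int:
        return len(self.step_names)

    def receptor_steady_active(self) -> float:
        """Steady active receptor concentration under the spec's ligand level."""
        a = self.k_on * self.ligand
        return a / (a + self.k_off) * self.X0[0]


@dataclass(frozen=True)
class CascadeState:
    """Concentrations of inactive (``X``) and active (``Xstar``) forms at one time."""

    time: float
    X: np.ndarray
    Xstar: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_1d(np.asarray(self.X, dtype=float))
        Xs = np.atleast_1d(np.asarray(self.Xstar, dtype=float))
        if X.shape != Xs.shape:
            raise CascadeValidationError("X and Xstar must have the same length")
        if np.any(X < 0):
            raise CascadeValidationError("X must be nonnegative")
        if np.any(Xs < 0):
            raise CascadeValidationError("Xstar must be nonnegative")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Xstar", Xs)
        object.__setattr__(self, "time", float(self.time))

    @classmethod
    def from_active(cls, spec: CascadeSpec, time: float, Xstar) -> "CascadeState":
        Xs = np.atleast_1d(np.asarray(Xstar, dtype=float))
        return cls(time=time, X=spec.X0 - Xs, Xstar=Xs)

    def check_conservation(self, spec: CascadeSpec, rtol: float = 1e-9) -> None:
        """Raise unless ``X + Xstar = X0`` within ``rtol`` per step."""
        total = self.X + self.Xstar
        bad = np.abs(total - spec.X0) > rtol * spec.X0
        if np.any(bad):
            j = int(np.argmax(bad)) + 1
            raise CascadeValidationError(
                f"conservation violated at step {j}: X+Xstar={total[j - 1]!r} "
                f"vs X0={spec.X0[j - 1]!r}"
            )


class FluxEntry(NamedTuple):
    """Forward and reverse flux of one inter-step transition."""

    v_fwd: float
    v_rev: float


@dataclass(frozen=True)
class FluxRecord:
    """Fluxes and transition probabilities for all ``n - 1`` transitions."""

    v_fwd: np.ndarray
    v_rev: np.ndarray
    p_trans_fwd: np.ndarray
    p_trans_rev: np.ndarray

    def __post_init__(self) -> None:
        for name in ("v_fwd", "v_rev"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise CascadeValidationError(f"{name} must be finite and nonnegative")
            object.__setattr__(self, name, v)
        for name in ("p_trans_fwd", "p_trans_rev"):
            p = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any((p < 0) | (p > 1)):
                raise CascadeValidationError(f"{name} must lie in [0, 1]")
            object.__setattr__(self, name, p)
        lengths = {self.v_fwd.size, self.v_rev.size,
                   self.p_trans_fwd.size, self.p_trans_rev.size}
        if len(lengths) != 1:
            raise CascadeValidationError("flux record fields must share one length")


@dataclass(frozen=True)
class SteadyState:
    """Steady-state partition of every step into inactive/active form."""

    X_st: np.ndarray
    Xstar_st: np.ndarray

    def __post_init__(self) -> None:
        for name in ("X_st", "Xstar_st"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(v < 0):
                raise CascadeValidationError(f"{name} must be nonnegative")
            object.__setattr__(self, name, v)

    def as_state(self, time: float = 0.0) -> CascadeState:
        return CascadeState(time=time, X=self.X_st, Xstar=self.Xstar_st)


def compute_fluxes(spec: CascadeSpec, state: CascadeState, j: int) -> FluxEntry:
    """Mass-action fluxes of transition ``j`` (1-based, ``1 <= j <= n - 1``).

    Returns ``v_j = k_j A X_j* X_{j+1}`` and ``v_-j = k_-j Ph_{j+1} X_{j+1}*``.
    """
    if not 1 <= j <= spec.n_steps - 1:
        raise CascadeValidationError(
            f"transition index j={j} out of range 1..{spec.n_steps - 1}"
        )
    state.check_conservation(spec)
    i = j - 1
    v_fwd = spec.k_fwd[i] * spec.A0 * state.Xstar[i] * state.X[i + 1]
    v_rev = spec.k_rev[i] * spec.Ph[i + 1] * state.Xstar[i + 1]
    return FluxEntry(float(v_fwd), float(v_rev))


def flux_record(
    spec: CascadeSpec,
    state: CascadeState,
    p_trans_fwd=1.0,
    p_trans_rev=1.0,
) -> FluxRecord:
    """All inter-step fluxes of ``state`` plus the transition probabilities."""
    n_trans = spec.n_steps - 1
    entries = [compute_fluxes(spec, state, j) for j in range(1, n_trans + 1)]
    return FluxRecord(
        v_fwd=np.array([e.v_fwd for e in entries]),
        v_rev=np.array([e.v_rev for e in entries]),
        p_trans_fwd=np.broadcast_to(np.asarray(p_trans_fwd, float), (n_trans,)).copy(),
        p_trans_rev=np.broadcast_to(np.asarray(p_trans_rev, float), (n_trans,)).copy(),
    )


def steady_state_entry(
    spec: CascadeSpec,
    j: int,
    xstar_upstream: float,
    p_trans_fwd: float = 1.0,
    p_trans_rev: float = 1.0,
) -> tuple[float, float]:
    """Steady partition of step ``j + 1`` given the upstream active level.

    ``a = k_j p(j+1|j) A X_j^st*`` and ``b = k_-j p(j|j+1) Ph_{j+1}`` split the
    total exactly: ``X_{j+1}^st = b/(a+b) X_{j+1}^0``,
    ``X_{j+1}^st* = a/(a+b) X_{j+1}^0``.
    """
    if not 1 <= j <= spec.n_steps - 1:
        raise CascadeValidationError(
            f"transition index j={j} out of range 1..{spec.n_steps - 1}"
        )
    for name, p in (("p_trans_fwd", p_trans_fwd), ("p_trans_rev", p_trans_rev)):
        if not 0 < p <= 1:
            raise CascadeValidationError(f"{name} must lie in (0, 1], got {p}")
    if xstar_upstream < 0:
        raise CascadeValidationError("xstar_upstream must be nonnegative")
    i = j - 1
    a = spec.k_fwd[i] * p_trans_fwd * spec.A0 * xstar_upstream
    b = spec.k_rev[i] * p_trans_rev * spec.Ph[i + 1]
    if a + b == 0:
        raise DegenerateCascadeError(f"transition {j}: both drives vanish (a = b = 0)")
    total = spec.X0[i + 1]
    return b / (a + b) * total, a / (a + b) * total


def steady_state(
    spec: CascadeSpec,
    p_trans_fwd=1.0,
    p_trans_rev=1.0,
    xstar1: float | None = None,
) -> SteadyState:
    """Propagate the steady state down the whole cascade.

    The receptor level is the ligand balance unless ``xstar1`` overrides it;
    each downstream step then follows the closed-form partition, so the result
    is a fixed point of the kinetics by construction.
    """
    n = spec.n_steps
    pf = np.broadcast_to(np.asarray(p_trans_fwd, float), (max(n - 1, 1),))
    pr = np.broadcast_to(np.asarray(p_trans_rev, float), (max(n - 1, 1),))
    Xstar_st = np.empty(n)
    Xstar_st[0] = spec.receptor_steady_active() if xstar1 is None else float(xstar1)
    for j in range(1, n):
        _, Xstar_st[j] = steady_state_entry(spec, j, Xstar_st[j - 1], pf[j - 1], pr[j - 1])
    return SteadyState(X_st=spec.X0 - Xstar_st, Xstar_st=Xstar_st)


class BalanceCheck(NamedTuple):
    passed: bool
    max_residual: float
    residuals: np.ndarray


def verify_detailed_balance(
    spec: CascadeSpec,
    steady: SteadyState,
    p_trans_fwd=1.0,
    p_trans_rev=1.0,
    tol: float = 1e-12,
) -> BalanceCheck:
    """Residual of the detailed-balance condition at a candidate steady state.

    Returns ``max_j |p(j|j+1) v_-j - p(j+1|j) v_j|`` over all transitions and
    whether it stays below ``tol``.
    """
    if steady.X_st.size != spec.n_steps:
        raise CascadeValidationError("steady state length does not match spec")
    record = flux_record(spec, steady.as_state(), p_trans_fwd, p_trans_rev)
    residuals = np.abs(
        record.p_trans_rev * record.v_rev - record.p_trans_fwd * record.v_fwd
    )
    max_res = float(residuals.max()) if residuals.size else 0.0
    return BalanceCheck(max_res <= tol, max_res, residuals)
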