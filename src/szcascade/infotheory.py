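"""Binary-code entropy of a cascade state.

Each step of the cascade carries a two-symbol code: a molecule is either
inactive (``X_j``) or active (``X_j*``).  For a pool of ``X`` molecules the
number of distinguishable arrangements over the 2n symbols is the
multinomial

    Psi = X! / (prod_j X_j! * prod_j X_j*!),

whose logarithm converges, by Stirling's approximation, to Shannon's entropy
of the selection probabilities ``p_j = X_j / X`` and ``p_j* = X_j* / X``:

    S = -X * sum_j (p_j log p_j + p_j* log p_j*).

When a signal perturbs step j by ``dX_j* = X dp_j*`` (with ``dp_j + dp_j* = 0``
by conservation) the per-step entropy shifts by

    H_j = dX_j* log(p_j / p_j*),        h_j = H_j / dX_j* = log(p_j / p_j*),

the entropy difference and its per-molecule density.  Multiplying by k_B T
gives the energy-like entropy current ``C_j`` and current density ``c_j``.
Natural logarithms are used throughout; k_B T defaults to 1 so dimensionless
values are directly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln, xlogy

from .cascade_model import CascadeState, CascadeValidationError


class InfiniteEntropyError(ValueError):
    """log(p/p*) requested with a zero probability.

    Regularise the state first (e.g. add a pseudo-count or use Omega-scaled
    counts with at least one molecule per symbol) rather than propagating an
    infinity.
    """


@dataclass(frozen=True)
class BinaryCodeState:
    """Molecule numbers (or concentrations) per binary symbol.

    ``X[j]`` and ``Xstar[j]`` are the inactive/active amounts of step ``j``;
    ``X_total`` is the pool size that normalises the selection probabilities
    ``p = X / X_total`` and ``pstar = Xstar / X_total``.
    """

    X: np.ndarray
    Xstar: np.ndarray
    X_total: float

    def __post_init__(self) -> None:
        X = np.atleast_1d(np.asarray(self.X, dtype=float))
        Xs = np.atleast_1d(np.asarray(self.Xstar, dtype=float))
        if X.shape != Xs.shape:
            raise CascadeValidationError("X and Xstar must have the same length")
        if np.any(X < 0) or np.any(Xs < 0):
            raise CascadeValidationError("binary-code counts must be nonnegative")
        total = float(self.X_total)
        if total <= 0:
            raise CascadeValidationError("X_total must be positive")
        if abs((X.sum() + Xs.sum()) - total) > 1e-9 * total:
            raise CascadeValidationError(
                f"counts sum to {X.sum() + Xs.sum()!r}, not X_total={total!r}"
            )
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Xstar", Xs)
        object.__setattr__(self, "X_total", total)

    @property
    def n_steps(self) -> int:
        return self.X.size

    @property
    def p(self) -> np.ndarray:
        return self.X / self.X_total

    @property
    def pstar(self) -> np.ndarray:
        return self.Xstar / self.X_total

    @classmethod
    def from_cascade_state(cls, state: CascadeState) -> "BinaryCodeState":
        """Pool all steps into one code (sum of totals normalises)."""
        total = float(state.X.sum() + state.Xstar.sum())
        return cls(X=state.X, Xstar=state.Xstar, X_total=total)


class SelectionProbabilities(NamedTuple):
    """One step's code probabilities and their signalling fluctuation.

    ``dp + dpstar = 0`` (conservation of the step total); ``dXstar`` is the
    absolute change of the active amount driving the fluctuation.
    """

    p: float
    pstar: float
    dp: float = 0.0
    dpstar: float = 0.0
    dXstar: float = 0.0


def validate_selection(sel: SelectionProbabilities) -> None:
    if not 0 <= sel.p <= 1 or not 0 <= sel.pstar <= 1:
        raise CascadeValidationError("p and pstar must lie in [0, 1]")
    if abs(sel.dp + sel.dpstar) > 1e-12 * max(abs(sel.dp), abs(sel.dpstar), 1.0):
        raise CascadeValidationError("fluctuations must cancel: dp + dpstar = 0")
    if not 0 <= sel.p + sel.dp <= 1 or not 0 <= sel.pstar + sel.dpstar <= 1:
        raise CascadeValidationError("fluctuated probabilities leave [0, 1]")


def log_signal_event_number(state: BinaryCodeState) -> float:
    """log Psi, the log count of code arrangements, exact via log-gamma.

    Counts are interpreted as integer multiplicities (they are rounded, as
    produced by Omega-scaling a concentration); no Stirling truncation.
    """
    X = np.round(state.X)
    Xs = np.round(state.Xstar)
    total = round(state.X_total)
    drift = max(
        np.abs(X - state.X).max(),
        np.abs(Xs - state.Xstar).max(),
        abs(total - state.X_total),
    )
    if drift > 1e-6 or abs(X.sum() + Xs.sum() - total) > 0:
        raise CascadeValidationError(
            "arrangement count needs integer multiplicities summing to X_total; "
            "round Omega-scaled concentrations to counts first"
        )
    return float(gammaln(total + 1) - gammaln(X + 1).sum() - gammaln(Xs + 1).sum())


def shannon_entropy(state: BinaryCodeState) -> float:
    """Shannon entropy of the selection probabilities, scaled by the pool size.

    ``S = -X_total * sum_j (p_j log p_j + p_j* log p_j*)``; ``0 log 0 = 0``.
    """
    p, ps = state.p, state.pstar
    return float(-state.X_total * (xlogy(p, p).sum() + xlogy(ps, ps).sum()))


def per_step_entropy(state: BinaryCodeState) -> np.ndarray:
    """The step-wise terms s_j whose sum is :func:`shannon_entropy`."""
    p, ps = state.p, state.pstar
    return -state.X_total * (xlogy(p, p) + xlogy(ps, ps))


def _log_ratio(p: float, pstar: float) -> float:
    if p <= 0 or pstar <= 0:
        raise InfiniteEntropyError(
            f"log(p/pstar) undefined for p={p}, pstar={pstar}; regularise the "
            "state (nonzero occupancy of both symbols) before computing entropy "
            "differences"
        )
    return float(np.log(p / pstar))


def entropy_difference(
    sel: SelectionProbabilities, X_total: float | None = None
) -> tuple[float, float]:
    """Entropy difference H_j and its per-molecule density h_j.

    ``H_j = dXstar * log(p/pstar)`` and ``h_j = log(p/pstar)``.  If ``X_total``
    is given, ``dXstar`` must be consistent with ``X_total * dpstar``.
    """
    validate_selection(sel)
    if X_total is not None and sel.dpstar != 0:
        expected = X_total * sel.dpstar
        if abs(sel.dXstar - expected) > 1e-9 * max(abs(expected), 1.0):
            raise CascadeValidationError(
                f"dXstar={sel.dXstar} inconsistent with X_total*dpstar={expected}"
            )
    h = _log_ratio(sel.p, sel.pstar)
    return sel.dXstar * h, h


def entropy_current(
    sel: SelectionProbabilities, dXstar_next: float, kBT: float = 1.0
) -> tuple[float, float]:
    """Entropy current C_j and current density c_j, in units of k_B T.

    ``C_j = kBT * log(p/pstar) * dXstar_next`` carries the entropy difference
    of step j onto the active-molecule change it hands to step j+1;
    ``c_j = kBT * log(p/pstar)`` is the per-molecule density.
    """
    if kBT <= 0:
        raise CascadeValidationError("kBT must be positive")
    validate_selection(sel)
    c = kBT * _log_ratio(sel.p, sel.pstar)
    return c * dXstar_next, c


@dataclass(frozen=True)
class EntropyReport:
    """Entropy bookkeeping of one cascade snapshot."""

    logPsi: float
    S: float
    s: np.ndarray
    H: np.ndarray
    h: np.ndarray
    current_C: np.ndarray
    current_c: np.ndarray


def entropy_report(
    state: BinaryCodeState,
    dXstar: np.ndarray | None = None,
    kBT: float = 1.0,
) -> EntropyReport:
    """Assemble the full entropy report for one binary-code state.

    ``dXstar`` (per step) drives the entropy differences and currents; when
    omitted the state is treated as unfluctuated (H = C = 0, densities still
    reported).  ``logPsi`` uses rounded counts and is meaningful when the
    state holds Omega-scaled molecule numbers.
    """
    n = state.n_steps
    d = np.zeros(n) if dXstar is None else np.atleast_1d(np.asarray(dXstar, float))
    if d.size != n:
        raise CascadeValidationError("dXstar must have one entry per step")
    sels = [
        SelectionProbabilities(
            p=float(state.p[i]), pstar=float(state.pstar[i]),
            dp=float(-d[i] / state.X_total), dpstar=float(d[i] / state.X_total),
            dXstar=float(d[i]),
        )
        for i in range(n)
    ]
    Hh = [entropy_difference(s) for s in sels]
    Cc = [entropy_current(s, s.dXstar, kBT) for s in sels]
    try:
        log_psi = log_signal_event_number(state)
    except CascadeValidationError:
        log_psi = float("nan")  # non-integer counts: arrangement count undefined
    return EntropyReport(
        logPsi=log_psi,
        S=shannon_entropy(state),
        s=per_step_entropy(state),
        H=np.array([x[0] for x in Hh]),
        h=np.array([x[1] for x in Hh]),
        current_C=np.array([x[0] for x in Cc]),
        current_c=np.array([x[1] for x in Cc]),
    )
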