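"""Channel capacity of one cascade step, forward and reverse.

A step transmits one binary symbol (inactive/active) to the next step
through a noisy channel.  With noise occurrence probability ``phi`` the
noise entropy is the binary entropy

    xi = -phi log phi - (1 - phi) log(1 - phi),

and the mutual entropy of the forward channel, as a function of the input
distribution ``(q, q*)`` with ``q + q* = 1``, is

    U(q) = -q log q - q* log q* - xi q*.

Maximising U by Lagrange's method gives the optimal input in closed form:
with ``Phi = exp(xi)`` (a capacity parameter in [1, 2], not a probability),

    q = Phi / (Phi + 1),   q* = 1 / (Phi + 1),
    C_fwd = -log(Phi / (Phi + 1)).

The reverse channel penalises the complementary symbol (``+ xi q`` in place
of ``- xi q*``), shares the same optimal input, and reaches

    C_rev = log(Phi + 1),

so the step mutual entropy obeys the identity chain

    h_step = C_rev - C_fwd = xi = log(q / q*),

which equals the per-molecule entropy difference log(p/p*) of the
information module when the step's selection probabilities are normalised to
two symbols.  Natural logarithms throughout; helpers convert to bits.

A brute-force grid maximiser of the two objectives serves as an independent
oracle for the closed forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import xlogy

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


class ChannelDomainError(ValueError):
    """Input outside the two-symbol channel model's admissible range."""


def binary_entropy(phi) -> np.ndarray | float:
    """Binary (Shannon) entropy of a probability, natural log; H(0)=H(1)=0."""
    phi = np.asarray(phi, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        raise ChannelDomainError("phi must lie in [0, 1]")
    out = -(xlogy(phi, phi) + xlogy(1.0 - phi, 1.0 - phi))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ChannelSolution:
    """Closed-form channel solution of one step.

    ``phi_noise`` is the noise occurrence probability; ``Phi = exp(xi)`` is
    the distinct capacity parameter (>= 1) that the closed forms are written
    in — the two are never conflated.
    """

    phi_noise: float
    xi: float
    Phi: float
    q_opt: float
    qstar_opt: float
    C_fwd: float
    C_rev: float
    h_step: float
    h0: float
    h_cond: float

    def in_bits(self) -> "ChannelSolution":
        """Same solution with all entropies/capacities converted to bits."""
        return ChannelSolution(
            phi_noise=self.phi_noise,
            xi=self.xi / LN2,
            Phi=self.Phi,
            q_opt=self.q_opt,
            qstar_opt=self.qstar_opt,
            C_fwd=self.C_fwd / LN2,
            C_rev=self.C_rev / LN2,
            h_step=self.h_step / LN2,
            h0=self.h0 / LN2,
            h_cond=self.h_cond / LN2,
        )


def solve_channel(phi_noise: float) -> ChannelSolution:
    """Closed-form forward/reverse capacities for noise probability ``phi``.

    The boundary values ``phi in {0, 1}`` are the noiseless limit (xi = 0,
    Phi = 1, both capacities ln 2) and are accepted with a logged note.
    """
    phi = float(phi_noise)
    if not 0 <= phi <= 1:
        raise ChannelDomainError(f"phi_noise must lie in [0, 1], got {phi}")
    if phi in (0.0, 1.0):
        logger.info("phi_noise=%g is the noiseless boundary (xi=0, Phi=1)", phi)
    xi = float(binary_entropy(phi))
    Phi = float(np.exp(xi))
    q = Phi / (Phi + 1.0)
    qstar = 1.0 / (Phi + 1.0)
    C_fwd = float(-np.log(Phi / (Phi + 1.0)))
    C_rev = float(np.log(Phi + 1.0))
    h0 = float(-(xlogy(q, q) + xlogy(qstar, qstar)))
    h_cond = xi * qstar
    return ChannelSolution(
        phi_noise=phi, xi=xi, Phi=Phi, q_opt=q, qstar_opt=qstar,
        C_fwd=C_fwd, C_rev=C_rev, h_step=C_rev - C_fwd, h0=h0, h_cond=h_cond,
    )


def objective_U(q, phi_noise: float):
    """Forward mutual-entropy objective with the constraint eliminated.

    ``U(q) = -q log q - (1-q) log(1-q) - xi (1-q)``; its maximum over
    ``q in [0, 1]`` is the forward capacity.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ChannelDomainError("q must lie in [0, 1]")
    xi = binary_entropy(phi_noise)
    out = -(xlogy(q, q) + xlogy(1.0 - q, 1.0 - q)) - xi * (1.0 - q)
    return float(out) if out.ndim == 0 else out


def reverse_objective_U(q, phi_noise: float):
    """Reverse mutual-entropy objective: the noise penalty sits on ``q``.

    The reverse noise entropy equals minus the forward one, so the penalty
    term is ``+ xi q``; the maximum is the reverse capacity.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ChannelDomainError("q must lie in [0, 1]")
    xi = binary_entropy(phi_noise)
    out = -(xlogy(q, q) + xlogy(1.0 - q, 1.0 - q)) + xi * q
    return float(out) if out.ndim == 0 else out


class GridMax(NamedTuple):
    q_argmax: float
    value: float


def grid_oracle(
    phi_noise: float, grid_size: int = 100_000, reverse: bool = False
) -> GridMax:
    """Brute-force maximiser of the (forward or reverse) objective.

    Uniform grid on [0, 1]; independent check of the Lagrange closed forms.
    """
    if grid_size < 1000:
        raise ValueError("grid_size must be at least 10^3")
    q = np.linspace(0.0, 1.0, grid_size + 1)
    vals = reverse_objective_U(q, phi_noise) if reverse else objective_U(q, phi_noise)
    i = int(np.argmax(vals))
    return GridMax(q_argmax=float(q[i]), value=float(vals[i]))


def phi_from_selection(p: float, pstar: float, upper_branch: bool = False) -> float:
    """Noise probability whose binary entropy equals log(p/pstar).

    Inverts ``xi = log(p/pstar)`` on the branch ``phi in (0, 0.5]`` (the
    mirror branch ``1 - phi`` via ``upper_branch``).  Requires
    ``0 <= log(p/pstar) <= ln 2``; outside that range the cascade state has no
    admissible noise probability in this model.
    """
    if p <= 0 or pstar <= 0:
        raise ChannelDomainError("p and pstar must be strictly positive")
    xi = float(np.log(p / pstar))
    if xi < -1e-12 or xi > LN2 + 1e-12:
        raise ChannelDomainError(
            f"log(p/pstar)={xi:.6g} outside [0, ln 2]; no noise probability "
            "reproduces this selection ratio"
        )
    xi = min(max(xi, 0.0), LN2)
    if xi == 0.0:
        phi = 0.0
    elif xi == LN2:
        phi = 0.5
    else:
        phi = float(brentq(lambda f: binary_entropy(f) - xi, 1e-300, 0.5,
                           xtol=1e-15, rtol=8.9e-16))
    return 1.0 - phi if upper_branch else phi
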