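"""Governing equations of the plastic star network.

A star network has one hub oscillator (phase ``theta0``, natural frequency
``omega0``) and ``N`` leaf oscillators, each coupled only to the hub.  Both
directions of every hub-leaf link carry a plastic synaptic weight: ``A[j]``
(leaf j -> hub) and ``B[j]`` (hub -> leaf j), confined to ``[0, alpha]``.

The phases follow Kuramoto dynamics

    dtheta0/dt = omega0 + sum_k A_k sin(theta_k - theta0)
    dthetaj/dt = omega_j + B_j sin(theta0 - theta_j)

while the weights evolve slowly (prefactor ``epsilon``) under a
phase-difference-dependent plasticity (PDDP) rule: with the hub-leaf phase
difference ``phi_j = theta0 - theta_j`` wrapped to [-pi, pi),

    phi_j in [-pi, 0):  dA_j =  eps * F(alpha - A_j) * exp( phi_j / tau_plus)
                        dB_j = -eps * F(B_j)         * exp( phi_j / tau_minus)
    phi_j in [0,  pi):  dA_j = -eps * F(A_j)         * exp(-phi_j / tau_minus)
                        dB_j =  eps * F(alpha - B_j) * exp(-phi_j / tau_plus)

``F`` is a boundary function that vanishes at 0 and pins the weights inside
the box; ``tau_plus`` / ``tau_minus`` are the potentiation / depression
learning windows (``tau_minus > tau_plus``, i.e. depression dominates).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "BoundaryFamily",
    "BoundarySpec",
    "NetworkParams",
    "FullState",
    "FullDeriv",
    "wrap_phase",
    "boundary_eval",
    "pddp_rates",
    "full_rhs",
    "phase_diff_rhs",
    "pack_state",
    "unpack_state",
]

TWO_PI = 2.0 * np.pi


class BoundaryFamily(str, enum.Enum):
    """Shape family of the weight boundary function F."""

    POWER = "power"          # F(x) = x**mu, soft (mu=1) to hard (mu -> 0)
    SIGMOID = "sigmoid"      # F(x) = tanh(x/mu)
    HEAVISIDE = "heaviside"  # F(x) = H(x), hard boundary; H(0) = 0


@dataclass(frozen=True)
class BoundarySpec:
    """Boundary function ``F`` keeping weights in [0, alpha].

    Parameters
    ----------
    family
        One of :class:`BoundaryFamily` (or its string value).
    mu
        Sharpness parameter, > 0.  Ignored for the Heaviside family.
        For the power family ``mu`` must lie in (0, 1] so that F
        interpolates between the soft (linear, mu=1) and hard (mu -> 0)
        boundary.  ``mu -> 0`` is the hard-boundary limit for both smooth
        families.
    """

    family: BoundaryFamily = BoundaryFamily.SIGMOID
    mu: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", BoundaryFamily(self.family))
        if self.family is not BoundaryFamily.HEAVISIDE:
            if not np.isfinite(self.mu) or self.mu <= 0:
                raise ValueError(f"mu must be positive, got {self.mu}")
            if self.family is BoundaryFamily.POWER and self.mu > 1:
                raise ValueError(f"power boundary requires mu in (0, 1], got {self.mu}")


def wrap_phase(x):
    """Wrap an angle (rad) to the half-open interval [-pi, pi).

    ``pi`` maps to ``-pi``; the PDDP rule branches on the sign of the
    wrapped phase difference, so the convention matters only on a set of
    measure zero.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap_phase requires finite input")
    out = np.mod(x + np.pi, TWO_PI) - np.pi
    return out if out.ndim else float(out)


def boundary_eval(spec: BoundarySpec, x, *, neg_tol: float = 1e-9):
    """Evaluate the boundary function F at ``x`` (scalar or array).

    ``x`` is a weight (or ``alpha`` minus a weight) and must be >= 0 up to
    ``neg_tol``; a larger negative value means a weight escaped the box and
    raises.  Small negative round-off is treated as 0, and F(0) = 0 for all
    families (Heaviside convention H(0) = 0, which keeps the synchronized
    equilibrium exact).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < -neg_tol):
        raise ValueError(f"boundary function argument below 0 beyond tolerance: min={x.min()}")
    xc = np.clip(x, 0.0, None)
    if spec.family is BoundaryFamily.POWER:
        out = np.power(xc, spec.mu)
    elif spec.family is BoundaryFamily.SIGMOID:
        out = np.tanh(xc / spec.mu)
    else:
        out = (xc > 0).astype(float)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NetworkParams:
    """All constants of an N-leaf plastic star network.

    ``omega`` holds the leaf natural frequencies in strictly ascending
    order; ``omega0`` is the hub frequency and may not coincide with any
    leaf frequency.  ``alpha`` bounds the weights, ``epsilon`` is the
    weight/phase time-scale ratio.
    """

    omega0: float
    omega: np.ndarray
    alpha: float = 1.0
    tau_plus: float = 0.15
    tau_minus: float = 0.3
    epsilon: float = 1e-3
    boundary: BoundarySpec = field(default_factory=BoundarySpec)

    def __post_init__(self) -> None:
        omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        object.__setattr__(self, "omega", omega)
        if omega.size < 1:
            raise ValueError("need at least one leaf")
        if np.any(np.diff(omega) <= 0):
            raise ValueError("leaf frequencies must be strictly ascending")
        if np.any(omega == self.omega0):
            raise ValueError("hub frequency must differ from every leaf frequency")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 < self.tau_plus < self.tau_minus):
            raise ValueError("need tau_minus > tau_plus > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def N(self) -> int:
        return int(self.omega.size)

    @property
    def detunings(self) -> np.ndarray:
        """Hub-leaf frequency mismatches Delta_j = omega0 - omega_j."""
        return self.omega0 - self.omega


@dataclass
class FullState:
    """Phases and weights of the full (non-reduced) system."""

    theta0: float
    theta: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.A = np.atleast_1d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_1d(np.asarray(self.B, dtype=float))
        if not (self.theta.shape == self.A.shape == self.B.shape):
            raise ValueError("theta, A and B must have equal length N")

    @property
    def N(self) -> int:
        return int(self.theta.size)

    def phase_diffs(self) -> np.ndarray:
        """Hub-leaf phase differences phi_j = theta0 - theta_j in [-pi, pi)."""
        return np.atleast_1d(wrap_phase(self.theta0 - self.theta))


class FullDeriv(NamedTuple):
    """Time derivative of a :class:`FullState`."""

    theta0: float
    theta: np.ndarray
    A: np.ndarray
    B: np.ndarray


def pddp_rates(phi, A, B, params: NetworkParams):
    """Weight derivatives (dA, dB) of the four-branch PDDP rule.

    ``phi`` is wrapped internally; potentiation uses the window
    ``tau_plus``, depression ``tau_minus``, and the opposing boundary
    factors F(alpha - w) / F(w) pin the flow inside [0, alpha].
    """
    phi = np.atleast_1d(wrap_phase(phi))
    A = np.atleast_1d(np.asarray(A, dtype=float))
    B = np.atleast_1d(np.asarray(B, dtype=float))
    bd, al, eps = params.boundary, params.alpha, params.epsilon
    tp, tm = params.tau_plus, params.tau_minus
    neg = phi < 0
    dA = np.where(
        neg,
        boundary_eval(bd, al - A) * np.exp(phi / tp),
        -boundary_eval(bd, A) * np.exp(-phi / tm),
    )
    dB = np.where(
        neg,
        -boundary_eval(bd, B) * np.exp(phi / tm),
        boundary_eval(bd, al - B) * np.exp(-phi / tp),
    )
    return eps * dA, eps * dB


def full_rhs(state: FullState, params: NetworkParams) -> FullDeriv:
    """Right-hand side of the full system in (theta0, theta, A, B) form."""
    if state.N != params.N:
        raise ValueError("state and params disagree on N")
    phi = state.phase_diffs()
    dtheta0 = params.omega0 + float(np.sum(state.A * np.sin(state.theta - state.theta0)))
    dtheta = params.omega + state.B * np.sin(state.theta0 - state.theta)
    dA, dB = pddp_rates(phi, state.A, state.B, params)
    return FullDeriv(dtheta0, dtheta, dA, dB)


def phase_diff_rhs(phi, A, B, params: NetworkParams):
    """Right-hand side in the closed phase-difference form (3N equations).

    dphi_j/dt = omega0 - omega_j - B_j sin(phi_j) - sum_k A_k sin(phi_k)
    with the same weight derivatives as :func:`full_rhs`.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    A = np.atleast_1d(np.asarray(A, dtype=float))
    B = np.atleast_1d(np.asarray(B, dtype=float))
    sin_phi = np.sin(phi)
    dphi = params.detunings - B * sin_phi - float(np.sum(A * sin_phi))
    dA, dB = pddp_rates(phi, A, B, params)
    return dphi, dA, dB


def pack_state(phi, A, B) -> np.ndarray:
    """Flatten (phi, A, B) into the solver layout [phi, A, B]."""
    return np.concatenate([np.atleast_1d(phi), np.atleast_1d(A), np.atleast_1d(B)]).astype(float)


def unpack_state(y: np.ndarray, N: int):
    """Inverse of :func:`pack_state`; works on (..., 3N) trajectories."""
    y = np.asarray(y, dtype=float)
    return y[..., :N], y[..., N : 2 * N], y[..., 2 * N :]
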