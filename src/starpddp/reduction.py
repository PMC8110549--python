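"""Fast-slow reduction of the two-oscillator (N = 1) plastic system.

The phase difference phi_1 evolves on an O(1) time scale,

    dphi_1/dt = Delta - K sin(phi_1),      K = A_1 + B_1,

while the weights move at O(epsilon).  Freezing K on the fast scale splits
the (A_1, B_1) plane along the line K = Delta:

* K > Delta (phase-locked branch): phi_1 settles at the stable locked phase
  phi* = arcsin(Delta/K) and the weights obey the substituted PDDP rule,
  which drives the system monotonically to the synchronized attractor
  (A_1, B_1) = (0, alpha).
* K < Delta (drifting branch): phi_1 rotates with period
  T(K) = 2*pi/sqrt(Delta^2 - K^2) and the weight equations are averaged
  over one rotation, producing four kernel integrals of
  G_pm(K, phi) = exp(phi/tau_pm) / (Delta - K sin(phi)).

The averaged flow has a stable low-weight fixed point A* = B* that solves
F(A*)/F(alpha - A*) = q with the learning-window ratio

    q = tau_plus (1 - exp(-pi/tau_plus)) / (tau_minus (1 - exp(-pi/tau_minus))),

and A* -> 0 in the hard-boundary limit mu -> 0 (A* = q**(1/mu) for the
power family, A* = mu*atanh(q) for the sigmoid family).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .model import BoundaryFamily, BoundarySpec, NetworkParams, boundary_eval

__all__ = [
    "TwoOscParams",
    "ReducedState",
    "UnsyncFixedPoint",
    "ReducedTrajectory",
    "AveragedTables",
    "q_factor",
    "locked_phase",
    "oscillation_period",
    "averaging_kernel",
    "kernel_integrals",
    "sync_branch_rhs",
    "averaged_rhs",
    "reduced_rhs",
    "stationary_weight",
    "stationary_K_power",
    "stationary_state",
    "integrate_reduced",
    "basin_grid",
]


@dataclass(frozen=True)
class TwoOscParams:
    """Parameters of the two-oscillator reduction (detuning Delta > 0)."""

    delta: float
    alpha: float = 1.0
    tau_plus: float = 0.15
    tau_minus: float = 0.3
    epsilon: float = 1e-3
    boundary: BoundarySpec = field(default_factory=BoundarySpec)

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("detuning delta must be positive (hub faster convention)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 < self.tau_plus < self.tau_minus):
            raise ValueError("need tau_minus > tau_plus > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @classmethod
    def from_network(cls, params: NetworkParams) -> "TwoOscParams":
        if params.N != 1:
            raise ValueError("reduction applies to the N=1 star only")
        delta = float(params.detunings[0])
        if delta <= 0:
            raise ValueError("requires omega0 > omega1")
        return cls(delta, params.alpha, params.tau_plus, params.tau_minus,
                   params.epsilon, params.boundary)

    def network(self, omega1: float = 0.5) -> NetworkParams:
        """Equivalent N=1 NetworkParams (only the detuning matters)."""
        return NetworkParams(omega0=omega1 + self.delta, omega=np.array([omega1]),
                             alpha=self.alpha, tau_plus=self.tau_plus,
                             tau_minus=self.tau_minus, epsilon=self.epsilon,
                             boundary=self.boundary)


@dataclass
class ReducedState:
    """Slow weight pair of the reduction."""

    A1: float
    B1: float

    @property
    def K(self) -> float:
        return self.A1 + self.B1


@dataclass(frozen=True)
class UnsyncFixedPoint:
    """Low-weight stationary state of the averaged (drifting) branch."""

    A: float
    B: float
    K: float
    n_roots: int  # sign changes of K - f1(K) - f2(K) found on the scan grid


def q_factor(tau_plus: float, tau_minus: float) -> float:
    """Learning-window ratio q; q < 1 whenever tau_plus < tau_minus."""
    if tau_plus <= 0 or tau_minus <= 0:
        raise ValueError("learning windows must be positive")
    num = tau_plus * (1.0 - math.exp(-math.pi / tau_plus))
    den = tau_minus * (1.0 - math.exp(-math.pi / tau_minus))
    return num / den


def locked_phase(K: float, delta: float) -> float:
    """Stable locked phase arcsin(delta/K) in (0, pi/2]; requires K > delta."""
    if K <= delta:
        raise ValueError(f"no phase-locked solution for K={K} <= delta={delta}")
    return math.asin(min(delta / K, 1.0))


def oscillation_period(K: float, delta: float) -> float:
    """Rotation period 2*pi/sqrt(delta^2 - K^2) of the drifting phase."""
    if not 0 <= K < delta:
        raise ValueError(f"period defined for 0 <= K < delta, got K={K}, delta={delta}")
    return 2.0 * math.pi / math.sqrt(delta * delta - K * K)


def averaging_kernel(K: float, phi, tau: float, delta: float):
    """Kernel G(K, phi) = exp(phi/tau) / (delta - K sin(phi)); needs |K| < delta."""
    if abs(K) >= delta:
        raise ValueError(f"averaging kernel requires |K| < delta, got K={K}")
    phi = np.asarray(phi, dtype=float)
    out = np.exp(phi / tau) / (delta - K * np.sin(phi))
    return out if out.ndim else float(out)


def _clipped_F(spec: BoundarySpec, x: float, alpha: float) -> float:
    # tolerate solver round-off slightly outside the box
    return float(boundary_eval(spec, min(max(x, 0.0), alpha)))


def sync_branch_rhs(A1: float, B1: float, p: TwoOscParams):
    """Slow weight flow on the phase-locked branch (K > Delta).

    dA1/dt = -eps F(A1) exp(-phi*/tau_minus),
    dB1/dt = +eps F(alpha-B1) exp(-phi*/tau_plus),  phi* = arcsin(Delta/K).
    The flow is monotone toward the synchronized attractor (0, alpha).
    """
    phi_star = locked_phase(A1 + B1, p.delta)
    dA = -p.epsilon * _clipped_F(p.boundary, A1, p.alpha) * math.exp(-phi_star / p.tau_minus)
    dB = p.epsilon * _clipped_F(p.boundary, p.alpha - B1, p.alpha) * math.exp(-phi_star / p.tau_plus)
    return dA, dB


def kernel_integrals(K: float, p: TwoOscParams, *, epsabs: float = 1e-10):
    """The four averaging quadratures as functions of K (|K| < Delta).

    Returns (Ip_neg, Im_pos, Ip_pos, Im_neg):
      Ip_neg = int_{-pi}^{0} G_+(K, phi)   dphi   (A potentiation)
      Im_pos = int_{0}^{pi}  G_-(-K, -phi) dphi   (A depression)
      Ip_pos = int_{0}^{pi}  G_+(-K, -phi) dphi   (B potentiation)
      Im_neg = int_{-pi}^{0} G_-(K, phi)   dphi   (B depression)
    """
    d, tp, tm = p.delta, p.tau_plus, p.tau_minus
    if abs(K) >= d:
        raise ValueError(f"averaging requires |K| < delta, got K={K}")

    def g(phi, tau, sign):
        return math.exp(sign * phi / tau) / (d - K * math.sin(phi))

    # the denominator is smallest near phi = +pi/2 (for K > 0); help quad there
    pts_pos = [math.pi / 2]
    pts_neg = [-math.pi / 2]
    ip_neg = quad(g, -math.pi, 0.0, args=(tp, 1), epsabs=epsabs, points=pts_neg, limit=200)[0]
    im_pos = quad(g, 0.0, math.pi, args=(tm, -1), epsabs=epsabs, points=pts_pos, limit=200)[0]
    ip_pos = quad(g, 0.0, math.pi, args=(tp, -1), epsabs=epsabs, points=pts_pos, limit=200)[0]
    im_neg = quad(g, -math.pi, 0.0, args=(tm, 1), epsabs=epsabs, points=pts_neg, limit=200)[0]
    return ip_neg, im_pos, ip_pos, im_neg


class AveragedTables:
    """PCHIP interpolants of the four kernel integrals over K in [0, ~Delta).

    Basin-grid labeling of the reduced flow evaluates the averaged equations
    tens of thousands of times; interpolating the purely K-dependent
    integrals (grid refined toward the integrable blow-up at K = Delta)
    makes that cheap without touching the quadrature oracle.
    """

    def __init__(self, p: TwoOscParams, n_linear: int = 160, n_edge: int = 60):
        d = p.delta
        frac = np.unique(np.concatenate([
            np.linspace(0.0, 0.9, n_linear),
            1.0 - np.logspace(-1, -4, n_edge),
        ]))
        self.K_max = d * frac[-1]
        grid = d * frac
        vals = np.array([kernel_integrals(K, p) for K in grid])
        self._interp = [PchipInterpolator(grid, vals[:, i]) for i in range(4)]

    def __call__(self, K: float):
        K = min(abs(K), self.K_max)
        return tuple(float(f(K)) for f in self._interp)


def averaged_rhs(A1: float, B1: float, p: TwoOscParams,
                 tables: AveragedTables | None = None):
    """Period-averaged slow weight flow on the drifting branch (K < Delta).

    Both derivatives scale linearly in epsilon.  In the K -> 0 limit the A
    and B equations become identical and decoupled, with stationary state
    F(A*)/F(alpha - A*) = q.
    """
    K = A1 + B1
    if tables is not None:
        ip_neg, im_pos, ip_pos, im_neg = tables(K)
        T = oscillation_period(min(K, tables.K_max), p.delta)
    else:
        ip_neg, im_pos, ip_pos, im_neg = kernel_integrals(K, p)
        T = oscillation_period(K, p.delta)
    FA = _clipped_F(p.boundary, A1, p.alpha)
    FaA = _clipped_F(p.boundary, p.alpha - A1, p.alpha)
    FB = _clipped_F(p.boundary, B1, p.alpha)
    FaB = _clipped_F(p.boundary, p.alpha - B1, p.alpha)
    dA = p.epsilon / T * (FaA * ip_neg - FA * im_pos)
    dB = p.epsilon / T * (FaB * ip_pos - FB * im_neg)
    return dA, dB


_SYNC_BAND = 1e-9


def reduced_rhs(A1: float, B1: float, p: TwoOscParams,
                tables: AveragedTables | None = None):
    """Complete reduced flow: locked branch for K > Delta, averaged below.

    Within |K - Delta| < 1e-9 (where the averaged equations are singular,
    T -> infinity) the locked branch is used.
    """
    K = A1 + B1
    if K > p.delta + _SYNC_BAND:
        return sync_branch_rhs(A1, B1, p)
    if K >= p.delta - _SYNC_BAND:
        # on the line the locked phase is pi/2; use the locked-branch form
        dA = -p.epsilon * _clipped_F(p.boundary, A1, p.alpha) * math.exp(
            -0.5 * math.pi / p.tau_minus)
        dB = p.epsilon * _clipped_F(p.boundary, p.alpha - B1, p.alpha) * math.exp(
            -0.5 * math.pi / p.tau_plus)
        return dA, dB
    return averaged_rhs(*_guard_unsync(A1, B1, p.delta), p, tables=tables)


def stationary_weight(boundary: BoundarySpec, alpha: float, q: float) -> float:
    """Solve F(A*)/F(alpha - A*) = q for the low-weight stationary state.

    Bracketed root finding on (0, alpha); works for any monotone boundary
    family.  For small mu this approaches q**(1/mu) (power) and
    mu*atanh(q) (sigmoid).
    """
    if not 0 < q < 1:
        raise ValueError(f"q must lie in (0, 1), got {q}")

    def g(a: float) -> float:
        return boundary_eval(boundary, a) - q * boundary_eval(boundary, alpha - a)

    if not g(0.0) < 0 < g(alpha):
        raise ValueError("stationary weight not bracketed on (0, alpha)")
    # the root is exponentially small in the hard-boundary limit (e.g.
    # q**(1/mu) for the power family), so bisect in log space
    lo_u = -700.0 + math.log(alpha)
    hi_u = math.log(alpha) - 1e-12
    if g(math.exp(lo_u)) >= 0:
        return float(math.exp(lo_u))  # root below representable range
    return float(math.exp(brentq(lambda u: g(math.exp(u)), lo_u, hi_u,
                                 xtol=1e-12)))


def _scan_smallest_root(h: Callable[[float], float], grid: np.ndarray):
    """Smallest bracketed root of h on the grid; returns (root, n_sign_changes)."""
    vals = np.array([h(K) for K in grid])
    sign_changes = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if len(sign_changes) == 0:
        raise ValueError("no root bracketed on the scan interval")
    i = sign_changes[0]
    root = float(brentq(h, grid[i], grid[i + 1], xtol=1e-13))
    return root, len(sign_changes)


def stationary_K_power(mu: float, p: TwoOscParams) -> float:
    """Stationary coupling sum K* of the power-boundary averaged flow.

    Solves K = f1(K) + f2(K), where f1, f2 are the graphical-solution
    curves built from ratios of the kernel integrals raised to 1/mu.
    Returns the smallest root in [0, Delta).
    """
    if not 0 < mu <= 1:
        raise ValueError("power boundary requires mu in (0, 1]")

    def f1f2(K: float):
        ip_neg, im_pos, ip_pos, im_neg = kernel_integrals(K, p)
        f1 = p.alpha / (1.0 + (im_pos / ip_neg) ** (1.0 / mu))
        f2 = p.alpha / (1.0 + (im_neg / ip_pos) ** (1.0 / mu))
        return f1, f2

    def h(K: float) -> float:
        f1, f2 = f1f2(K)
        return f1 + f2 - K

    grid = p.delta * np.linspace(0.0, 1.0 - 1e-9, 201)
    root, _ = _scan_smallest_root(h, grid)
    return root


def stationary_state(p: TwoOscParams, scan_points: int = 201) -> UnsyncFixedPoint:
    """Unsynchronized fixed point (A*, B*) for any boundary family.

    For each K the per-weight stationarity conditions
    F(alpha-A) Ip_neg = F(A) Im_pos and F(alpha-B) Ip_pos = F(B) Im_neg are
    solved by bisection (no closed-form inverse of F needed), then
    K = A(K) + B(K) is solved for the self-consistent coupling sum.
    """

    def weights_at(K: float):
        ip_neg, im_pos, ip_pos, im_neg = kernel_integrals(K, p)

        def gA(a):
            return (boundary_eval(p.boundary, p.alpha - a) * ip_neg
                    - boundary_eval(p.boundary, a) * im_pos)

        def gB(b):
            return (boundary_eval(p.boundary, p.alpha - b) * ip_pos
                    - boundary_eval(p.boundary, b) * im_neg)

        A = float(brentq(gA, 0.0, p.alpha, xtol=1e-14))
        B = float(brentq(gB, 0.0, p.alpha, xtol=1e-14))
        return A, B

    def h(K: float) -> float:
        A, B = weights_at(K)
        return A + B - K

    grid = p.delta * np.linspace(0.0, 1.0 - 1e-9, scan_points)
    K_star, n_roots = _scan_smallest_root(h, grid)
    A, B = weights_at(K_star)
    return UnsyncFixedPoint(A=A, B=B, K=K_star, n_roots=n_roots)


@dataclass
class ReducedTrajectory:
    """Piecewise dense solution of the reduced flow with branch switches."""

    t: np.ndarray
    A: np.ndarray
    B: np.ndarray
    switch_times: list[float]
    _segments: list = field(default_factory=list, repr=False)

    @property
    def K(self) -> np.ndarray:
        return self.A + self.B

    @property
    def final(self) -> tuple[float, float]:
        return float(self.A[-1]), float(self.B[-1])

    def __call__(self, times):
        """Evaluate (A, B) at arbitrary times via the dense segment solutions."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.empty((times.size, 2))
        for i, ti in enumerate(times):
            seg = self._segments[0]
            for cand in self._segments:
                if cand[0] <= ti:
                    seg = cand
                else:
                    break
            t0, t1, sol = seg
            out[i] = sol(min(max(ti, t0), t1))
        return out


def integrate_reduced(A0: float, B0: float, p: TwoOscParams, t_end: float, *,
                      rtol: float = 1e-8, atol: float = 1e-10,
                      tables: AveragedTables | None = None,
                      max_switches: int = 40) -> ReducedTrajectory:
    """Integrate the reduced flow, switching branches at K = Delta crossings.

    Each branch is integrated with adaptive RK45 and a terminal event on
    K - Delta = 0 (crossing direction toward the other branch); at a switch
    the state is nudged by 1e-7 across the line along the flow direction.
    """
    d = p.delta
    t, A, B = 0.0, float(A0), float(B0)
    ts, As, Bs = [t], [A], [B]
    switches: list[float] = []
    segments = []
    nudge = 1e-7
    for _ in range(max_switches):
        if t >= t_end:
            break
        on_sync = (A + B) > d

        if on_sync:
            def rhs(_t, y):
                # trial steps may momentarily dip below K = Delta; the locked
                # phase saturates continuously at pi/2 there
                if y[0] + y[1] <= d:
                    phi_star = 0.5 * math.pi
                    dA = -p.epsilon * _clipped_F(p.boundary, y[0], p.alpha) \
                        * math.exp(-phi_star / p.tau_minus)
                    dB = p.epsilon * _clipped_F(p.boundary, p.alpha - y[1], p.alpha) \
                        * math.exp(-phi_star / p.tau_plus)
                    return dA, dB
                return sync_branch_rhs(y[0], y[1], p)

            def event(_t, y):
                return y[0] + y[1] - d
            event.direction = -1.0
        else:
            def rhs(_t, y):
                return averaged_rhs(*(_guard_unsync(y[0], y[1], d)), p, tables=tables)

            def event(_t, y):
                return y[0] + y[1] - d
            event.direction = 1.0
        event.terminal = True
        sol = solve_ivp(rhs, (t, t_end), [A, B], method="RK45", rtol=rtol,
                        atol=atol, events=event, dense_output=True)
        if not sol.success:
            raise RuntimeError(f"reduced integration failed: {sol.message}")
        segments.append((t, sol.t[-1], sol.sol))
        ts.extend(sol.t[1:].tolist())
        As.extend(sol.y[0, 1:].tolist())
        Bs.extend(sol.y[1, 1:].tolist())
        t = float(sol.t[-1])
        A, B = float(sol.y[0, -1]), float(sol.y[1, -1])
        if sol.status == 1:  # hit the K = Delta line: step across it
            switches.append(t)
            shift = nudge if not on_sync else -nudge
            A = min(max(A + shift / 2, 0.0), p.alpha)
            B = min(max(B + shift / 2, 0.0), p.alpha)
        else:
            break
    return ReducedTrajectory(np.asarray(ts), np.asarray(As), np.asarray(Bs),
                             switches, segments)


def _guard_unsync(A: float, B: float, d: float):
    """Clamp trial evaluations at/above the K = Delta line into the branch."""
    K = A + B
    cap = d * (1.0 - 1e-9)
    if K >= cap and K > 0:
        s = cap / K
        return A * s, B * s
    return max(A, 0.0), max(B, 0.0)


def basin_grid(p: TwoOscParams, n: int = 30, s_end: float = 80.0, *,
               tables: AveragedTables | None = None,
               rtol: float = 1e-6, atol: float = 1e-9) -> np.ndarray:
    """Label an n-by-n grid of initial weights by reduced-flow attractor.

    Integrates the reduced flow in slow time (epsilon = 1) from each grid
    point and labels 1 for the synchronized attractor (0, alpha), 0 for the
    low-weight unsynchronized fixed point, -1 if unresolved within s_end.
    """
    p1 = replace(p, epsilon=1.0)
    if tables is None:
        tables = AveragedTables(p1)
    fp = stationary_state(p1)
    grid = np.linspace(p.alpha / (2 * n), p.alpha * (1 - 1 / (2 * n)), n)
    labels = np.full((n, n), -1, dtype=int)
    for i, A0 in enumerate(grid):
        for j, B0 in enumerate(grid):
            traj = integrate_reduced(A0, B0, p1, s_end, rtol=rtol, atol=atol,
                                     tables=tables)
            A, B = traj.final
            if B > p.delta:
                # committed: on the locked branch B only grows, so K = A+B
                # stays above Delta forever and the flow ends at (0, alpha)
                labels[i, j] = 1
            elif math.hypot(A - fp.A, B - fp.B) < 0.1 * p.alpha:
                labels[i, j] = 0
    return labels
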