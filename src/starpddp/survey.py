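"""Ensemble protocols on the full star-network model.

Three experiment drivers built on the compiled integrator:

* :func:`basin_survey` -- integrate many random initial conditions to
  saturation, classify each endpoint into a configuration code and estimate
  basin probabilities (the multistability census).
* :func:`perturbation_protocol` -- start at a fixed small weight-space
  distance from each of the 2^N predicted attractors and track the distance
  to the target over time (stability check of every predicted state).
* :func:`saturation_detector` -- windowed-drift criterion deciding when the
  weights of a trajectory have stopped evolving.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels, codes
from .model import (BoundaryFamily, FullState, NetworkParams, pack_state,
                    phase_diff_rhs, unpack_state, wrap_phase)

__all__ = [
    "Trajectory",
    "SurveyResult",
    "PerturbationRun",
    "integrate_network",
    "sample_initial_conditions",
    "basin_survey",
    "perturbation_protocol",
    "saturation_detector",
]

_FAMILY_CODE = {
    BoundaryFamily.POWER: _kernels.FAM_POWER,
    BoundaryFamily.SIGMOID: _kernels.FAM_SIGMOID,
    BoundaryFamily.HEAVISIDE: _kernels.FAM_HEAVISIDE,
}


@dataclass
class Trajectory:
    """Checkpointed trajectory of the phase-difference system."""

    t: np.ndarray
    phi: np.ndarray  # (n_rec, N)
    A: np.ndarray
    B: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        """(n_rec, 2N) weight part (A_1..A_N, B_1..B_N) of the state."""
        return np.concatenate([self.A, self.B], axis=1)

    def final(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.phi[-1], self.A[-1], self.B[-1]

    def mean_weights(self, window: float) -> tuple[np.ndarray, np.ndarray]:
        """Time-averaged (A, B) over the trailing ``window`` time units.

        Averaging over a couple of fast periods removes the O(epsilon)
        ripple of the drifting states before classification.
        """
        mask = self.t >= self.t[-1] - window
        return self.A[mask].mean(axis=0), self.B[mask].mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        N = self.phi.shape[1]
        cols = {"t": self.t}
        for j in range(N):
            cols[f"phi_{j+1}"] = self.phi[:, j]
        for j in range(N):
            cols[f"A_{j+1}"] = self.A[:, j]
        for j in range(N):
            cols[f"B_{j+1}"] = self.B[:, j]
        return pd.DataFrame(cols)


def _initial_to_y(initial, params: NetworkParams) -> np.ndarray:
    if isinstance(initial, FullState):
        return pack_state(initial.phase_diffs(), initial.A, initial.B)
    phi, A, B = initial
    return pack_state(wrap_phase(phi), A, B)


def integrate_network(params: NetworkParams, initial, t_end: float, *,
                      dt: float = 0.01, record_every: float | None = None,
                      method: str = "rk4", rtol: float = 1e-8,
                      atol: float = 1e-10) -> Trajectory:
    """Integrate the 3N phase-difference system from ``initial`` to ``t_end``.

    ``initial`` is a :class:`FullState` or a ``(phi, A, B)`` triple.  The
    default path is the compiled fixed-step RK4 kernel (weights clipped to
    the box after every step); ``method="rk45"`` uses scipy's adaptive
    solver on the same right-hand side for validation.  Deterministic for
    given inputs and tolerances.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = _initial_to_y(initial, params)
    N = params.N
    if record_every is None:
        record_every = max(dt, t_end / 2000.0)

    if method == "rk4":
        stride = max(1, round(record_every / dt))
        n_steps = max(1, math.ceil(t_end / dt / stride) * stride)
        saved = _kernels.integrate_rk4(
            y0, params.omega0, params.omega, params.alpha, params.tau_plus,
            params.tau_minus, params.epsilon, _FAMILY_CODE[params.boundary.family],
            params.boundary.mu, dt, n_steps, stride)
        t = np.arange(saved.shape[0]) * (stride * dt)
    elif method == "rk45":
        from scipy.integrate import solve_ivp

        def rhs(_t, y):
            phi, A, B = unpack_state(y, N)
            dphi, dA, dB = phase_diff_rhs(phi, np.clip(A, 0, params.alpha),
                                          np.clip(B, 0, params.alpha), params)
            return np.concatenate([dphi, dA, dB])

        t = np.arange(0.0, t_end + record_every / 2, record_every)
        sol = solve_ivp(rhs, (0.0, t_end), y0, method="RK45", rtol=rtol,
                        atol=atol, t_eval=t)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        saved = sol.y.T.copy()
        saved[:, :N] = wrap_phase(saved[:, :N])
        saved[:, N:] = np.clip(saved[:, N:], 0.0, params.alpha)
    else:
        raise ValueError(f"unknown method {method!r}")
    phi, A, B = unpack_state(saved, N)
    return Trajectory(t=t, phi=phi, A=A, B=B)


def sample_initial_conditions(params: NetworkParams, count: int,
                              seed: int) -> list[FullState]:
    """Random initial states: weights ~ U[0, alpha], phases ~ U[0, 2*pi)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    N = params.N
    out = []
    for _ in range(count):
        out.append(FullState(
            theta0=float(rng.uniform(0.0, 2 * np.pi)),
            theta=rng.uniform(0.0, 2 * np.pi, size=N),
            A=rng.uniform(0.0, params.alpha, size=N),
            B=rng.uniform(0.0, params.alpha, size=N),
        ))
    return out


@dataclass
class SurveyResult:
    """Outcome of a basin survey."""

    params: NetworkParams
    k: int
    runs: pd.DataFrame          # one row per IC: n, code, saturated, weights
    probabilities: dict[int, float]  # over cleanly classified, admissible runs
    anomalies: list[dict] = field(default_factory=list)

    @property
    def n_distinct(self) -> int:
        return len(self.probabilities)


def basin_survey(params: NetworkParams, count: int, seed: int,
                 t_end: float | None = None, *, dt: float = 0.02,
                 threshold_fraction: float = 0.5, avg_window: float = 30.0,
                 saturation_tol: float = 1e-3, extend_rounds: int = 9,
                 record_every: float | None = None) -> SurveyResult:
    """Monte-Carlo census of the asymptotic configurations.

    Integrates ``count`` random initial conditions (weights uniform on
    [0, alpha], phases uniform) until the weights saturate (a first chunk
    of ``t_end``, default 40/epsilon, extended in chunks of ``t_end/4``
    while unresolved up to ``extend_rounds * t_end`` extra -- capture of a
    hub-driving link is exponentially slow near its threshold), classifies
    the trailing-window-averaged weights into configuration codes, and
    aggregates basin probabilities by configuration index n.  Runs whose
    endpoint cannot be classified or falls outside the admissible table
    are reported in ``anomalies`` -- never silently dropped; a per-run
    ``saturated`` flag (windowed-drift criterion) records whether the
    weights had stopped evolving, and ``t_total`` how long the run was
    integrated.
    """
    if t_end is None:
        t_end = 40.0 / params.epsilon
    if record_every is None:
        record_every = max(dt, t_end / 4000.0)
    k = codes.hub_interval(params.omega0, params.omega)
    admissible = {c.symbols for c in codes.admissible_table(params.N, k)}
    ics = sample_initial_conditions(params, count, seed)

    rows = []
    anomalies: list[dict] = []
    counts: dict[int, int] = {}
    for run, ic in enumerate(ics):
        traj = integrate_network(params, ic, t_end, dt=dt,
                                 record_every=record_every)
        t_total = t_end
        chunk = t_end / 4.0
        t_cap = (1 + extend_rounds) * t_end
        while True:
            A_bar, B_bar = traj.mean_weights(avg_window)
            saturated, _ = saturation_detector(traj, params, tol=saturation_tol)
            try:
                code = codes.classify_weights(A_bar, B_bar, params.alpha,
                                              threshold_fraction, k=k)
                failure = None
            except codes.ClassificationError as exc:
                code, failure = None, str(exc)
            # a weight still in the mid-range band cannot be labeled with
            # confidence; everything near 0 or alpha classifies reliably
            # even while its tail is still creeping
            W = np.concatenate([A_bar, B_bar])
            ambiguous = bool(np.any((W > 0.3 * params.alpha)
                                    & (W < 0.7 * params.alpha)))
            resolved = (not ambiguous and code is not None
                        and code.symbols in admissible)
            if resolved or t_total + chunk > t_cap:
                break
            traj = integrate_network(params, traj.final(), chunk, dt=dt,
                                     record_every=record_every)
            t_total += chunk
        row = {"run": run, "saturated": saturated, "t_total": t_total}
        for j in range(params.N):
            row[f"A_{j+1}"] = A_bar[j]
        for j in range(params.N):
            row[f"B_{j+1}"] = B_bar[j]
        if code is None:
            row.update({"n": -1, "code": None})
            anomalies.append({"run": run, "reason": failure})
            rows.append(row)
            continue
        row.update({"n": code.n, "code": str(code)})
        if code.symbols not in admissible:
            anomalies.append({"run": run,
                              "reason": f"code {code} not admissible for k={k}"})
        else:
            counts[code.n] = counts.get(code.n, 0) + 1
        rows.append(row)
    total = sum(counts.values())
    probabilities = {n: c / total for n, c in sorted(counts.items())} if total else {}
    return SurveyResult(params=params, k=k, runs=pd.DataFrame(rows),
                        probabilities=probabilities, anomalies=anomalies)


@dataclass
class PerturbationRun:
    """Distance-to-target record for one predicted configuration."""

    n: int
    code: str
    target: np.ndarray             # R_n in weight space (2N,)
    initial_distance: float
    checkpoint_times: np.ndarray
    distances: np.ndarray          # trailing-window-averaged |R(t) - R_n|
    final_weights: np.ndarray


def _locked_phases_for_code(code: codes.ConfigCode, params: NetworkParams,
                            rng: np.random.Generator) -> np.ndarray:
    """Initial phase differences consistent with a target configuration.

    Synchronized leaves start at their locked phase (cluster frequency =
    the hub-driving leaf's frequency if present, else the hub's own);
    unsynchronized leaves start at uniformly random phase differences.
    """
    symbols = code.symbols
    hub_driver = [j for j, s in enumerate(symbols) if s is codes.Symbol.ONE_H]
    Omega = params.omega[hub_driver[0]] if hub_driver else params.omega0
    phi = rng.uniform(-np.pi, np.pi, size=params.N)
    for j, s in enumerate(symbols):
        if s is codes.Symbol.ONE_L:
            phi[j] = math.asin(np.clip((Omega - params.omega[j]) / params.alpha, -1, 1))
        elif s is codes.Symbol.ONE_H:
            phi[j] = math.asin(np.clip((params.omega0 - Omega) / params.alpha, -1, 1))
    return phi


def _inward_perturbation(target: np.ndarray, distance: float, alpha: float,
                         rng: np.random.Generator, max_tries: int = 1000) -> np.ndarray:
    """Uniform random direction on the 2N-sphere, scaled to ``distance``,
    reflected into the box [0, alpha] coordinate-wise.

    For target coordinates pinned at 0 or alpha the reflection realizes the
    conditional distribution of reject-and-redraw sampling exactly (the
    isotropic direction is sign-symmetric per coordinate) without its
    exponentially small acceptance rate.
    """
    for _ in range(max_tries):
        v = rng.normal(size=target.size)
        v *= distance / np.linalg.norm(v)
        at_lo = target <= distance
        at_hi = target >= alpha - distance
        v[at_lo] = np.abs(v[at_lo])
        v[at_hi] = -np.abs(v[at_hi])
        point = target + v
        if np.all((point >= 0.0) & (point <= alpha)):
            return point
    raise RuntimeError("could not place perturbed initial condition in the box")


def perturbation_protocol(params: NetworkParams, distance: float = 0.05,
                          seed: int = 0,
                          checkpoint_times: tuple[float, ...] = (300.0, 8000.0),
                          *, dt: float = 0.02, avg_window: float = 25.0,
                          record_every: float | None = None
                          ) -> list[PerturbationRun]:
    """Convergence test of every predicted asymptotic configuration.

    For each n = 0..2^N-1 the predicted weight vector R_n is perturbed to a
    random point at the given Euclidean distance (weight coordinates only),
    the full system is integrated to the last checkpoint, and the distance
    |R(t) - R_n| -- averaged over a trailing window of a few fast periods --
    is recorded at every checkpoint.
    """
    if not np.all(params.alpha > np.abs(params.detunings)):
        raise ValueError("requires alpha > |omega0 - omega_j| for all leaves")
    k = codes.hub_interval(params.omega0, params.omega)
    rng = np.random.default_rng(seed)
    t_end = float(max(checkpoint_times))
    if record_every is None:
        record_every = max(dt, t_end / 8000.0)
    runs = []
    for n in range(2 ** params.N):
        code = codes.encode(n, k, params.N)
        target = codes.code_to_state_vector(code, params.alpha)
        R0 = _inward_perturbation(target, distance, params.alpha, rng)
        d0 = float(np.linalg.norm(R0 - target))
        assert abs(d0 - distance) < 1e-12
        phi0 = _locked_phases_for_code(code, params, rng)
        traj = integrate_network(params, (phi0, R0[: params.N], R0[params.N :]),
                                 t_end, dt=dt, record_every=record_every)
        dists = np.linalg.norm(traj.weights - target, axis=1)
        cp = np.asarray(checkpoint_times, dtype=float)
        averaged = np.empty(cp.size)
        for i, tc in enumerate(cp):
            mask = (traj.t >= tc - avg_window) & (traj.t <= tc)
            averaged[i] = dists[mask].mean()
        runs.append(PerturbationRun(
            n=n, code=str(code), target=target, initial_distance=d0,
            checkpoint_times=cp, distances=averaged,
            final_weights=traj.weights[-1]))
    return runs


def saturation_detector(traj: Trajectory, params: NetworkParams,
                        tol: float = 1e-3, window: float | None = None,
                        smooth: float = 25.0) -> tuple[bool, float | None]:
    """Decide whether (and when) the weights of a trajectory saturated.

    The weights are first smoothed with a running mean over ``smooth`` time
    units (a few fast-oscillation periods) so that the O(epsilon) ripple of
    drifting states does not register as drift; saturation is declared once
    the peak-to-peak excursion of every smoothed weight over a trailing
    window (default 10/epsilon time units) stays below ``tol * alpha``.
    Returns (False, None) if the criterion is never met within the
    trajectory -- a flag, not an error.
    """
    if traj.t[-1] < 2.0 / params.epsilon:
        raise ValueError("trajectory too short to assess saturation (< 2/epsilon)")
    if window is None:
        window = 10.0 / params.epsilon
    window = min(window, 0.8 * (traj.t[-1] - traj.t[0]))
    W = traj.weights
    t = traj.t
    n_rec = t.size
    step = t[1] - t[0] if n_rec > 1 else 0.0
    if step <= 0:
        return False, None
    from numpy.lib.stride_tricks import sliding_window_view

    ns = max(1, int(round(smooth / step)))
    if ns > 1:
        if ns > n_rec:
            return False, None
        W = sliding_window_view(W, ns, axis=0).mean(axis=-1)
        t = t[ns - 1 :]
        n_rec = t.size
    nw = max(2, int(round(window / step)) + 1)
    if nw > n_rec:
        return False, None
    windows = sliding_window_view(W, nw, axis=0)  # (n_rec-nw+1, 2N, nw)
    drift = windows.max(axis=-1) - windows.min(axis=-1)
    ok = np.all(drift < tol * params.alpha, axis=1)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return False, None
    return True, float(t[idx[0] + nw - 1])
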