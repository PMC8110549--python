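"""Two-oscillator fast-slow reduction: formulas, oracles, flow topology."""
import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import starpddp as sp
from starpddp import reduction as red
from starpddp.model import pddp_rates

DELTA = 0.5
Q = red.q_factor(0.15, 0.3)


@pytest.fixture(scope="module")
def p_sigmoid02() -> red.TwoOscParams:
    return red.TwoOscParams(delta=DELTA, alpha=1.0, epsilon=0.01,
                            boundary=sp.BoundarySpec("sigmoid", 0.2))


class TestQFactor:
    def test_reference_windows(self):
        assert red.q_factor(0.15, 0.3) == pytest.approx(0.5, abs=1e-3)

    def test_symmetric_windows(self):
        assert red.q_factor(0.2, 0.2) == 1.0

    def test_less_than_one_for_shorter_potentiation_window(self):
        for tp in np.linspace(0.02, 0.5, 12):
            for tm in np.linspace(0.02, 0.5, 12):
                if tp < tm:
                    assert red.q_factor(tp, tm) < 1.0


class TestLockedPhase:
    def test_marginal_coupling(self):
        assert red.locked_phase(DELTA * (1 + 1e-12), DELTA) == pytest.approx(
            math.pi / 2, abs=1e-5)

    def test_double_coupling(self):
        assert red.locked_phase(2 * DELTA, DELTA) == pytest.approx(math.pi / 6)

    def test_equilibrium_phase_of_full_system(self):
        assert red.locked_phase(1.0, 0.5) == pytest.approx(math.asin(0.5))

    def test_unlocked_rejected(self):
        with pytest.raises(ValueError):
            red.locked_phase(0.4, DELTA)


class TestOscillationPeriod:
    def test_uncoupled(self):
        assert red.oscillation_period(0.0, DELTA) == pytest.approx(4 * math.pi)

    def test_closed_form_value(self):
        assert red.oscillation_period(0.3, DELTA) == pytest.approx(5 * math.pi)

    def test_locked_region_rejected(self):
        with pytest.raises(ValueError):
            red.oscillation_period(0.6, DELTA)

    @pytest.mark.parametrize("K", [0.0, 0.1, 0.2, 0.3, 0.4])
    def test_matches_measured_return_time(self, K):
        """Event-detection oracle: the measured rotation period of the fast
        phase equation matches 2*pi/sqrt(Delta^2-K^2) to < 0.1%."""
        def ev(t, y):
            return y[0] - 2 * math.pi
        ev.terminal = True
        ev.direction = 1.0
        sol = solve_ivp(lambda t, y: [DELTA - K * math.sin(y[0])], (0, 1e4),
                        [0.0], events=ev, rtol=1e-10, atol=1e-12)
        measured = sol.t_events[0][0]
        assert measured == pytest.approx(red.oscillation_period(K, DELTA),
                                         rel=1e-3)


class TestAveragingKernel:
    def test_small_k_limit(self):
        phi = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(red.averaging_kernel(0.0, phi, 0.15, DELTA),
                                   np.exp(phi / 0.15) / DELTA)

    def test_unit_numerator_at_zero_phase(self):
        assert red.averaging_kernel(0.3, 0.0, 0.2, DELTA) == pytest.approx(1 / DELTA)

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError):
            red.averaging_kernel(0.5, 0.1, 0.2, DELTA)

    @pytest.mark.parametrize("K", [0.1, 0.3, 0.45])
    def test_density_integrates_to_period(self, K):
        val = quad(lambda f: 1.0 / (DELTA - K * math.sin(f)),
                   -math.pi, math.pi, epsabs=1e-12)[0]
        assert val == pytest.approx(red.oscillation_period(K, DELTA), rel=1e-10)


class TestSyncBranch:
    def test_synchronized_fixed_point(self, p_sigmoid02):
        dA, dB = red.sync_branch_rhs(0.0, 1.0, p_sigmoid02)
        assert dA == 0.0
        assert dB == 0.0

    def test_monotone_flow_toward_attractor(self, p_sigmoid02):
        for A, B in [(0.3, 0.5), (0.1, 0.9), (0.6, 0.6)]:
            dA, dB = red.sync_branch_rhs(A, B, p_sigmoid02)
            assert dA < 0 and dB > 0

    def test_matches_plasticity_rule_at_locked_phase(self, p_sigmoid02):
        """Direct-substitution oracle: the branch equals the PDDP rule
        evaluated at the locked phase."""
        p = p_sigmoid02
        A, B = 0.25, 0.65
        phi_star = red.locked_phase(A + B, p.delta)
        dA_o, dB_o = pddp_rates(phi_star, A, B, p.network())
        dA, dB = red.sync_branch_rhs(A, B, p)
        assert dA == pytest.approx(dA_o[0], rel=1e-12)
        assert dB == pytest.approx(dB_o[0], rel=1e-12)

    def test_attractor_is_linearly_stable(self, p_sigmoid02):
        h = 1e-7
        dA_in, _ = red.sync_branch_rhs(h, 1.0, p_sigmoid02)
        _, dB_in = red.sync_branch_rhs(0.0, 1.0 - h, p_sigmoid02)
        assert dA_in < 0    # perturbing A inward decays back
        assert dB_in > 0    # perturbing B downward is restored


class TestAveragedBranch:
    def test_small_k_limit_matches_decoupled_form(self, p_sigmoid02):
        """In the K->0 limit the A and B equations become identical with the
        window-integrated kernels; Delta drops out."""
        p = p_sigmoid02

        def decoupled(w):
            F = lambda x: sp.boundary_eval(p.boundary, x)
            return p.epsilon * (
                F(p.alpha - w) * p.tau_plus * (1 - math.exp(-math.pi / p.tau_plus))
                - F(w) * p.tau_minus * (1 - math.exp(-math.pi / p.tau_minus))
            ) / (2 * math.pi)

        for w in (0.05, 0.2, 0.4):
            dA, dB = red.averaged_rhs(w / 2, w / 2, replace(p, delta=37.0))
            # huge detuning emulates K/Delta -> 0 without changing the limit;
            # near the q-balance the two kernel terms nearly cancel, so an
            # absolute floor (1% of a single term) accompanies the relative one
            assert dA == pytest.approx(decoupled(w / 2), rel=0.02, abs=3e-6)
            dA0, dB0 = red.averaged_rhs(1e-9, 1e-9, p)
            assert dA0 == pytest.approx(decoupled(1e-9), rel=1e-6)
            assert dB0 == pytest.approx(dA0, rel=1e-6)

    def test_epsilon_is_a_prefactor(self, p_sigmoid02):
        dA1, dB1 = red.averaged_rhs(0.1, 0.15, p_sigmoid02)
        dA2, dB2 = red.averaged_rhs(0.1, 0.15,
                                    replace(p_sigmoid02, epsilon=0.02))
        assert dA2 == pytest.approx(2 * dA1, rel=1e-12)
        assert dB2 == pytest.approx(2 * dB1, rel=1e-12)

    def test_vanishes_at_stationary_state(self, p_sigmoid02):
        fp = red.stationary_state(p_sigmoid02)
        dA, dB = red.averaged_rhs(fp.A, fp.B, p_sigmoid02)
        assert abs(dA) < 1e-14 and abs(dB) < 1e-14

    def test_direct_averaging_oracle(self, p_sigmoid02):
        """Independent oracle: averaging the raw PDDP rule over one numerically
        integrated rotation of the fast phase reproduces the averaged flow."""
        p = p_sigmoid02
        A, B = 0.12, 0.18
        K = A + B
        T = red.oscillation_period(K, p.delta)
        net = p.network()

        def ev(t, y):  # rule branches at phi = 0: split the quadrature there
            return y[0]
        ev.direction = 1.0
        sol = solve_ivp(lambda t, y: [p.delta - K * math.sin(y[0])],
                        (0, T), [-math.pi], rtol=1e-12, atol=1e-14,
                        dense_output=True, events=ev)
        t0 = sol.t_events[0][0]

        def mean_rate(which):
            def f(t):
                phi = sp.wrap_phase(sol.sol(t)[0])
                return pddp_rates(phi, [A], [B], net)[which][0]
            return sum(quad(f, lo, hi, epsabs=1e-14, limit=400)[0]
                       for lo, hi in [(0.0, t0), (t0, T)]) / T

        dA, dB = red.averaged_rhs(A, B, p)
        assert dA == pytest.approx(mean_rate(0), rel=1e-9)
        assert dB == pytest.approx(mean_rate(1), rel=1e-9)


class TestStationaryStates:
    def test_power_reference_value(self):
        bd = sp.BoundarySpec("power", 0.2)
        # exact balance: A/(alpha-A) = q**(1/mu) -> A = 0.03125/1.03125
        assert red.stationary_weight(bd, 1.0, 0.5) == pytest.approx(
            0.5**5 / (1 + 0.5**5), rel=1e-10)

    def test_sigmoid_reference_value(self):
        bd = sp.BoundarySpec("sigmoid", 0.2)
        a = red.stationary_weight(bd, 1.0, Q)
        # oracle: plain bisection on tanh(a/mu) = q*tanh((1-a)/mu)
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if math.tanh(mid / 0.2) < Q * math.tanh((1 - mid) / 0.2):
                lo = mid
            else:
                hi = mid
        assert a == pytest.approx(lo, abs=1e-10)
        assert a == pytest.approx(0.2 * math.atanh(Q), rel=5e-3)

    @pytest.mark.parametrize("family", ["power", "sigmoid"])
    def test_vanishes_monotonically_with_mu(self, family):
        mus = [0.3, 0.2, 0.1, 0.05, 0.02]
        vals = [red.stationary_weight(sp.BoundarySpec(family, mu), 1.0, Q)
                for mu in mus]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_hard_boundary_limits(self):
        for mu in (0.05, 0.02, 0.01):
            a_sig = red.stationary_weight(sp.BoundarySpec("sigmoid", mu), 1.0, Q)
            assert a_sig / mu == pytest.approx(math.atanh(Q), rel=1e-3)
            a_pow = red.stationary_weight(sp.BoundarySpec("power", mu), 1.0, Q)
            assert a_pow**mu == pytest.approx(Q, rel=1e-2)

    def test_stationary_K_power_small_mu_law(self):
        p = red.TwoOscParams(delta=DELTA, alpha=1.0, epsilon=0.01,
                             boundary=sp.BoundarySpec("power", 0.1))
        assert red.stationary_K_power(0.1, p) == pytest.approx(
            2 * Q ** (1 / 0.1), rel=0.02)

    def test_stationary_K_power_monotone_in_mu(self):
        vals = []
        for mu in (0.6, 0.5, 0.3, 0.2, 0.1):
            p = red.TwoOscParams(delta=DELTA, alpha=1.0, epsilon=0.01,
                                 boundary=sp.BoundarySpec("power", mu))
            vals.append(red.stationary_K_power(mu, p))
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            red.stationary_weight(sp.BoundarySpec("sigmoid", 0.1), 1.0, 1.5)


class TestReducedFlow:
    def test_dispatch_between_branches(self, p_sigmoid02):
        dA_sync, _ = red.reduced_rhs(0.4, 0.4, p_sigmoid02)   # K = 0.8 > Delta
        assert (dA_sync, _) == red.sync_branch_rhs(0.4, 0.4, p_sigmoid02)
        dA_unsync, dB_unsync = red.reduced_rhs(0.1, 0.1, p_sigmoid02)
        assert (dA_unsync, dB_unsync) == red.averaged_rhs(0.1, 0.1, p_sigmoid02)

    def test_synchronized_basin_trajectory(self, p_sigmoid02):
        traj = red.integrate_reduced(0.6, 0.6, p_sigmoid02, 4000.0)
        A, B = traj.final
        assert A < 1e-6
        assert B > 0.95

    def test_unsynchronized_basin_trajectory(self, p_sigmoid02):
        fp = red.stationary_state(p_sigmoid02)
        traj = red.integrate_reduced(0.1, 0.1, p_sigmoid02, 4000.0)
        A, B = traj.final
        assert math.hypot(A - fp.A, B - fp.B) < 5e-3

    def test_bistable_basin_topology(self, p_sigmoid02):
        """Exactly two attractors whose basins form two connected regions
        separated by a single separatrix."""
        from scipy import ndimage

        labels = red.basin_grid(p_sigmoid02, n=30, s_end=120.0)
        present = set(np.unique(labels)) - {-1}
        assert present == {0, 1}
        assert (labels == -1).mean() < 0.02  # only separatrix-straddling cells
        assert ndimage.label(labels == 0)[1] == 1
        assert ndimage.label(labels == 1)[1] == 1
        # the origin corner is unsynchronized, the deep-locked corner not
        assert labels[0, 0] == 0
        assert labels[-1, -1] == 1
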