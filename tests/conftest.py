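import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import starpddp as sp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_two_osc() -> sp.NetworkParams:
    """Two-oscillator reference setup: hub at 1, leaf at 0.5, sigmoid mu=0.2."""
    return sp.NetworkParams(
        omega0=1.0, omega=np.array([0.5]), alpha=1.0, tau_plus=0.15,
        tau_minus=0.3, epsilon=1e-3, boundary=sp.BoundarySpec("sigmoid", 0.2))


@pytest.fixture(scope="session")
def three_leaf_params() -> sp.NetworkParams:
    """Three-leaf reference star: leaves (0.55, 0.7, 1.0), hub 0.85."""
    return sp.NetworkParams(
        omega0=0.85, omega=np.array([0.55, 0.7, 1.0]), alpha=1.0,
        epsilon=5e-3, boundary=sp.BoundarySpec("sigmoid", 0.01))


@pytest.fixture(scope="session")
def _warm_kernel(reference_two_osc):
    """Trigger the one-off numba compilation outside timed assertions."""
    from starpddp import survey

    survey.integrate_network(reference_two_osc, ([0.1], [0.4], [0.4]), 1.0, dt=0.01)
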