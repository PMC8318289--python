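"""Shared fixtures: parameter bundles, initial states, and a few
session-scoped simulated trajectories reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import tridomain as td
from tridomain.glia import resolve_kir_baseline
from tridomain.simulator import SolverSettings
from tridomain.state import compute_residual_charges


@pytest.fixture(scope="session")
def params():
    return td.build_default_parameters()


@pytest.fixture(scope="session")
def post_state(params):
    """Post-calibrated initial state with residuals installed."""
    return td.build_initial_state("post_calibrated", params)


@pytest.fixture(scope="session")
def rparams(params, post_state):
    """Parameters with the Kir baseline resolved for the post state."""
    return resolve_kir_baseline(params, post_state)


def make_random_state(base, params, rng, conc_sigma=0.02, vol_sigma=0.01):
    """Physiologically plausible random state: perturbed amounts and
    volumes with residual charges recomputed for random (but physical)
    membrane potentials, so potentials stay in the tens-of-mV range."""
    st = base.copy()
    st.N = base.N * np.exp(rng.normal(0.0, conc_sigma, size=(4, 6)))
    st.N[3, [2, 5]] = 0.0  # no glial Ca
    st.V = base.V * np.exp(rng.normal(0.0, vol_sigma, size=6))
    st.gating = np.clip(rng.uniform(0.0, 1.0, 6), 1e-3, 1.0)
    phi_n = rng.uniform(-0.09, 0.02)
    phi_g = rng.uniform(-0.10, -0.05)
    st.X = compute_residual_charges(st, params, phi_n, phi_g)
    return st


@pytest.fixture()
def random_states(post_state, rparams):
    rng = np.random.default_rng(1234)
    return [make_random_state(post_state, rparams, rng) for _ in range(20)]


# --- session-scoped simulations (reused by acceptance + unit tests) -----


@pytest.fixture(scope="session")
def resting_traj(params):
    """10 s unstimulated run from the calibrated resting state."""
    return td.run(None, (0.0, 10.0), params=params)


@pytest.fixture(scope="session")
def fig3_traj_3s(params):
    """First 3 s of the 1 Hz physiological firing protocol (22 pA K+
    somatic step), enough to capture the first action potential."""
    proto = td.InjectionProtocol("K", "soma", 22e-12, 1.0, 600.0)
    return td.run(proto, (0.0, 3.0), params=params)


@pytest.fixture(scope="session")
def fig4_traj_10s(params):
    """First 10 s of the pathological protocol (150 pA K+ somatic step
    from t = 1 to 8 s): fast initial firing then depolarization block."""
    proto = td.InjectionProtocol("K", "soma", 150e-12, 1.0, 8.0)
    return td.run(proto, (0.0, 10.0), SolverSettings(output_stride=2e-4), params)


@pytest.fixture(scope="session")
def fig3_traj_60s(params):
    """60 s of the 1 Hz physiological firing protocol, sampled finely
    enough (0.5 ms) to resolve action-potential peaks."""
    proto = td.InjectionProtocol("K", "soma", 22e-12, 1.0, 600.0)
    return td.run(proto, (0.0, 60.0), SolverSettings(output_stride=5e-4), params)
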