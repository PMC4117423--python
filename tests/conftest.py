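"""Shared fixtures: small networks and pre-run simulations reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from neuromass.connectivity import DelayMatrix, build_homogeneous
from neuromass.model_core import NetworkParams, find_fixed_points
from neuromass.network_simulator import simulate_ensemble


@pytest.fixture(scope="session")
def pair_net():
    """One isolated E/I pair at balanced inputs, no jitter."""
    return NetworkParams.balanced(1, 6.5, param_jitter=0.0, seed=0)


@pytest.fixture(scope="session")
def homogeneous_setup():
    """10-pair strong-coupling homogeneous network (no delays)."""
    n_pairs = 10
    c, k = 6.5, 2.0
    net = NetworkParams.balanced(n_pairs, c, seed=7)
    C = build_homogeneous(n_pairs, c, k)
    D = DelayMatrix.zero(2 * n_pairs)
    return {"net": net, "C": C, "D": D, "c": c, "k": k, "n_pairs": n_pairs}


@pytest.fixture(scope="session")
def homogeneous_run(homogeneous_setup):
    """Two-trial ensemble of the strong-coupling homogeneous network."""
    s = homogeneous_setup
    ens = simulate_ensemble(
        s["C"], s["D"], s["net"], duration=3.0, dt=1e-4, n_trials=2, base_seed=42
    )
    return {**s, "ens": ens, "window": (1.0, 2.75)}


@pytest.fixture(scope="session")
def homogeneous_fp(homogeneous_setup):
    s = homogeneous_setup
    return find_fixed_points(s["C"], s["net"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
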