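"""Averaged phase model: construction, simulation, Kuramoto mapping."""

import numpy as np
import pytest

from neuromass.connectivity import DelayMatrix, build_delays, build_homogeneous
from neuromass.model_core import NetworkParams, find_fixed_points
from neuromass.phase_reduction import (
    estimate_amplitudes,
    kuramoto_transform,
    order_parameter,
    reduce,
    simulate_phases,
    wrap_phase,
)


@pytest.fixture(scope="module")
def small_pm():
    net = NetworkParams.balanced(5, 6.5, param_jitter=0.0, seed=0)
    C = build_homogeneous(5, 6.5, 1.0)
    D = DelayMatrix.zero(10)
    fp = find_fixed_points(C, net)
    return reduce(C, D, net, fp)


class TestReduce:
    def test_zero_delay_gives_zero_shifts(self, small_pm):
        assert np.all(small_pm.shifts == 0)
        assert np.all(np.diag(small_pm.K) == 0)

    def test_shifts_are_omega_times_delay(self):
        net = NetworkParams.balanced(3, 6.5, param_jitter=0.0, seed=0)
        C = build_homogeneous(3, 6.5, 1.0)
        D = build_delays(6, "constant", 1e-3)
        pm = reduce(C, D, net)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(pm.shifts[off], pm.Omega * 1e-3)
        assert np.all(pm.shifts[~off] == 0)

    def test_k_linear_in_structural_coupling(self):
        net = NetworkParams.balanced(3, 6.5, param_jitter=0.0, seed=0)
        C1 = build_homogeneous(3, 6.5, 1.0)
        C2 = type(C1)(2.0 * C1.entries, C1.e_indices, C1.i_indices)
        fp = find_fixed_points(C1, net)
        D = DelayMatrix.zero(6)
        Om = reduce(C1, D, net, fp).Omega
        pm1 = reduce(C1, D, net, fp, Omega=Om)
        pm2 = reduce(C2, D, net, fp, Omega=Om)
        assert np.allclose(pm2.K, 2.0 * pm1.K)

    def test_equal_amplitudes_make_k_proportional_to_weighted_c(self):
        net = NetworkParams.balanced(3, 6.5, param_jitter=0.0, seed=0)
        C = build_homogeneous(3, 6.5, 1.0)
        fp = find_fixed_points(C, net)
        pm = reduce(C, DelayMatrix.zero(6), net, fp, amplitudes=np.ones(6))
        from neuromass.model_core import sigmoid_slope

        slopes = np.array(
            [float(sigmoid_slope(fp.V_star[m], net.masses[m].sigmoid)) for m in range(6)]
        )
        ab = net.a_vec() * net.b_vec()
        expect = -(ab[:, None] / (2 * pm.Omega)) * C.entries * slopes[None, :]
        np.fill_diagonal(expect, 0)
        assert np.allclose(pm.K, expect)

    def test_k_sign_pattern_follows_source_type(self, small_pm):
        e, i = small_pm.e_indices, small_pm.i_indices
        off = ~np.eye(small_pm.n_nodes, dtype=bool)
        K = small_pm.K
        # negative averaging prefactor: excitatory-source columns <= 0
        assert np.all((K[:, e] <= 0) | ~off[:, e])
        assert np.all((K[:, i] >= 0) | ~off[:, i])

    def test_zero_amplitude_rejected(self, small_pm):
        net = NetworkParams.balanced(2, 6.5, param_jitter=0.0, seed=0)
        C = build_homogeneous(2, 6.5, 1.0)
        with pytest.raises(ValueError):
            reduce(C, DelayMatrix.zero(4), net, amplitudes=np.zeros(4))


class TestAmplitudes:
    def test_pure_sinusoid_envelope(self):
        from neuromass.network_simulator import SimulationTrace

        t = np.arange(0, 2.0, 1e-3)
        V = 1.7 * np.cos(2 * np.pi * 40 * t)[None, :].repeat(4, axis=0)
        tr = SimulationTrace(t=t, V=V, W=np.zeros_like(V), meta={"dt": 1e-3})
        r = estimate_amplitudes(
            tr, (0.2, 1.8), e_indices=np.array([0, 1]), i_indices=np.array([2, 3])
        )
        assert np.allclose(r, 1.7, rtol=0.01)

    def test_pooled_mode_returns_two_values(self, homogeneous_run):
        tr = homogeneous_run["ens"].traces[0]
        C = homogeneous_run["C"]
        r = estimate_amplitudes(
            tr, homogeneous_run["window"],
            e_indices=C.e_indices, i_indices=C.i_indices,
        )
        assert len(np.unique(r)) <= 2

    def test_per_node_amplitudes_close_to_pooled(self):
        # the equal-amplitude assumption in its own regime: identical pairs
        from neuromass.network_simulator import simulate

        net = NetworkParams.balanced(6, 6.5, param_jitter=0.0, seed=0)
        C = build_homogeneous(6, 6.5, 2.0)
        tr = simulate(C, DelayMatrix.zero(12), net, 3.0, 1e-4, seed=11)
        r_raw = estimate_amplitudes(
            tr, (1.0, 2.75),
            e_indices=C.e_indices, i_indices=C.i_indices, pooled=False,
        )
        pooled_e = np.median(r_raw[C.e_indices])
        assert np.all(np.abs(r_raw[C.e_indices] - pooled_e) / pooled_e < 0.05)

    def test_short_window_rejected(self, homogeneous_run):
        tr = homogeneous_run["ens"].traces[0]
        C = homogeneous_run["C"]
        with pytest.raises(ValueError):
            estimate_amplitudes(
                tr, (1.0, 1.02), e_indices=C.e_indices, i_indices=C.i_indices
            )


class TestSimulatePhases:
    def test_free_rotation_without_coupling(self, small_pm):
        from dataclasses import replace

        pm0 = replace(small_pm, K=np.zeros_like(small_pm.K))
        phi0 = np.linspace(0, 1, pm0.n_nodes)
        tr = simulate_phases(pm0, phi0, 0.1, 1e-4)
        expect = phi0[:, None] + pm0.omega[:, None] * tr.t[None, :]
        assert np.allclose(tr.phi, expect, atol=1e-9)

    def test_synchronized_manifold_is_invariant(self):
        net = NetworkParams.balanced(4, 6.5, param_jitter=0.0, seed=0)
        C = build_homogeneous(4, 6.5, 1.5)
        pm = reduce(C, DelayMatrix.zero(8), net)
        # identical nodes, zero shifts: relative phases of the two-cluster
        # stationary state stay fixed
        from neuromass.stationary_clusters import compute_constants, solve_two_cluster

        sol = solve_two_cluster(compute_constants(pm), 0.0)
        phi0 = np.zeros(8)
        phi0[pm.i_indices] = sol.deltas[0]
        tr = simulate_phases(pm, phi0, 0.2, 1e-4, rotating_frame=True)
        rel = tr.phi - tr.phi[0]
        assert np.max(np.abs(rel[:, -1] - rel[:, 0])) < 1e-6


class TestKuramotoTransform:
    def make_equalized_pm(self, jitter=0.0):
        n = 8
        k_entry = 0.05
        net = NetworkParams.balanced(n, k_entry, param_jitter=jitter, seed=3)
        C = build_homogeneous(n, k_entry, k_entry * n)  # between entries == c
        pm = reduce(C, DelayMatrix.zero(2 * n), net, Omega=np.sqrt(220.0 * 720.0))
        return pm

    def test_homogeneous_input_gives_equal_magnitudes(self):
        kt = kuramoto_transform(self.make_equalized_pm())
        off = ~np.eye(kt.model.n_nodes, dtype=bool)
        mags = kt.model.K[off]
        assert kt.asymmetry < 1e-12
        assert np.allclose(mags, mags[0])

    def test_round_trip_trajectories_identical(self, rng):
        pm = self.make_equalized_pm(jitter=0.05)
        kt = kuramoto_transform(pm)
        phi0 = rng.uniform(-np.pi, np.pi, pm.n_nodes)
        tr = simulate_phases(pm, phi0, 0.5, 1e-3, rotating_frame=True)
        tr_t = simulate_phases(
            kt.model, kt.from_original(phi0), 0.5, 1e-3, rotating_frame=True
        )
        assert np.max(np.abs(kt.to_original(tr_t.phi) - tr.phi)) < 1e-9

    def test_asymmetry_monotone_in_inhomogeneity(self):
        from neuromass.connectivity import build_inhomogeneous

        asyms = []
        for width in (0.0, 0.3, 0.6, 0.9):
            net = NetworkParams.balanced(6, 6.5, param_jitter=0.0, seed=0)
            C = build_inhomogeneous(6, 6.5, 1.0, width, seed=5)
            pm = reduce(C, DelayMatrix.zero(12), net)
            asyms.append(kuramoto_transform(pm).asymmetry)
        assert all(a < b for a, b in zip(asyms, asyms[1:]))

    def test_synchronized_state_is_stationary_after_transform(self):
        # zero shifts, cosine coupling: the two-cluster state maps to full
        # synchrony and its drift vanishes
        pm = self.make_equalized_pm()
        kt = kuramoto_transform(pm)
        from neuromass.stationary_clusters import drift

        psi = np.zeros(pm.n_nodes)
        d = drift(kt.to_original(psi), pm)
        assert np.max(np.abs(d)) < 1e-10


class TestOrderParameter:
    def test_full_synchrony(self):
        R, Th = order_parameter(np.full(10, 0.7))
        assert R == pytest.approx(1.0)
        assert Th == pytest.approx(0.7)

    def test_uniform_spacing_cancels(self):
        phi = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        R, _ = order_parameter(phi)
        assert R < 1e-12

    def test_antipodal_clusters_cancel(self):
        phi = np.array([0.3] * 5 + [0.3 + np.pi] * 5)
        R, _ = order_parameter(phi)
        assert R < 1e-12

    def test_global_shift_invariance(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 50)
        R1, T1 = order_parameter(phi)
        R2, T2 = order_parameter(phi + 1.1)
        assert R2 == pytest.approx(R1)
        assert wrap_phase(T2 - T1 - 1.1) == pytest.approx(0.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            order_parameter(np.array([]))


def test_wrap_phase_interval():
    x = np.array([-np.pi, np.pi, 3 * np.pi, -3 * np.pi + 1e-9, 0.0])
    w = wrap_phase(x)
    assert np.all(w > -np.pi) and np.all(w <= np.pi)
    assert np.allclose(np.exp(1j * w), np.exp(1j * x))
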