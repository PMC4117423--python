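"""Measurement pipeline: spectra, filtering, Hilbert phases, distributions."""

import numpy as np
import pytest

from neuromass.fixtures import make_phase_fixture
from neuromass.phase_extraction import (
    bandpass,
    circular_correlation,
    circular_mean,
    circular_variance,
    count_modes,
    detect_common_frequency,
    detrend_align,
    extract_aligned_phases,
    hilbert_phase,
    phase_distribution,
    refine_frequency,
)
from neuromass.phase_reduction import PhaseTrace, wrap_phase


class TestDetectCommonFrequency:
    def test_common_sinusoid(self):
        fx = make_phase_fixture([40.0, 40.0, 40.0], [0.0, 0.5, 1.0], duration=3.0)
        Om = detect_common_frequency(fx.trace, (0.2, 2.8))
        assert abs(Om / (2 * np.pi) - 40.0) < 2.6  # within one bin

    def test_lowest_rule_with_harmonic(self):
        t = np.arange(0, 3.0, 1e-3)
        V = np.vstack(
            [np.cos(2 * np.pi * 30 * t) + 0.4 * np.cos(2 * np.pi * 60 * t)
             for _ in range(3)]
        )
        from neuromass.network_simulator import SimulationTrace

        tr = SimulationTrace(t=t, V=V, W=np.zeros_like(V), meta={"dt": 1e-3})
        Om = detect_common_frequency(tr, (0.2, 2.8))
        assert abs(Om / (2 * np.pi) - 30.0) < 2.6

    def test_disjoint_rhythms_fail_loudly(self):
        fx = make_phase_fixture([20.0, 45.0], [0.0, 0.0], duration=3.0)
        with pytest.raises(RuntimeError, match="coinciding"):
            detect_common_frequency(fx.trace, (0.2, 2.8))

    def test_pair_simulation_matches_linear_prediction(self, homogeneous_run):
        from neuromass.linear_analysis import isolated_pair, pair_eigenvalues_small_delay
        from neuromass.model_core import NetworkParams

        # frequency detected from the network run is near the pair prediction
        Om = detect_common_frequency(homogeneous_run["ens"], homogeneous_run["window"])
        net0 = NetworkParams.balanced(1, 6.5, param_jitter=0.0, seed=0)
        pp, _ = isolated_pair(net0, 6.5)
        lam = pair_eigenvalues_small_delay(pp, 6.5, 0.0).unstable_pair()
        assert abs(Om - lam.imag) / lam.imag < 0.15


class TestBandpassHilbert:
    def test_zero_phase_property_in_band(self):
        fx = make_phase_fixture([40.0], [0.3], duration=3.0)
        ft = bandpass(fx.trace, 2 * np.pi * 40.0, 2.0)
        ph = hilbert_phase(ft, (0.5, 2.5))
        sl = fx.trace.window_slice((0.5, 2.5))
        true = fx.true_phases[0, sl]
        err = wrap_phase(ph.phi[0] - true)
        assert np.max(np.abs(err)) < 1e-2
        assert abs(circular_mean(err)) < 1e-3

    def test_out_of_band_attenuation(self):
        fs, f0 = 1000.0, 10.0
        fx = make_phase_fixture([5 * (f0 + 2)], [0.0], duration=3.0, fs=fs)
        ft = bandpass(fx.trace, 2 * np.pi * f0, 2.0)
        sl = fx.trace.window_slice((0.5, 2.5))
        assert np.std(ft.V[0, sl]) < np.std(fx.trace.V[0, sl]) / 10

    def test_cascade_squares_magnitude_response(self):
        # sinusoid probes: filtering twice squares the amplitude gain
        for f_probe in (36.0, 40.0, 47.0):
            fx = make_phase_fixture([f_probe], [0.0], duration=4.0)
            once = bandpass(fx.trace, 2 * np.pi * 40, 5.0)
            twice = bandpass(once, 2 * np.pi * 40, 5.0)
            sl = fx.trace.window_slice((1.0, 3.0))
            a0 = np.std(fx.trace.V[0, sl])
            a1 = np.std(once.V[0, sl]) / a0
            a2 = np.std(twice.V[0, sl]) / a0
            assert a2 == pytest.approx(a1**2, rel=0.02)

    def test_band_outside_nyquist_rejected(self):
        fx = make_phase_fixture([40.0], [0.0], fs=200.0)
        with pytest.raises(ValueError):
            bandpass(fx.trace, 2 * np.pi * 99.0, 2.0)

    def test_phase_scale_invariance(self):
        fx = make_phase_fixture([40.0], [0.2], duration=2.0)
        tr2 = type(fx.trace)(
            t=fx.trace.t, V=5.0 * fx.trace.V, W=fx.trace.W, meta=fx.trace.meta
        )
        p1 = hilbert_phase(fx.trace, (0.3, 1.7)).phi
        p2 = hilbert_phase(tr2, (0.3, 1.7)).phi
        assert np.allclose(p1, p2, atol=1e-9)

    def test_relative_phase_offset_recovered(self):
        fx = make_phase_fixture([40.0, 40.0], [0.0, 0.8], duration=3.0)
        ft = bandpass(fx.trace, 2 * np.pi * 40, 2.0)
        ph = hilbert_phase(ft, (0.5, 2.5))
        rel = circular_mean(ph.phi[1] - ph.phi[0])
        assert abs(rel - 0.8) < 1e-3

    def test_window_touching_edges_rejected(self):
        fx = make_phase_fixture([40.0], [0.0], duration=2.0)
        with pytest.raises(ValueError):
            hilbert_phase(fx.trace, (0.0, 1.0))


class TestDetrendAlign:
    def make_phases(self, offset=0.0):
        t = np.arange(0, 1.0, 1e-3)
        Om = 2 * np.pi * 40
        phi = np.vstack([Om * t + 0.2 + offset, Om * t - 0.1 + offset, Om * t + 1.4 + offset])
        return PhaseTrace(t=t, phi=phi)

    def test_e_mean_centered_and_idempotent(self):
        ph = self.make_phases()
        e_idx = np.array([0, 1])
        al = detrend_align(ph, 2 * np.pi * 40, e_idx)
        assert abs(circular_mean(al.phi[e_idx].ravel())) < 1e-12
        al2 = detrend_align(al, 0.0, e_idx)
        assert np.allclose(al2.phi, al.phi, atol=1e-12)

    def test_global_offset_removed(self):
        e_idx = np.array([0, 1])
        a = detrend_align(self.make_phases(), 2 * np.pi * 40, e_idx)
        b = detrend_align(self.make_phases(offset=2.2), 2 * np.pi * 40, e_idx)
        assert np.allclose(a.phi, b.phi, atol=1e-9)

    def test_empty_excitatory_set_rejected(self):
        with pytest.raises(ValueError):
            detrend_align(self.make_phases(), 0.0, np.array([]))

    def test_refine_frequency_beats_bin_resolution(self):
        fx = make_phase_fixture([40.37], [0.0], duration=3.0)
        ft = bandpass(fx.trace, 2 * np.pi * 40, 3.0)
        ph = hilbert_phase(ft, (0.5, 2.5))
        Om = refine_frequency(ph)
        assert abs(Om / (2 * np.pi) - 40.37) < 0.01


class TestDistribution:
    def test_identical_phases_single_mode_zero_variance(self):
        phi = np.full((4, 500), 0.4)
        tr = PhaseTrace(t=np.arange(500) * 1e-3, phi=phi)
        dist = phase_distribution(tr, np.array([0, 1]), np.array([2, 3]))
        assert dist.mode_count == 1
        assert dist.circ_var_e < 1e-12
        width = dist.bin_edges[1] - dist.bin_edges[0]
        assert np.sum(dist.density_e) * width == pytest.approx(1.0)

    def test_uniform_phases_no_modes_high_variance(self, rng):
        phi = rng.uniform(-np.pi, np.pi, (4, 20000))
        tr = PhaseTrace(t=np.arange(20000) * 1e-3, phi=phi)
        dist = phase_distribution(tr, np.array([0, 1]), np.array([2, 3]))
        assert dist.circ_var_e > 0.95
        assert dist.mode_count == 0

    def test_two_cluster_sample_counts_two_modes(self, rng):
        e = rng.vonmises(0.0, 80.0, (2, 5000))
        i = rng.vonmises(-1.3, 80.0, (2, 5000))
        tr = PhaseTrace(t=np.arange(5000) * 1e-3, phi=np.vstack([e, i]))
        dist = phase_distribution(tr, np.array([0, 1]), np.array([2, 3]))
        assert dist.mode_count == 2

    def test_too_few_bins_rejected(self):
        tr = PhaseTrace(t=np.arange(10) * 1e-3, phi=np.zeros((2, 10)))
        with pytest.raises(ValueError):
            phase_distribution(tr, np.array([0]), np.array([1]), bins=4)

    def test_pipeline_rotation_equivariance(self, homogeneous_run):
        ens = homogeneous_run["ens"]
        C = homogeneous_run["C"]
        window = homogeneous_run["window"]
        aligned, _ = extract_aligned_phases(ens, window, C.e_indices)
        d1 = phase_distribution(aligned, C.e_indices, C.i_indices)
        # rotating every raw trace in time (circular shift of initial phase)
        # is absorbed by the per-trial alignment: distributions coincide
        rotated = [PhaseTrace(t=a.t, phi=a.phi + 1.234) for a in aligned]
        realigned = [detrend_align(r, 0.0, C.e_indices) for r in rotated]
        d2 = phase_distribution(realigned, C.e_indices, C.i_indices)
        assert np.allclose(d1.density_e, d2.density_e, atol=1e-12)
        assert d1.circ_var_e == pytest.approx(d2.circ_var_e, abs=1e-12)


def test_circular_statistics_basics(rng):
    x = rng.vonmises(0.7, 5.0, 3000)
    assert abs(circular_mean(x) - 0.7) < 0.05
    assert 0 < circular_variance(x) < 0.3
    y = wrap_phase(x + 0.4 + 0.05 * rng.standard_normal(3000))
    assert circular_correlation(x, y) > 0.9
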