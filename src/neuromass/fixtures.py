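"""Deterministic synthetic inputs with analytically known answers.

Two families: analytic phase fixtures (sinusoidal traces whose
instantaneous phases, pairwise offsets and phase-locking values are known in
closed form) and isolated E/I pair fixtures bundling the network with its
recomputed linear spectrum.  Manifests are recomputed from closed forms at
construction, never stored as magic numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linear_analysis import LinearSpectrum, PairParams, isolated_pair, pair_eigenvalues_small_delay
from .model_core import NetworkParams
from .network_simulator import SimulationTrace

__all__ = ["PhaseFixture", "PairFixture", "make_phase_fixture", "make_pair_fixture", "get_fixture"]


@dataclass(frozen=True)
class PhaseFixture:
    """Sinusoidal traces with exactly known instantaneous phases."""

    trace: SimulationTrace
    true_phases: np.ndarray      # unwrapped, per node x sample
    freqs: np.ndarray            # Hz per node
    offsets: np.ndarray          # rad per node
    noise_sd: float
    seed: int

    def expected_plv(self, n: int, m: int, window: tuple[float, float]) -> float:
        """Closed-form noise-free PLV of nodes n, m over the window.

        For a constant frequency difference ``dw`` over a window of length
        ``T`` the time-averaged phasor of the relative phase has modulus
        ``|sinc(dw T / 2)| = |sin(dw T / 2) / (dw T / 2)|``.
        """
        T = window[1] - window[0]
        dw = 2.0 * np.pi * (self.freqs[n] - self.freqs[m])
        if dw == 0:
            return 1.0
        x = dw * T / 2.0
        return float(abs(np.sin(x) / x))


def make_phase_fixture(
    freqs,
    offsets,
    noise_sd: float = 0.0,
    duration: float = 2.0,
    fs: float = 1000.0,
    seed: int = 0,
) -> PhaseFixture:
    """Cosine voltage traces ``cos(2 pi f_n t + delta_n)`` plus optional noise."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    if freqs.shape != offsets.shape:
        raise ValueError("freqs and offsets must have matching shapes")
    if fs <= 4.0 * freqs.max():
        raise ValueError("sampling rate must exceed 4x the largest frequency")
    t = np.arange(int(round(duration * fs)) + 1) / fs
    phases = 2.0 * np.pi * freqs[:, None] * t[None, :] + offsets[:, None]
    V = np.cos(phases)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        V = V + noise_sd * rng.standard_normal(V.shape)
    trace = SimulationTrace(
        t=t, V=V, W=np.zeros_like(V),
        meta={"dt": 1.0 / fs, "duration": duration, "seed": seed,
              "param_digest": "phase-fixture"},
    )
    return PhaseFixture(
        trace=trace, true_phases=phases, freqs=freqs, offsets=offsets,
        noise_sd=noise_sd, seed=seed,
    )


@dataclass(frozen=True)
class PairFixture:
    """One isolated E/I pair with its closed-form linear spectrum."""

    net: NetworkParams
    c: float
    pairp: PairParams
    spectrum: LinearSpectrum        # at tau = 0
    oscillatory: bool
    coupling: np.ndarray = field(repr=False)

    @property
    def frequency_hz(self) -> float:
        lam = self.spectrum.unstable_pair()
        return float(lam.imag / (2.0 * np.pi)) if lam is not None else np.nan


def make_pair_fixture(c: float = 6.0, *, damped: bool = False, seed: int = 0) -> PairFixture:
    """Isolated pair at balanced inputs; ``damped`` selects a sub-threshold c.

    The default sits just above the oscillation threshold, the regime in
    which the averaging assumptions (growth slow against the rhythm) hold.
    """
    if damped:
        c = min(c, 4.0)
    net = NetworkParams.balanced(1, c, param_jitter=0.0, seed=seed)
    pairp, fp = isolated_pair(net, c)
    spec = pair_eigenvalues_small_delay(pairp, c, 0.0)
    C = np.zeros((2, 2))
    C[0, 1], C[1, 0] = -c, c
    return PairFixture(
        net=net, c=c, pairp=pairp, spectrum=spec,
        oscillatory=spec.unstable_pair() is not None, coupling=C,
    )


_REGISTRY = {
    "pair_default": lambda: make_pair_fixture(),
    "pair_damped": lambda: make_pair_fixture(damped=True),
    "two_tone": lambda: make_phase_fixture([40.0, 41.0], [0.0, 0.7], seed=1),
    "locked_pair": lambda: make_phase_fixture([40.0, 40.0], [0.0, 0.9], seed=2),
}


def get_fixture(name: str):
    """Fixture lookup by name (``pair_default``, ``two_tone``, ...)."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_REGISTRY)}") from None
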