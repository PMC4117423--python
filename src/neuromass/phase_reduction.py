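"""Averaged phase-oscillator reduction of the delayed neural-mass network.

Writing each mass as a perturbed harmonic oscillation around its fixed
point, ``V_n = V*_n + r_n cos(Omega t + phi_n)``, and averaging the
linear-coupling dynamics over one period (rotating-wave plus slowly-varying
amplitude approximation) collapses every node to a single phase variable:

    phi_n' = omega_n - Omega + sum_m K_nm cos(phi_m - phi_n - Omega tau_nm)

with

    omega_n = Omega + (a_n b_n - Omega^2) / (2 Omega)
    K_nm    = -(a_n b_n / (2 Omega)) C_nm S'(V*_m) r_m / r_n

Delays survive only as phase shifts ``Omega tau_nm`` (time-scale separation:
phase dynamics slow against the oscillation, delays at most of the order of
one period).  The sign convention was fixed against the linear eigenmode of
an isolated E/I pair: the inhibitory member lags its excitatory partner by
pi/2 with amplitude ratio ``r_I / r_E = sqrt(S'_E / S'_I)``, and both the
phase model and the full model reproduce this.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import CouplingMatrix, DelayMatrix
from .linear_analysis import PairParams, pair_characteristic_root, pair_eigenvalues_small_delay
from .model_core import FixedPoint, NetworkParams, find_fixed_points, sigmoid_slope
from .network_simulator import SimulationTrace

__all__ = [
    "PhaseModel",
    "PhaseTrace",
    "reduce",
    "estimate_amplitudes",
    "amplitude_ratio_analytic",
    "simulate_phases",
    "kuramoto_transform",
    "order_parameter",
    "wrap_phase",
]


def wrap_phase(phi):
    """Wrap angles to the interval (-pi, pi]."""
    return -np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi) + np.pi


@dataclass(frozen=True)
class PhaseModel:
    """Reduced phase description: frequencies, effective coupling, shifts.

    ``omega`` are absolute natural frequencies (rad/s), ``K`` the effective
    coupling (1/s), ``shifts`` the delay-induced phase shifts ``Omega tau``
    (rad), ``Omega`` the common carrier frequency, ``amplitudes`` the
    stationary oscillation amplitudes entering ``K``.
    """

    omega: np.ndarray
    K: np.ndarray
    shifts: np.ndarray
    Omega: float
    amplitudes: np.ndarray
    e_indices: np.ndarray
    i_indices: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.omega.shape[0]
        if self.K.shape != (n, n) or self.shifts.shape != (n, n):
            raise ValueError("inconsistent phase-model shapes")
        if np.any(np.diag(self.K) != 0):
            raise ValueError("effective coupling must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.omega.shape[0]

    def velocity(self, phi: np.ndarray, rotating_frame: bool = False) -> np.ndarray:
        """Instantaneous phase velocities at configuration ``phi``."""
        diff = phi[None, :] - phi[:, None] - self.shifts
        v = self.omega + np.sum(self.K * np.cos(diff), axis=1)
        if rotating_frame:
            v = v - self.Omega
        return v


@dataclass(frozen=True)
class PhaseTrace:
    """Unwrapped phases on a uniform grid; wrap with :func:`wrap_phase`."""

    t: np.ndarray
    phi: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.phi.shape[0]


def amplitude_ratio_analytic(pairp: PairParams) -> float:
    """Stationary amplitude ratio r_I / r_E of one pair from its eigenmode."""
    return float(np.sqrt(pairp.slope_e / pairp.slope_i))


def estimate_amplitudes(
    trace: SimulationTrace,
    window: tuple[float, float],
    *,
    e_indices: np.ndarray | None = None,
    i_indices: np.ndarray | None = None,
    pooled: bool = True,
) -> np.ndarray:
    """Per-node oscillation amplitudes from the analytic-signal envelope.

    The per-node envelope median over ``window`` is returned; with ``pooled``
    (and the node partition given) amplitudes are pooled by node type into a
    single ``r_E`` and ``r_I`` — the homogeneity assumption of the reduction.
    The window must span at least 3 oscillation periods (estimated from the
    dominant spectral component).
    """
    from scipy.signal import hilbert, periodogram

    sl = trace.window_slice(window)
    X = trace.V[:, sl]
    X = X - X.mean(axis=1, keepdims=True)
    f, p = periodogram(X.mean(axis=0), fs=1.0 / trace.dt)
    f0 = f[np.argmax(p[1:]) + 1]
    if f0 > 0 and (window[1] - window[0]) < 3.0 / f0:
        raise ValueError("amplitude window must span at least 3 oscillation periods")
    env = np.abs(hilbert(X, axis=1))
    r = np.median(env, axis=1)
    if pooled:
        if e_indices is None or i_indices is None:
            raise ValueError("pooled amplitude estimate needs the E/I partition")
        r = r.copy()
        r[e_indices] = np.median(r[e_indices])
        r[i_indices] = np.median(r[i_indices])
    return r


def _network_frequency(
    C: CouplingMatrix, net: NetworkParams, fp: FixedPoint, D: DelayMatrix,
    tol: float = 1e-10, max_iter: int = 100,
) -> float:
    """Self-consistent common frequency Omega.

    Each pair's within-pair gain defines its characteristic root; Omega is
    the mean unstable-root frequency at the mean delay, refined by a
    fixed-point loop over complex-Newton solves of the exact delayed
    characteristic equation (delays enter the reduction only through the
    shift ``Omega tau``, so the carrier must solve its own dispersion
    relation).
    """
    e_idx, i_idx = C.e_indices, C.i_indices
    n = C.n_nodes
    off = ~np.eye(n, dtype=bool)
    tau_bar = float(D.entries[off].mean()) if n > 1 else 0.0

    slopes = np.array(
        [sigmoid_slope(fp.V_star[m], net.masses[m].sigmoid) for m in range(n)]
    )
    omegas = []
    pair_items = list(net.pairing.items())
    for e, i in pair_items:
        c_ei = abs(C.entries[e, i])
        if c_ei == 0:
            continue
        pairp = PairParams(
            a=net.masses[e].a, b=net.masses[e].b,
            slope_e=float(slopes[e]), slope_i=float(slopes[i]),
        )
        lam0 = pair_eigenvalues_small_delay(pairp, c_ei, 0.0).unstable_pair()
        if lam0 is None:
            # sub-threshold pair: use the marginal zero-delay frequency
            # sqrt(ab), the rhythm the pair adopts at oscillation onset
            omegas.append(np.sqrt(pairp.a * pairp.b))
            continue
        omega = abs(lam0.imag)
        for _ in range(max_iter):
            lam = pair_characteristic_root(
                pairp, c_ei, tau_bar, branch=complex(lam0.real, omega)
            )
            if abs(abs(lam.imag) - omega) < tol:
                omega = abs(lam.imag)
                break
            omega = abs(lam.imag)
        omegas.append(omega)
    if not omegas:
        raise RuntimeError("no coupled pair found; cannot determine a carrier frequency")
    return float(np.mean(omegas))


def reduce(
    C: CouplingMatrix,
    D: DelayMatrix,
    net: NetworkParams,
    fp: FixedPoint | None = None,
    amplitudes: np.ndarray | None = None,
    Omega: float | None = None,
) -> PhaseModel:
    """Construct the averaged phase model from the structural description.

    ``amplitudes`` defaults to the analytic per-pair stationary ratio
    (``r_E = 1``, ``r_I = sqrt(S'_E / S'_I)``); pass simulation-estimated
    values (see :func:`estimate_amplitudes`) to use measured ones.  ``Omega``
    defaults to the self-consistent network frequency.
    """
    n = net.n_nodes
    if fp is None:
        fp = find_fixed_points(C, net)
    slopes = np.array(
        [sigmoid_slope(fp.V_star[m], net.masses[m].sigmoid) for m in range(n)]
    )
    if amplitudes is None:
        amplitudes = np.ones(n)
        for e, i in net.pairing.items():
            amplitudes[i] = np.sqrt(slopes[e] / slopes[i])
    else:
        amplitudes = np.asarray(amplitudes, dtype=float)
        if np.any(amplitudes <= 0):
            raise ValueError("amplitudes must be strictly positive")
    if Omega is None:
        Omega = _network_frequency(C, net, fp, D)

    a, b = net.a_vec(), net.b_vec()
    ab = a * b
    K = -(ab[:, None] / (2.0 * Omega)) * C.entries * slopes[None, :] * (
        amplitudes[None, :] / amplitudes[:, None]
    )
    np.fill_diagonal(K, 0.0)
    omega = Omega + (ab - Omega**2) / (2.0 * Omega)
    shifts = Omega * D.entries
    return PhaseModel(
        omega=omega, K=K, shifts=shifts, Omega=float(Omega),
        amplitudes=amplitudes, e_indices=C.e_indices, i_indices=C.i_indices,
        meta={"scheme": C.scheme_tag},
    )


def simulate_phases(
    pm: PhaseModel,
    init: np.ndarray,
    duration: float,
    dt: float,
    *,
    rotating_frame: bool = False,
) -> PhaseTrace:
    """Euler-forward trajectory of the phase model (phases stored unwrapped).

    With ``rotating_frame`` the common carrier ``Omega`` is subtracted, which
    permits much larger steps since only the slow phase dynamics remains.
    """
    max_rate = float(np.max(np.abs(pm.omega - (pm.Omega if rotating_frame else 0.0))))
    if max_rate > 0 and dt > 0.2 * 2.0 * np.pi / max(max_rate, 1e-12):
        raise ValueError("dt too coarse for the fastest phase rate")
    phi = np.asarray(init, dtype=float).copy()
    if phi.shape != (pm.n_nodes,):
        raise ValueError("init must provide one phase per node")
    steps = int(round(duration / dt))
    out = np.empty((pm.n_nodes, steps + 1))
    out[:, 0] = phi
    for s in range(steps):
        phi = phi + dt * pm.velocity(phi, rotating_frame=rotating_frame)
        if not np.all(np.isfinite(phi)):
            raise FloatingPointError(f"non-finite phase at step {s + 1}")
        out[:, s + 1] = phi
    return PhaseTrace(t=np.arange(steps + 1) * dt, phi=out)


def order_parameter(phi, weights=None) -> tuple[float, float]:
    """Kuramoto order parameter: modulus R and angle Theta of the mean phasor."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("order parameter of an empty phase set")
    z = np.exp(1j * phi)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        z = (w * z).sum() / w.sum()
    else:
        z = z.mean()
    return float(np.abs(z)), float(np.angle(z))


@dataclass(frozen=True)
class KuramotoTransform:
    """Variable-shifted phase model with homogenized coupling magnitudes.

    ``model`` is the transformed :class:`PhaseModel` (coupling ``|K|``, all
    sign structure folded into the shift matrix, inhibitory phases shifted by
    the stationary two-cluster offset ``delta``); ``node_shift`` maps back:
    ``phi_original = psi + node_shift``.  ``asymmetry`` quantifies the spread
    of off-diagonal ``|K|`` (zero exactly for the homogeneous scheme under
    the equal-strength simplification).
    """

    model: PhaseModel
    node_shift: np.ndarray
    asymmetry: float

    def to_original(self, psi: np.ndarray) -> np.ndarray:
        return psi + self.node_shift[:, None] if psi.ndim == 2 else psi + self.node_shift

    def from_original(self, phi: np.ndarray) -> np.ndarray:
        return phi - self.node_shift[:, None] if phi.ndim == 2 else phi - self.node_shift


def kuramoto_transform(pm: PhaseModel, delta: float | None = None) -> KuramotoTransform:
    """Map the E/I phase model onto a homogeneously coupled Kuramoto-type form.

    The coupling of the averaged model is sign-structured by source type
    (``-cos`` from excitatory, ``+cos`` from inhibitory sources).  Two exact
    rewrites remove that structure: ``-cos x = cos(x - pi)`` folds every
    negative entry into an extra ``pi`` shift, and shifting all inhibitory
    phases by the stationary E-I offset ``delta`` (from the two-cluster
    condition; fallback ``-pi/2``, the isolated-pair lag) makes the
    synchronized cluster state read as full synchrony of the new variables.
    Both are changes of variables, so trajectories map back exactly.  The
    validity report is the relative spread of off-diagonal ``|K|``: zero iff
    the magnitudes are fully homogeneous.
    """
    if delta is None:
        import logging

        from .stationary_clusters import compute_constants, solve_two_cluster

        # class-mean pooling is intended here even for jittered models, so
        # the inhomogeneity warning of compute_constants is suppressed
        cluster_logger = logging.getLogger("neuromass.stationary_clusters")
        prev = cluster_logger.level
        cluster_logger.setLevel(logging.ERROR)
        try:
            cc = compute_constants(pm)
            sol = solve_two_cluster(cc, float(np.mean(pm.shifts)))
        finally:
            cluster_logger.setLevel(prev)
        delta = sol.deltas[0] if sol.found else -np.pi / 2.0

    n = pm.n_nodes
    s = np.zeros(n)
    s[pm.i_indices] = delta

    K_new = np.abs(pm.K)
    sign_shift = np.where(pm.K < 0, np.pi, 0.0)
    # cos(phi_m - phi_n - beta) with phi = psi + s becomes
    # cos(psi_m - psi_n - (beta - s_m + s_n)); negative K adds pi to beta.
    shifts_new = wrap_phase(pm.shifts + sign_shift - s[None, :] + s[:, None])
    shifts_new = np.where(K_new == 0, 0.0, shifts_new)

    off = ~np.eye(n, dtype=bool)
    mags = K_new[off]
    mean_mag = mags.mean() if mags.size else 0.0
    asym = float(mags.std() / mean_mag) if mean_mag > 0 else 0.0

    model = PhaseModel(
        omega=pm.omega.copy(), K=K_new, shifts=shifts_new, Omega=pm.Omega,
        amplitudes=pm.amplitudes.copy(), e_indices=pm.e_indices,
        i_indices=pm.i_indices, meta={**pm.meta, "transformed": True},
    )
    return KuramotoTransform(model=model, node_shift=s, asymmetry=asym)
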