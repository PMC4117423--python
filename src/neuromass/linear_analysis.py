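"""Linearization around the fixed point and delay-dependent frequency prediction.

Around the fixed point ``V*`` the deviations ``u = V - V*`` of the delayed
network obey (memoryless kernel)

    u_n'' + (a_n + b_n) u_n' + a_n b_n u_n = a_n b_n sum_m C_nm S'(V*_m) u_m(t - tau_nm)

For a single isolated E/I pair with shared rates ``a, b``, within-pair
strength ``c`` and equal delays ``tau``, the coupling matrix of the pair has
eigenvalues ``mu = ± i kappa`` with ``kappa = a b c sqrt(S'_E S'_I)``, and the
characteristic roots satisfy

    lambda^2 + (a + b) lambda + a b - mu e^(-lambda tau) = 0.

Expanding the delayed term to linear order in ``tau`` (the small-delay
approximation, valid for delays up to the order of one oscillation period)
turns this into the quadratic

    lambda^2 + (a + b + mu tau) lambda + (a b - mu) = 0,

whose closed-form roots this module exposes; the exact transcendental root,
located by complex Newton iteration seeded at the tau=0 root, serves as the
independent oracle.  The imaginary part of the unstable conjugate pair is the
predicted network frequency Omega(tau).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import CouplingMatrix
from .model_core import FixedPoint, NetworkParams, find_fixed_points, sigmoid_slope

__all__ = [
    "LinearSpectrum",
    "PairParams",
    "jacobian",
    "pair_eigenvalues_small_delay",
    "pair_characteristic_root",
    "predicted_frequency",
    "oscillatory_regime_check",
    "isolated_pair",
]


@dataclass(frozen=True)
class LinearSpectrum:
    """Eigenvalues of a linearized system at one delay value."""

    eigenvalues: np.ndarray
    delay: float

    @property
    def growth_rates(self) -> np.ndarray:
        return self.eigenvalues.real

    @property
    def frequencies(self) -> np.ndarray:
        return self.eigenvalues.imag

    def unstable_pair(self) -> complex | None:
        """The unstable conjugate pair with smallest |Im| (None if stable).

        When several pairs are unstable the lowest-frequency one is taken,
        matching the spectral-peak convention of the measurement pipeline.
        """
        lam = self.eigenvalues
        cand = lam[(lam.real > 0) & (lam.imag > 1e-12)]
        if cand.size == 0:
            return None
        return complex(cand[np.argmin(cand.imag)])


@dataclass(frozen=True)
class PairParams:
    """Reduced description of one E/I pair: shared rates and fixed-point slopes."""

    a: float
    b: float
    slope_e: float
    slope_i: float

    @property
    def kappa(self) -> float:
        """Coupling gain per unit within-pair strength: a*b*sqrt(S'_E S'_I)."""
        return self.a * self.b * np.sqrt(self.slope_e * self.slope_i)


def isolated_pair(net: NetworkParams, c: float) -> tuple[PairParams, FixedPoint]:
    """Fixed point and slope parameters of a single isolated E/I pair.

    ``net`` must describe one pair (2 nodes); the pair coupling is
    ``E <- I: -c``, ``I <- E: +c``.
    """
    if net.n_nodes != 2:
        raise ValueError("isolated_pair expects a 2-node network")
    e, i = int(net.e_indices[0]), int(net.i_indices[0])
    C = np.zeros((2, 2))
    C[e, i] = -c
    C[i, e] = c
    fp = find_fixed_points(C, net)
    slope_e = float(sigmoid_slope(fp.V_star[e], net.masses[e].sigmoid))
    slope_i = float(sigmoid_slope(fp.V_star[i], net.masses[i].sigmoid))
    me = net.masses[e]
    return PairParams(a=me.a, b=me.b, slope_e=slope_e, slope_i=slope_i), fp


def jacobian(C: CouplingMatrix, net: NetworkParams, fp: FixedPoint) -> np.ndarray:
    """Exact zero-delay Jacobian of the two-dimensional system at ``V*``.

    State ordering ``x = [V; W]`` gives the block form
    ``[[0, I], [a b (-I + C diag(S'(V*))), -(a + b) I]]``.
    """
    n = net.n_nodes
    if C.n_nodes != n or fp.V_star.shape != (n,):
        raise ValueError("dimension mismatch between coupling, network and fixed point")
    a, b = net.a_vec(), net.b_vec()
    slopes = np.array(
        [sigmoid_slope(fp.V_star[m], net.masses[m].sigmoid) for m in range(n)]
    )
    J = np.zeros((2 * n, 2 * n))
    J[:n, n:] = np.eye(n)
    J[n:, :n] = (a * b)[:, None] * (-np.eye(n) + C.entries * slopes[None, :])
    J[n:, n:] = -np.diag(a + b)
    return J


def _pair_quadratic_roots(pairp: PairParams, c: float, tau: float) -> np.ndarray:
    """Roots of lambda^2 + (a+b+mu*tau) lambda + (ab - mu) = 0 for mu = ±i kappa."""
    a, b = pairp.a, pairp.b
    kappa = pairp.kappa * c
    roots = []
    for mu in (1j * kappa, -1j * kappa):
        p = a + b + mu * tau
        disc = p * p - 4.0 * (a * b - mu)
        sq = np.sqrt(disc)
        roots.extend([(-p + sq) / 2.0, (-p - sq) / 2.0])
    return np.array(roots)


def pair_eigenvalues_small_delay(
    pairp: PairParams, c: float, tau: float
) -> LinearSpectrum:
    """Closed-form small-delay eigenvalues of one E/I pair.

    Valid for ``tau`` small against the oscillation period; a warning regime
    beyond half a period is the caller's responsibility (see
    :func:`predicted_frequency`, which truncates its grid).
    """
    if c < 0:
        raise ValueError("within-pair strength must be non-negative")
    if tau < 0:
        raise ValueError("delay must be non-negative")
    lam = _pair_quadratic_roots(pairp, c, tau)
    if not np.all(np.isfinite(lam)):
        raise FloatingPointError("eigenvalue expressions undefined for these parameters")
    return LinearSpectrum(eigenvalues=lam, delay=tau)


def pair_characteristic_root(
    pairp: PairParams,
    c: float,
    tau: float,
    *,
    branch: complex | None = None,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> complex:
    """Exact root of the delayed characteristic equation (oracle).

    Solves ``lambda^2 + (a+b) lambda + ab - mu e^(-lambda tau) = 0`` with
    ``mu = i kappa`` by complex Newton iteration seeded at ``branch`` (default:
    the unstable small-delay root at the same tau, falling back to tau=0).
    """
    a, b = pairp.a, pairp.b
    mu = 1j * pairp.kappa * c
    if branch is None:
        sd = pair_eigenvalues_small_delay(pairp, c, tau).unstable_pair()
        if sd is None:
            sd = pair_eigenvalues_small_delay(pairp, c, 0.0).eigenvalues[0]
        branch = sd
    lam = complex(branch)
    for _ in range(max_iter):
        f = lam * lam + (a + b) * lam + a * b - mu * np.exp(-lam * tau)
        fp = 2.0 * lam + (a + b) + tau * mu * np.exp(-lam * tau)
        step = f / fp
        lam -= step
        if abs(step) < tol * max(1.0, abs(lam)):
            return lam
    raise RuntimeError("complex Newton iteration did not converge")


def predicted_frequency(
    pairp: PairParams,
    c: float,
    tau_grid: np.ndarray,
    *,
    method: str = "small_delay",
) -> dict:
    """Frequency curve Omega(tau) of the unstable pair along a delay grid.

    Returns ``tau``, ``Omega`` (rad/s), ``period`` (s) and the eigenvalue per
    grid point; the grid is truncated (with the boundary recorded) if the
    oscillatory regime is lost along it.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    taus, lams = [], []
    boundary = None
    for tau in tau_grid:
        if method == "small_delay":
            lam = pair_eigenvalues_small_delay(pairp, c, tau).unstable_pair()
        elif method == "exact":
            lam = pair_characteristic_root(pairp, c, tau)
            if lam.real <= 0 or abs(lam.imag) < 1e-12:
                lam = None
        else:
            raise ValueError("method must be 'small_delay' or 'exact'")
        if lam is None:
            boundary = float(tau)
            break
        taus.append(tau)
        lams.append(lam)
    lams = np.array(lams)
    omega = np.abs(lams.imag)
    return {
        "tau": np.array(taus),
        "Omega": omega,
        "period": 2.0 * np.pi / omega,
        "eigenvalues": lams,
        "truncated_at": boundary,
    }


def oscillatory_regime_check(C: CouplingMatrix, net: NetworkParams) -> dict:
    """True iff the zero-delay Jacobian has a conjugate pair with Re>0, Im!=0.

    Reports (never raises for valid inputs) the offending pairs when the
    check fails, and the leading unstable eigenvalue when it succeeds.
    """
    fp = find_fixed_points(C, net)
    lam = np.linalg.eigvals(jacobian(C, net, fp))
    unstable = lam[(lam.real > 0) & (np.abs(lam.imag) > 1e-9)]
    ok = unstable.size > 0
    report = {
        "oscillatory": ok,
        "eigenvalues": lam,
        "leading": complex(unstable[np.argmax(unstable.real)]) if ok else None,
    }
    if not ok:
        report["max_real_part"] = float(lam.real.max())
    return report
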