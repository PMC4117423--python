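"""Stationary clustered solutions of the phase-density continuity equation.

For a countable network the zero-noise phase density is a sum of delta
clusters; a configuration is stationary when the drift (the bracketed
right-hand side of the continuity equation, i.e. every node's phase velocity
in the co-rotating frame) vanishes identically.  For the homogeneous coupling
scheme the drift of any node depends only on its class (E/I), the class-wise
pooled coupling constants, and the centroid phase differences — which turns
stationarity into a small set of constraining equations for the generalized
centroid differences ``Delta_kl``.

For two clusters (all E in one, all I in the other) with a common shift
``beta`` the condition reads

    (n-1)(q_EE - q_II) cos(beta)
      + Q_EI cos(Delta - beta) - Q_IE cos(Delta + beta) = omega_I - omega_E

with ``Q_ts`` the aggregated cross-class couplings (between-pair plus the
within-pair partner term); a bounded root search in ``Delta`` decides
existence.  The generalized ``M``-cluster system is solved by damped
multivariate root-finding with random restarts.  Every returned solution is
re-verified by the independent drift evaluation on the full phase model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .phase_reduction import PhaseModel, wrap_phase

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterConstants",
    "ClusterSolution",
    "compute_constants",
    "drift",
    "solve_two_cluster",
    "solve_m_clusters",
    "classify_stability",
    "default_memberships",
]


@dataclass(frozen=True)
class ClusterConstants:
    """Class-pooled coupling constants of a homogeneous-scheme phase model.

    ``q_ts`` is the mean single-edge between-pair coupling from source class
    ``s`` into a target of class ``t``; ``c_ts`` the mean within-pair
    (partner) coupling.  ``solvable_two_cluster`` records whether the
    two-cluster stationarity condition admits a root at the pooled shift.
    """

    n_pairs: int
    omega_e: float
    omega_i: float
    q_ee: float
    q_ei: float
    q_ie: float
    q_ii: float
    c_ei: float
    c_ie: float
    beta: float
    solvable_two_cluster: bool
    pm: PhaseModel = field(repr=False)

    def aggregated(self) -> dict:
        n = self.n_pairs
        return {
            "A_ee": (n - 1) * self.q_ee,
            "A_ii": (n - 1) * self.q_ii,
            "Q_ei": (n - 1) * self.q_ei + self.c_ei,
            "Q_ie": (n - 1) * self.q_ie + self.c_ie,
        }


@dataclass(frozen=True)
class ClusterSolution:
    """Centroid differences of a stationary clustered configuration."""

    M: int
    deltas: np.ndarray          # centroid phases relative to the first E cluster
    memberships: np.ndarray     # node count per cluster
    residual: float
    found: bool
    phases: np.ndarray | None = None   # a realized full configuration (gauge phi_E1 = 0)

    def delta_matrix(self) -> np.ndarray:
        """Antisymmetric generalized differences Delta_kl = centroid_k - centroid_l."""
        cen = np.concatenate([[0.0], np.atleast_1d(self.deltas)])[: self.M]
        return wrap_phase(cen[:, None] - cen[None, :])


def _pairs(pm: PhaseModel) -> tuple[np.ndarray, np.ndarray]:
    # blocked layout: pair j = (e_indices[j], i_indices[j])
    return pm.e_indices, pm.i_indices


def compute_constants(pm: PhaseModel) -> ClusterConstants:
    """Pool the effective coupling of a homogeneous scheme into class constants.

    Warns (but proceeds with means) when the model is not exactly homogeneous.
    """
    e_idx, i_idx = _pairs(pm)
    n = len(e_idx)
    K = pm.K

    def block(rows, cols, exclude_pair: bool):
        sub = K[np.ix_(rows, cols)]
        if exclude_pair:
            mask = ~np.eye(n, dtype=bool)
            vals = sub[mask]
        else:
            vals = np.diag(sub)
        return float(vals.mean()) if vals.size else 0.0, float(vals.std()) if vals.size else 0.0

    q_ee, s1 = block(e_idx, e_idx, True)
    q_ii, s2 = block(i_idx, i_idx, True)
    q_ei, s3 = block(e_idx, i_idx, True)
    q_ie, s4 = block(i_idx, e_idx, True)
    c_ei, s5 = block(e_idx, i_idx, False)
    c_ie, s6 = block(i_idx, e_idx, False)
    spread = max(s1, s2, s3, s4, s5, s6)
    scale = max(abs(c_ei), abs(c_ie), 1e-300)
    if spread > 1e-6 * scale:
        logger.warning(
            "phase model is not exactly homogeneous (coupling spread %.3g); "
            "cluster constants use class means", spread,
        )
    off = ~np.eye(2 * n, dtype=bool)
    beta = float(pm.shifts[off].mean()) if n > 0 else 0.0
    omega_e = float(pm.omega[e_idx].mean())
    omega_i = float(pm.omega[i_idx].mean())

    cc = ClusterConstants(
        n_pairs=n, omega_e=omega_e, omega_i=omega_i,
        q_ee=q_ee, q_ei=q_ei, q_ie=q_ie, q_ii=q_ii,
        c_ei=c_ei, c_ie=c_ie, beta=beta,
        solvable_two_cluster=False, pm=pm,
    )
    solvable = _two_cluster_condition_has_root(cc, beta)
    object.__setattr__(cc, "solvable_two_cluster", solvable)
    return cc


def _two_cluster_f(cc: ClusterConstants, beta: float):
    agg = cc.aggregated()

    def f(delta: float) -> float:
        v_e = cc.omega_e + agg["A_ee"] * np.cos(beta) + agg["Q_ei"] * np.cos(delta - beta)
        v_i = cc.omega_i + agg["A_ii"] * np.cos(beta) + agg["Q_ie"] * np.cos(delta + beta)
        return v_e - v_i

    return f


def _two_cluster_condition_has_root(cc: ClusterConstants, beta: float) -> bool:
    f = _two_cluster_f(cc, beta)
    grid = np.linspace(-np.pi, np.pi, 721)
    vals = np.array([f(d) for d in grid])
    return bool(np.any(vals[:-1] * vals[1:] <= 0))


def drift(phases: np.ndarray, pm: PhaseModel, frame: float | None = None) -> np.ndarray:
    """Per-node drift: instantaneous phase velocity minus the rotating frame.

    ``frame`` defaults to the mean velocity over nodes, so a configuration is
    stationary (all nodes co-rotate) iff the drift vanishes.  This is the
    verifier code path, deliberately independent of the pooled-constant
    solvers.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.shape != (pm.n_nodes,):
        raise ValueError("phase configuration length must equal n_nodes")
    v = pm.velocity(phases)
    if frame is None:
        frame = float(v.mean())
    return v - frame


def _realize(pm: PhaseModel, e_cent, i_cent, e_ids, i_ids) -> np.ndarray:
    phases = np.zeros(pm.n_nodes)
    e_idx, i_idx = _pairs(pm)
    phases[e_idx] = np.asarray(e_cent)[np.asarray(e_ids)]
    phases[i_idx] = np.asarray(i_cent)[np.asarray(i_ids)]
    return phases


def solve_two_cluster(cc: ClusterConstants, shift: float) -> ClusterSolution:
    """Stationary two-cluster state: all E at one centroid, all I at another.

    Solves the scalar condition by bracketed root-finding in
    ``Delta = phi_I - phi_E`` over ``(-pi, pi]``.  A missing root is a valid
    "no stationary two-cluster state" outcome (``found=False``), not an
    exception.  The returned ``Delta`` is re-verified through :func:`drift`.
    """
    f = _two_cluster_f(cc, shift)
    grid = np.linspace(-np.pi, np.pi, 721)
    vals = np.array([f(d) for d in grid])
    roots = []
    for lo, hi, vlo, vhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if vlo == 0.0:
            roots.append(float(lo))
        elif vlo * vhi < 0:
            roots.append(float(optimize.brentq(f, lo, hi, xtol=1e-14)))
    n = cc.n_pairs
    if not roots:
        return ClusterSolution(
            M=2, deltas=np.array([]), memberships=np.array([n, n]),
            residual=np.inf, found=False,
        )
    # prefer the E-leading root (the isolated-pair eigenmode has I lagging E)
    roots = sorted(roots, key=lambda d: (d > 0, abs(abs(d) - np.pi / 2)))
    delta = roots[0]
    e_idx, i_idx = _pairs(cc.pm)
    phases = np.zeros(cc.pm.n_nodes)
    phases[i_idx] = delta
    resid = float(np.max(np.abs(drift(phases, cc.pm))))
    return ClusterSolution(
        M=2, deltas=np.array([delta]), memberships=np.array([n, n]),
        residual=resid, found=True, phases=phases,
    )


def default_memberships(M: int, n_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    """Pair-respecting cluster assignment for M clusters.

    Pairs are split into ``G = ceil(M / 2)`` groups; each group's E nodes
    form one cluster and its I nodes another (``M = 2G``).  For odd ``M`` the
    inhibitory clusters of the last two groups are merged.
    """
    if M < 2 or M > 2 * n_pairs:
        raise ValueError("need 2 <= M <= 2 * n_pairs")
    G = (M + 1) // 2
    if n_pairs < G:
        raise ValueError("not enough pairs for the requested cluster count")
    e_ids = np.array_split(np.arange(n_pairs), G)
    e_assign = np.empty(n_pairs, dtype=int)
    for g, idx in enumerate(e_ids):
        e_assign[idx] = g
    i_assign = e_assign.copy()
    if M % 2:
        i_assign[i_assign == G - 1] = G - 2
    return e_assign, i_assign


def _membership_counts(assign: np.ndarray) -> np.ndarray:
    return np.bincount(assign)


def solve_m_clusters(
    M: int,
    cc: ClusterConstants,
    shifts: float | None = None,
    memberships: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
    n_restarts: int = 32,
    tol: float = 1e-12,
) -> ClusterSolution:
    """Stationary M-cluster state of the homogeneous scheme.

    ``memberships`` assigns each pair an (E-cluster, I-cluster) id; empty
    clusters are rejected.  The constraining equations (equal drift for every
    distinct membership combination) are solved by damped least-squares
    root-finding over the independent centroid differences with random
    restarts; the result is verified via :func:`drift`.  ``M = 2`` with the
    default membership reduces to :func:`solve_two_cluster`.
    """
    n = cc.n_pairs
    beta = cc.beta if shifts is None else float(shifts)
    if memberships is None:
        memberships = default_memberships(M, n)
    e_assign, i_assign = (np.asarray(a, dtype=int) for a in memberships)
    nEc = int(e_assign.max()) + 1
    nIc = int(i_assign.max()) + 1
    cnt_e = _membership_counts(e_assign)
    cnt_i = _membership_counts(i_assign)
    if np.any(cnt_e == 0) or np.any(cnt_i == 0):
        raise ValueError("empty cluster in membership assignment")
    if nEc + nIc != M:
        raise ValueError(f"memberships define {nEc + nIc} clusters, not M = {M}")

    combos = sorted({(int(e_assign[j]), int(i_assign[j])) for j in range(n)})

    def unpack(z):
        x_e = np.concatenate([[0.0], z[: nEc - 1]])
        x_i = z[nEc - 1 : nEc - 1 + nIc]
        nu = z[-1]
        return x_e, x_i, nu

    def combo_velocities(x_e, x_i):
        out = []
        for (p, q) in combos:
            v_e = cc.omega_e
            for p2 in range(nEc):
                cnt = cnt_e[p2] - (1 if p2 == p else 0)
                v_e += cnt * cc.q_ee * np.cos(x_e[p2] - x_e[p] - beta)
            for q2 in range(nIc):
                v_e += cnt_i[q2] * cc.q_ei * np.cos(x_i[q2] - x_e[p] - beta)
            v_e += (cc.c_ei - cc.q_ei) * np.cos(x_i[q] - x_e[p] - beta)
            v_i = cc.omega_i
            for q2 in range(nIc):
                cnt = cnt_i[q2] - (1 if q2 == q else 0)
                v_i += cnt * cc.q_ii * np.cos(x_i[q2] - x_i[q] - beta)
            for p2 in range(nEc):
                v_i += cnt_e[p2] * cc.q_ie * np.cos(x_e[p2] - x_i[q] - beta)
            v_i += (cc.c_ie - cc.q_ie) * np.cos(x_e[p] - x_i[q] - beta)
            out.extend([v_e, v_i])
        return np.array(out)

    def residuals(z):
        x_e, x_i, nu = unpack(z)
        return combo_velocities(x_e, x_i) - nu

    rng = np.random.default_rng(seed)
    n_unknowns = (nEc - 1) + nIc + 1
    best = None
    log = []
    for attempt in range(n_restarts):
        if attempt == 0:
            z0 = np.zeros(n_unknowns)
            z0[nEc - 1 : nEc - 1 + nIc] = -np.pi / 2
            z0[-1] = cc.omega_e
        else:
            z0 = np.concatenate(
                [rng.uniform(-np.pi, np.pi, n_unknowns - 1), [cc.omega_e]]
            )
        sol = optimize.least_squares(residuals, z0, method="lm", xtol=1e-15, ftol=1e-15)
        res = float(np.max(np.abs(sol.fun)))
        log.append(res)
        if best is None or res < best[0]:
            best = (res, sol.x)
        if res < tol:
            break

    res, z = best
    x_e, x_i, nu = unpack(z)
    phases = _realize(cc.pm, x_e, x_i, e_assign, i_assign)
    drift_res = float(np.max(np.abs(drift(phases, cc.pm))))
    found = res < max(tol, 1e-9)
    if not found:
        logger.info("M=%d cluster search failed; restart residuals: %s", M, log)
    centroids = np.concatenate([x_e, x_i])
    deltas = wrap_phase(centroids[1:] - centroids[0])
    member_counts = np.concatenate([cnt_e, cnt_i])
    return ClusterSolution(
        M=M, deltas=deltas, memberships=member_counts,
        residual=drift_res if found else res, found=found, phases=phases,
    )


def classify_stability(sol: ClusterSolution, pm: PhaseModel) -> dict:
    """Numerical stability of a verified clustered configuration.

    Sign of the leading eigenvalue of the phase-dynamics Jacobian at the
    configuration, excluding the global-rotation zero mode.
    """
    if sol.phases is None:
        raise ValueError("solution carries no realized configuration")
    phi = sol.phases
    diff = phi[None, :] - phi[:, None] - pm.shifts  # diff[n, m] = phi_m - phi_n - beta_nm
    S = pm.K * np.sin(diff)
    J = -S
    np.fill_diagonal(J, 0.0)
    np.fill_diagonal(J, S.sum(axis=1) - np.diag(S))
    lam = np.linalg.eigvals(J)
    zero_mode = int(np.argmin(np.abs(lam)))
    rest = np.delete(lam, zero_mode)
    leading = rest[np.argmax(rest.real)]
    return {
        "stable": bool(leading.real < 1e-8),
        "leading_exponent": complex(leading),
        "zero_mode": complex(lam[zero_mode]),
        "eigenvalues": lam,
    }
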