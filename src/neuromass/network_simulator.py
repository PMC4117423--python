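"""Fixed-step Euler-forward integration of the delayed neural-mass network.

The two-dimensional form per node is

    V_n' = W_n
    W_n' = a_n b_n (P_n + sum_m C_nm z_nm(t) - V_n) - (a_n + b_n) W_n

where ``z_nm(t)`` is the synaptically filtered, delayed source activity.  In
the memoryless-kernel limit ``z_nm(t) = S(V_m(t - tau_nm))``; for a finite
kernel rate gamma an auxiliary first-order state ``u_m`` with
``u_m' = gamma (S(V_m) - u_m)`` is integrated per source and read delayed
(the exponential kernel commutes with the delay).  Delayed values are served
from a per-edge ring buffer with delays rounded to integer multiples of the
step; the pre-history is clamped to the initial condition.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from math import erf

import numpy as np
from numba import njit
from scipy.special import ndtr

from .connectivity import CouplingMatrix, DelayMatrix
from .model_core import NetworkParams

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationTrace",
    "TrialEnsemble",
    "SimulationDivergence",
    "simulate",
    "simulate_ensemble",
]


class SimulationDivergence(RuntimeError):
    """Trajectory exceeded the divergence bound; carries node and time."""

    def __init__(self, node: int, time: float):
        self.node = node
        self.time = time
        super().__init__(f"divergence at node {node}, t = {time:.6f} s")


@dataclass(frozen=True)
class SimulationTrace:
    """Uniformly sampled membrane potentials ``V`` and derivatives ``W``."""

    t: np.ndarray
    V: np.ndarray
    W: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.meta["dt"])

    @property
    def n_nodes(self) -> int:
        return self.V.shape[0]

    def window_slice(self, window: tuple[float, float]) -> slice:
        i0 = int(np.searchsorted(self.t, window[0]))
        i1 = int(np.searchsorted(self.t, window[1], side="right"))
        return slice(i0, i1)


@dataclass(frozen=True)
class TrialEnsemble:
    """Traces sharing parameters and grid, differing in initial conditions."""

    traces: tuple[SimulationTrace, ...]

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("ensemble must contain at least one trace")
        ref = self.traces[0].meta
        for tr in self.traces[1:]:
            for key in ("dt", "duration", "param_digest"):
                if tr.meta.get(key) != ref.get(key):
                    raise ValueError(f"ensemble members disagree on {key}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)


@njit(cache=True)
def _euler_delay_loop(
    V, W, u, a, b, P, C, lag, buf, scale, mu, sd, steps, dt, gamma, memoryless, bound,
):  # pragma: no cover - exercised via simulate()
    """Integrate `steps` Euler steps, recording into V, W (n x steps+1).

    Returns (steps_taken, diverged_node); diverged_node is -1 on success.
    """
    n = V.shape[0]
    H = buf.shape[1]
    inv_sqrt2 = 0.7071067811865476
    for step in range(steps):
        ptr = step % H
        nxt = (ptr + 1) % H
        for i in range(n):
            acc = 0.0
            for m in range(n):
                cim = C[i, m]
                if cim != 0.0:
                    idx = ptr - lag[i, m]
                    if idx < 0:
                        idx += H
                    acc += cim * buf[m, idx]
            vi = V[i, step]
            wi = W[i, step]
            V[i, step + 1] = vi + dt * wi
            W[i, step + 1] = wi + dt * (
                a[i] * b[i] * (P[i] + acc - vi) - (a[i] + b[i]) * wi
            )
        for i in range(n):
            vi = V[i, step + 1]
            if abs(vi) > bound:
                return step + 1, i
            z = (vi - mu[i]) / sd[i]
            s = scale[i] * 0.5 * (1.0 + erf(z * inv_sqrt2))
            if memoryless:
                u[i] = s
            else:
                u[i] = u[i] + dt * gamma * (s - u[i])
            buf[i, nxt] = u[i]
    return steps, -1


def _param_digest(C: CouplingMatrix, D: DelayMatrix, net: NetworkParams) -> str:
    h = hashlib.sha256()
    h.update(C.entries.tobytes())
    h.update(D.entries.tobytes())
    for m in net.masses:
        h.update(
            np.array(
                [m.a, m.b, m.P, m.sigmoid.scale, m.sigmoid.threshold_mean,
                 m.sigmoid.threshold_sd]
            ).tobytes()
        )
        h.update(m.node_type.encode())
    h.update(np.array([net.kernel_rate if np.isfinite(net.kernel_rate) else -1.0]).tobytes())
    return h.hexdigest()[:16]


def _draw_initial(net: NetworkParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # potentials uniformly around the sigmoid threshold region, derivatives at rest
    mu = np.array([m.sigmoid.threshold_mean for m in net.masses])
    V0 = mu + rng.uniform(-1.0, 1.0, size=net.n_nodes)
    W0 = np.zeros(net.n_nodes)
    return V0, W0


def simulate(
    C: CouplingMatrix,
    D: DelayMatrix,
    net: NetworkParams,
    duration: float,
    dt: float = 1e-4,
    *,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
    divergence_bound: float | None = None,
) -> SimulationTrace:
    """Euler-forward trajectory of the delayed network.

    ``init`` overrides the random initial condition (a ``(V0, W0)`` tuple);
    otherwise ``V0 ~ threshold + U(-1, 1)``, ``W0 = 0``, drawn from ``seed``.
    The pre-``t0`` history is clamped to the initial condition.  Delays are
    rounded to integer multiples of ``dt`` (a warning is logged when the
    rounding error exceeds 1% of the delay); ``dt`` must not exceed the
    smallest positive delay.
    """
    n = net.n_nodes
    if C.n_nodes != n or D.n_nodes != n:
        raise ValueError("coupling/delay/network sizes disagree")
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    min_delay = D.min_positive()
    if min_delay and dt > min_delay + 1e-15:
        raise ValueError(f"dt = {dt} exceeds the smallest positive delay {min_delay}")

    lag = np.rint(D.entries / dt).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_err = np.abs(lag * dt - D.entries) / np.where(D.entries > 0, D.entries, np.inf)
    if np.any(rel_err > 0.01):
        logger.warning(
            "delay rounding error exceeds 1%% of tau for %d entries", int((rel_err > 0.01).sum())
        )

    rng = np.random.default_rng(seed)
    if init is None:
        V0, W0 = _draw_initial(net, rng)
    else:
        V0, W0 = (np.asarray(x, dtype=float).copy() for x in init)
        if V0.shape != (n,) or W0.shape != (n,):
            raise ValueError("init arrays must have shape (n_nodes,)")

    a, b, P = net.a_vec(), net.b_vec(), net.P_vec()
    scale = np.array([m.sigmoid.scale for m in net.masses])
    mu = np.array([m.sigmoid.threshold_mean for m in net.masses])
    sd = np.array([m.sigmoid.threshold_sd for m in net.masses])
    if divergence_bound is None:
        divergence_bound = 1e3 * max(float(np.max(np.abs(P))), 1.0)

    steps = int(round(duration / dt))
    H = int(lag.max()) + 1
    memoryless = not np.isfinite(net.kernel_rate)
    gamma = float(net.kernel_rate) if not memoryless else 0.0

    s0 = scale * ndtr((V0 - mu) / sd)
    buf = np.tile(s0[:, None], (1, H))  # history clamped to the initial condition
    u = s0.copy()

    V = np.empty((n, steps + 1))
    W = np.empty((n, steps + 1))
    V[:, 0], W[:, 0] = V0, W0

    taken, bad = _euler_delay_loop(
        V, W, u, a, b, P, np.ascontiguousarray(C.entries), lag, buf,
        scale, mu, sd, steps, dt, gamma, memoryless, divergence_bound,
    )
    if bad >= 0:
        raise SimulationDivergence(bad, taken * dt)

    t = np.arange(steps + 1) * dt
    meta = {
        "dt": dt,
        "duration": duration,
        "seed": seed,
        "param_digest": _param_digest(C, D, net),
        "scheme": C.scheme_tag,
    }
    return SimulationTrace(t=t, V=V, W=W, meta=meta)


def simulate_ensemble(
    C: CouplingMatrix,
    D: DelayMatrix,
    net: NetworkParams,
    duration: float,
    dt: float = 1e-4,
    *,
    n_trials: int = 1,
    base_seed: int = 0,
    divergence_bound: float | None = None,
) -> TrialEnsemble:
    """Trial ensemble with fixed parameters and varying initial conditions.

    Trial ``i`` draws its initial condition from seed ``base_seed + i``.
    Diverging trials are excluded (logged); more than 10% divergence is a
    hard failure.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    traces, failures = [], 0
    for i in range(n_trials):
        try:
            traces.append(
                simulate(
                    C, D, net, duration, dt,
                    seed=base_seed + i, divergence_bound=divergence_bound,
                )
            )
        except SimulationDivergence as exc:
            failures += 1
            logger.warning("trial %d diverged: %s", i, exc)
    if failures > 0.1 * n_trials or not traces:
        raise RuntimeError(f"{failures}/{n_trials} trials diverged")
    return TrialEnsemble(traces=tuple(traces))
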