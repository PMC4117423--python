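"""Parameter containers, sigmoidal activation and fixed points of coupled neural masses.

The node model is a Freeman-type neural mass: the mean membrane potential
``V_n`` of population ``n`` obeys a driven second-order dynamics

    (d/dt + a_n)(d/dt + b_n) V_n / (a_n b_n) = P_n + sum_m C_nm (g * S(V_m(t - tau_nm)))

where ``a_n`` and ``b_n`` are the mean rise and decay rates of the population
response, ``P_n`` a constant external input, ``S`` a sigmoidal activation
(the normal CDF scaled to a maximum firing rate), ``g`` an exponentially
decaying synaptic kernel and ``C_nm`` the structural coupling from source
``m`` into target ``n``.  This module holds the parameter containers, the
activation function and the stationary (fixed-point) solver; delays never
enter the fixed point because the delayed argument equals the stationary
value itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "SigmoidParams",
    "MassParams",
    "NetworkParams",
    "FixedPoint",
    "sigmoid",
    "sigmoid_slope",
    "find_fixed_points",
    "FixedPointError",
]

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class SigmoidParams:
    """Normal-CDF activation: ``S(V) = scale * Phi((V - threshold_mean) / threshold_sd)``.

    ``threshold_mean``/``threshold_sd`` describe the distribution of firing
    thresholds across the population; ``scale`` is the maximum output.
    """

    scale: float = 1.0
    threshold_mean: float = 1.0
    threshold_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.threshold_sd > 0):
            raise ValueError("sigmoid scale and threshold_sd must be positive")


@dataclass(frozen=True)
class MassParams:
    """One neural mass: rise rate ``a`` (1/s), decay rate ``b`` (1/s), input ``P``."""

    a: float
    b: float
    P: float
    node_type: Literal["E", "I"]
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("rates a, b must be strictly positive")
        if self.node_type not in ("E", "I"):
            raise ValueError("node_type must be 'E' or 'I'")


# Defaults that place the linearized pair frequency in the fast (gamma) band
# and the homogeneous-network fixed point exactly at the sigmoid threshold
# (P_E - c*S(1) = 1 and P_I + c*S(1) = 1 for within-pair strength c = 10).
DEFAULT_A = 220.0
DEFAULT_B = 720.0
DEFAULT_P_E = 6.0
DEFAULT_P_I = -4.0


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of a network of E/I-paired masses.

    Nodes are ordered block-wise: excitatory masses ``0..n_pairs-1`` followed
    by their inhibitory partners ``n_pairs..2*n_pairs-1``; ``pairing`` maps
    each excitatory index to its partner.  ``param_jitter`` is the half-width
    of the mean-centered uniform jitter applied multiplicatively to ``a`` and
    ``b`` per pair (both members of a pair share the draw, so each pair has
    its own natural frequency).  ``kernel_rate`` is the synaptic kernel rate
    γ; ``inf`` selects the memoryless limit.
    """

    masses: tuple[MassParams, ...]
    pairing: dict[int, int]
    kernel_rate: float = np.inf
    param_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.masses)
        if n % 2:
            raise ValueError("network must contain an even number of masses")
        e_set = {i for i, m in enumerate(self.masses) if m.node_type == "E"}
        i_set = set(range(n)) - e_set
        if set(self.pairing) != e_set or set(self.pairing.values()) != i_set:
            raise ValueError("pairing must be a bijection between the E and I sets")

    @property
    def n_nodes(self) -> int:
        return len(self.masses)

    @property
    def e_indices(self) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.masses) if m.node_type == "E"])

    @property
    def i_indices(self) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.masses) if m.node_type == "I"])

    def a_vec(self) -> np.ndarray:
        return np.array([m.a for m in self.masses])

    def b_vec(self) -> np.ndarray:
        return np.array([m.b for m in self.masses])

    def P_vec(self) -> np.ndarray:
        return np.array([m.P for m in self.masses])

    @classmethod
    def paired(
        cls,
        n_pairs: int,
        *,
        a: float = DEFAULT_A,
        b: float = DEFAULT_B,
        P_e: float = DEFAULT_P_E,
        P_i: float = DEFAULT_P_I,
        sigmoid: SigmoidParams | None = None,
        kernel_rate: float = np.inf,
        param_jitter: float = 0.05,
        seed: int = 0,
    ) -> "NetworkParams":
        """Build ``n_pairs`` E/I pairs with per-pair jittered rates.

        Pair ``j`` consists of excitatory node ``j`` and inhibitory node
        ``n_pairs + j``.  Per pair, ``a`` and ``b`` are drawn from uniform
        distributions ``a*(1 ± param_jitter)`` and ``b*(1 ± param_jitter)``
        (independent draws for a and b, shared by both pair members), giving
        the pairs distributed natural frequencies.
        """
        if n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        sg = sigmoid if sigmoid is not None else SigmoidParams()
        rng = np.random.default_rng(seed)
        ja = a * (1.0 + param_jitter * rng.uniform(-1.0, 1.0, size=n_pairs))
        jb = b * (1.0 + param_jitter * rng.uniform(-1.0, 1.0, size=n_pairs))
        if np.any(ja <= 0) or np.any(jb <= 0):
            raise ValueError("jitter drove a rate non-positive")
        e_masses = [MassParams(ja[j], jb[j], P_e, "E", sg) for j in range(n_pairs)]
        i_masses = [MassParams(ja[j], jb[j], P_i, "I", sg) for j in range(n_pairs)]
        pairing = {j: n_pairs + j for j in range(n_pairs)}
        return cls(
            masses=tuple(e_masses + i_masses),
            pairing=pairing,
            kernel_rate=kernel_rate,
            param_jitter=param_jitter,
            seed=seed,
        )

    @classmethod
    def balanced(cls, n_pairs: int, c: float, **kwargs) -> "NetworkParams":
        """Pairs whose inputs balance the within-pair coupling at threshold.

        With within-pair strength ``c`` the inputs ``P_E = mu + c s/2`` and
        ``P_I = mu - c s/2`` (``mu``, ``s`` threshold mean and sigmoid scale)
        put the fixed point of every mass exactly at the sigmoid threshold,
        where the slope — and hence the oscillation gain — is maximal; for
        the homogeneous scheme the balanced E and I between-pair inputs
        cancel so this holds for the full network as well.
        """
        sg = kwargs.get("sigmoid") or SigmoidParams()
        half = c * sg.scale / 2.0
        kwargs.setdefault("P_e", sg.threshold_mean + half)
        kwargs.setdefault("P_i", sg.threshold_mean - half)
        return cls.paired(n_pairs, **kwargs)

    def with_inputs(self, P_e: float, P_i: float) -> "NetworkParams":
        masses = tuple(
            replace(m, P=P_e if m.node_type == "E" else P_i) for m in self.masses
        )
        return replace(self, masses=masses)


@dataclass(frozen=True)
class FixedPoint:
    """Stationary potentials ``V*`` with the achieved residual of ``V - P - C S(V)``."""

    V_star: np.ndarray
    residual: float


class FixedPointError(RuntimeError):
    """Raised when the stationary equation cannot be solved to tolerance."""


def _as_sigmoid_arrays(net: NetworkParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    scale = np.array([m.sigmoid.scale for m in net.masses])
    mu = np.array([m.sigmoid.threshold_mean for m in net.masses])
    sd = np.array([m.sigmoid.threshold_sd for m in net.masses])
    return scale, mu, sd


def sigmoid(V, p: SigmoidParams):
    """Sigmoidal activation, the scaled normal CDF of the firing thresholds.

    Strictly increasing with range ``(0, p.scale)``.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("sigmoid: non-finite membrane potential")
    return p.scale * ndtr((V - p.threshold_mean) / p.threshold_sd)


def sigmoid_slope(V, p: SigmoidParams):
    """Analytic derivative of :func:`sigmoid`; strictly positive everywhere."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("sigmoid_slope: non-finite membrane potential")
    z = (V - p.threshold_mean) / p.threshold_sd
    return p.scale * _INV_SQRT_2PI * np.exp(-0.5 * z * z) / p.threshold_sd


def _net_sigmoid(V: np.ndarray, net: NetworkParams) -> np.ndarray:
    scale, mu, sd = _as_sigmoid_arrays(net)
    return scale * ndtr((V - mu) / sd)


def _net_sigmoid_slope(V: np.ndarray, net: NetworkParams) -> np.ndarray:
    scale, mu, sd = _as_sigmoid_arrays(net)
    z = (V - mu) / sd
    return scale * _INV_SQRT_2PI * np.exp(-0.5 * z * z) / sd


def find_fixed_points(
    C,
    net: NetworkParams,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> FixedPoint:
    """Solve the stationary equation ``V* = P + C S(V*)``.

    Damped fixed-point iteration started at ``V = P`` with a Newton fallback;
    the residual decreases monotonically across accepted iterations.  The
    result is independent of any delay matrix by construction (stationarity
    makes the delayed argument equal to the value itself).

    ``C`` may be a :class:`~neuromass.connectivity.CouplingMatrix` or a plain
    square array.
    """
    entries = np.asarray(getattr(C, "entries", C), dtype=float)
    n = net.n_nodes
    if entries.shape != (n, n):
        raise ValueError(f"coupling matrix shape {entries.shape} != ({n}, {n})")
    if tol <= 0:
        raise ValueError("tol must be positive")

    P = net.P_vec()

    def resid(V: np.ndarray) -> np.ndarray:
        return V - P - entries @ _net_sigmoid(V, net)

    # Damped Newton with backtracking on ||r||_2, started at V = P.  The plain
    # stationary map V -> P + C S(V) is rotational for E/I coupling (complex
    # map eigenvalues), so undamped Picard iteration may diverge; the Newton
    # direction with a line search is robust and keeps the accepted residual
    # strictly decreasing.
    V = P.copy()
    r = resid(V)
    rn = float(np.linalg.norm(r))
    for _ in range(max_iter):
        if float(np.max(np.abs(r))) < tol:
            return FixedPoint(V_star=V, residual=float(np.max(np.abs(r))))
        J = np.eye(n) - entries * _net_sigmoid_slope(V, net)[None, :]
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step = -r  # damped Picard direction as fallback
        eta, accepted = 1.0, False
        while eta > 1e-10:
            V_new = V + eta * step
            r_new = resid(V_new)
            rn_new = float(np.linalg.norm(r_new))
            if np.isfinite(rn_new) and rn_new < rn:
                V, r, rn = V_new, r_new, rn_new
                accepted = True
                break
            eta *= 0.5
        if not accepted:
            raise FixedPointError(
                f"fixed-point solver stalled at residual {rn:.3e} "
                "(parameters may lie outside the regime where fixed points exist)"
            )
    if float(np.max(np.abs(r))) < tol:
        return FixedPoint(V_star=V, residual=float(np.max(np.abs(r))))
    raise FixedPointError(f"no convergence after {max_iter} iterations (residual {rn:.3e})")
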