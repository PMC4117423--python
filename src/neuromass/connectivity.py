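"""Builders and I/O for structural coupling, delay and binary connectome matrices.

Orientation convention: rows are targets, so ``C[n, m]`` couples source ``m``
into target ``n`` (the direction of the network summation).  Signs follow the
source node's type: columns of excitatory sources are non-negative, columns of
inhibitory sources non-positive.  Self-coupling is always zero.

Three schemes are provided:

* homogeneous -- fully connected E/I pairs; ``c`` within a pair, ``k``
  between pairs;
* inhomogeneous -- as homogeneous, but between-pair magnitudes drawn
  i.i.d. uniform on ``[k_mean - width, k_mean + width]``;
* anatomical -- a binary structural connectome wires the excitatory
  units only, each excitatory unit keeps a private inhibitory partner.

Between-pair entries are by default scaled by ``1/n_pairs`` so the total
input per node stays intensive as the network grows; pass
``normalize=False`` for raw strengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingMatrix",
    "DelayMatrix",
    "StructuralMatrix",
    "build_homogeneous",
    "build_inhomogeneous",
    "build_anatomical",
    "build_delays",
    "generate_synthetic_sc",
    "zero_pair_delays",
    "read_matrix",
    "write_matrix",
]


@dataclass(frozen=True)
class CouplingMatrix:
    """Dense structural coupling ``C`` with its E/I partition and scheme tag."""

    entries: np.ndarray
    e_indices: np.ndarray
    i_indices: np.ndarray
    scheme_tag: str = "custom"

    def __post_init__(self) -> None:
        C = np.asarray(self.entries, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("coupling matrix must be square")
        if np.any(np.diag(C) != 0.0):
            raise ValueError("self-coupling must be zero (zero diagonal)")
        if np.any(C[:, self.i_indices] > 0):
            raise ValueError("inhibitory-source columns must be non-positive")
        if np.any(C[:, self.e_indices] < 0):
            raise ValueError("excitatory-source columns must be non-negative")
        object.__setattr__(self, "entries", C)

    @property
    def n_nodes(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class DelayMatrix:
    """Non-negative transmission delays ``tau[n, m]`` in seconds, zero diagonal."""

    entries: np.ndarray
    distribution_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        D = np.asarray(self.entries, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("delay matrix must be square")
        if np.any(D < 0):
            raise ValueError("delays must be non-negative")
        if np.any(np.diag(D) != 0.0):
            raise ValueError("delay matrix must have zero diagonal")
        object.__setattr__(self, "entries", D)

    @property
    def n_nodes(self) -> int:
        return self.entries.shape[0]

    def min_positive(self) -> float:
        pos = self.entries[self.entries > 0]
        return float(pos.min()) if pos.size else 0.0

    @classmethod
    def zero(cls, n_nodes: int) -> "DelayMatrix":
        return cls(np.zeros((n_nodes, n_nodes)), {"mode": "constant", "tau0": 0.0})


@dataclass(frozen=True)
class StructuralMatrix:
    """Binary symmetric adjacency over anatomical areas."""

    adjacency: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("structural matrix must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("structural matrix must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("structural matrix must have zero diagonal")
        if not np.all(np.isin(A, (0, 1))):
            raise ValueError("structural matrix must be binary")
        object.__setattr__(self, "adjacency", A.astype(float))
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"area{i}" for i in range(A.shape[0]))
            )

    @property
    def n_areas(self) -> int:
        return self.adjacency.shape[0]


def _pair_partition(n_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    return np.arange(n_pairs), np.arange(n_pairs, 2 * n_pairs)


def _homogeneous_entries(n_pairs: int, c: float, k_between: np.ndarray) -> np.ndarray:
    """Assemble the block matrix [[E<-E, E<-I], [I<-E, I<-I]].

    ``k_between`` is an (N, N) matrix of between-pair magnitudes (only its
    off-pair entries are used); within-pair coupling is exactly ``±c``.
    """
    n = n_pairs
    off = 1.0 - np.eye(n)
    C = np.zeros((2 * n, 2 * n))
    C[:n, :n] = k_between[:n, :n] * off          # E <- E, + between
    C[n:, n:] = -k_between[n:, n:] * off         # I <- I, - between
    C[:n, n:] = -k_between[:n, n:] * off - c * np.eye(n)   # E <- I
    C[n:, :n] = k_between[n:, :n] * off + c * np.eye(n)    # I <- E
    return C


def build_homogeneous(
    n_pairs: int, c: float, k: float, *, normalize: bool = True
) -> CouplingMatrix:
    """Fully connected E/I pairs: ``±c`` within each pair, ``±k`` between pairs.

    Signs are set by the source type.  With ``normalize`` the between-pair
    strength is ``k / n_pairs``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if c < 0 or k < 0:
        raise ValueError("coupling strengths must be non-negative")
    k_eff = k / n_pairs if normalize else k
    N = 2 * n_pairs
    e_idx, i_idx = _pair_partition(n_pairs)
    C = _homogeneous_entries(n_pairs, c, np.full((N, N), k_eff))
    return CouplingMatrix(C, e_idx, i_idx, scheme_tag="homogeneous")


def build_inhomogeneous(
    n_pairs: int,
    c: float,
    k_mean: float,
    width: float,
    seed: int,
    *,
    normalize: bool = True,
) -> CouplingMatrix:
    """Homogeneous scheme with between-pair magnitudes ~ U[k_mean-width, k_mean+width].

    ``width <= k_mean`` keeps magnitudes non-negative so entry signs remain
    fully determined by the source type.  Within-pair entries stay exactly
    ``±c``.  Reproducible given ``seed``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if c < 0 or k_mean < 0:
        raise ValueError("coupling strengths must be non-negative")
    if width < 0 or width > k_mean:
        raise ValueError("width must satisfy 0 <= width <= k_mean (sign constraint)")
    N = 2 * n_pairs
    rng = np.random.default_rng(seed)
    mags = rng.uniform(k_mean - width, k_mean + width, size=(N, N))
    if normalize:
        mags = mags / n_pairs
    e_idx, i_idx = _pair_partition(n_pairs)
    C = _homogeneous_entries(n_pairs, c, mags)
    return CouplingMatrix(C, e_idx, i_idx, scheme_tag="inhomogeneous")


def build_anatomical(
    sc: StructuralMatrix,
    c: float,
    k: float,
    *,
    k_ii: float = 0.0,
    k_ei: float = 0.0,
    k_ie: float = 0.0,
    normalize: bool = True,
) -> CouplingMatrix:
    """Wire ``2 * n_areas`` masses: the connectome couples excitatory units only.

    The E<-E block is ``k * SC``; each excitatory unit is paired with one
    inhibitory unit at identity-structured ``±c``.  The remaining between-area
    blocks default to zero but are exposed as named strengths (``k_ii``,
    ``k_ei``, ``k_ie``) multiplying SC with source-type signs.  With
    ``normalize``, between-area strengths are divided by the mean degree of
    the connectome.
    """
    A = sc.n_areas
    if c < 0 or k < 0 or min(k_ii, k_ei, k_ie) < 0:
        raise ValueError("coupling strengths must be non-negative")
    deg = sc.adjacency.sum(axis=1).mean()
    scale = 1.0 / deg if (normalize and deg > 0) else 1.0
    S = sc.adjacency
    C = np.zeros((2 * A, 2 * A))
    C[:A, :A] = k * scale * S
    C[A:, A:] = -k_ii * scale * S
    C[:A, A:] = -k_ei * scale * S - c * np.eye(A)
    C[A:, :A] = k_ie * scale * S + c * np.eye(A)
    e_idx, i_idx = _pair_partition(A)
    return CouplingMatrix(C, e_idx, i_idx, scheme_tag="anatomical")


def build_delays(
    n_nodes: int,
    mode: str,
    tau0: float,
    width: float = 0.0,
    *,
    symmetric: bool = True,
    seed: int = 0,
) -> DelayMatrix:
    """Constant or uniformly distributed delay matrix (seconds).

    ``constant`` puts ``tau0`` on every off-diagonal entry; ``uniform`` draws
    i.i.d. from ``[tau0 - width, tau0 + width]``.  ``symmetric`` forces
    ``tau[n, m] == tau[m, n]`` (delays proportional to distance).
    """
    if tau0 < 0:
        raise ValueError("tau0 must be non-negative")
    if width < 0 or width > tau0:
        raise ValueError("width must satisfy 0 <= width <= tau0 (no negative delays)")
    if mode not in ("constant", "uniform"):
        raise ValueError("mode must be 'constant' or 'uniform'")
    if mode == "constant" or width == 0.0:
        D = np.full((n_nodes, n_nodes), tau0)
    else:
        rng = np.random.default_rng(seed)
        D = rng.uniform(tau0 - width, tau0 + width, size=(n_nodes, n_nodes))
        if symmetric:
            D = np.triu(D, 1)
            D = D + D.T
    np.fill_diagonal(D, 0.0)
    spec = {"mode": mode, "tau0": tau0, "width": width, "symmetric": symmetric, "seed": seed}
    return DelayMatrix(D, spec)


def zero_pair_delays(D: DelayMatrix, e_indices, i_indices) -> DelayMatrix:
    """Zero the within-pair (intra-areal) delay entries.

    Conduction delays scale with distance, and each E/I pair models one
    area, so the partner loop is effectively instantaneous while
    between-area connections carry the long delays.
    """
    e_idx = np.asarray(e_indices)
    i_idx = np.asarray(i_indices)
    entries = D.entries.copy()
    entries[e_idx, i_idx] = 0.0
    entries[i_idx, e_idx] = 0.0
    spec = {**D.distribution_spec, "pair_delays": "zeroed"}
    return DelayMatrix(entries, spec)


def generate_synthetic_sc(
    n_areas: int = 66,
    mean_degree: int = 8,
    rewiring: float = 0.1,
    seed: int = 0,
) -> StructuralMatrix:
    """Connected binary small-world (Watts-Strogatz) connectome.

    A stand-in for an empirical binary cortical connection matrix: ring
    lattice of degree ``mean_degree`` with edges rewired at probability
    ``rewiring``; disconnected draws are regenerated with an incremented
    sub-seed (logged).
    """
    if mean_degree % 2 or mean_degree >= n_areas:
        raise ValueError("mean_degree must be even and < n_areas")
    sub_seed = seed
    for _ in range(100):
        g = nx.watts_strogatz_graph(n_areas, mean_degree, rewiring, seed=sub_seed)
        if nx.is_connected(g):
            A = nx.to_numpy_array(g, dtype=float)
            return StructuralMatrix((A > 0).astype(int))
        logger.warning(
            "synthetic connectome disconnected at sub-seed %d; regenerating", sub_seed
        )
        sub_seed += 1
    raise RuntimeError("could not generate a connected connectome in 100 attempts")


_KINDS = {
    "coupling": CouplingMatrix,
    "delays": DelayMatrix,
    "sc": StructuralMatrix,
}


def write_matrix(obj, path) -> None:
    """Write a matrix object as whitespace-delimited text with a header line."""
    path = Path(path)
    if isinstance(obj, CouplingMatrix):
        kind = "coupling"
        header = (
            f"kind=coupling n={obj.n_nodes} scheme={obj.scheme_tag} "
            f"orientation=row-is-target "
            f"e_indices={','.join(map(str, obj.e_indices))}"
        )
        M = obj.entries
    elif isinstance(obj, DelayMatrix):
        kind = "delays"
        header = f"kind=delays n={obj.n_nodes} units=seconds orientation=row-is-target"
        M = obj.entries
    elif isinstance(obj, StructuralMatrix):
        kind = "sc"
        header = f"kind=sc n={obj.n_areas} binary=1"
        M = obj.adjacency
    else:
        raise TypeError(f"cannot write object of type {type(obj)!r}")
    fmt = "%d" if kind == "sc" else "%.17g"
    np.savetxt(path, M, fmt=fmt, delimiter="\t", header=header)


def _load_text_matrix(path: Path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split()
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(f"{path}: ragged row at line {ln}")
            try:
                row = [float(x) for x in cells]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell at line {ln}") from exc
            if not all(np.isfinite(row)):
                raise ValueError(f"{path}: non-finite value at line {ln}")
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    return np.array(rows)


def read_matrix(path, kind: str):
    """Read a text matrix file back as the requested kind.

    ``kind`` is one of ``coupling``, ``delays`` or ``sc``.  Coupling files
    restore the E/I partition from the header; files without one are rejected.
    """
    path = Path(path)
    if kind not in _KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    M = _load_text_matrix(path)
    if kind == "sc":
        return StructuralMatrix(M.astype(int) if np.all(np.isin(M, (0, 1))) else M)
    if kind == "delays":
        return DelayMatrix(M)
    header = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            header = first[1:].strip()
    fields = dict(kv.split("=", 1) for kv in header.split() if "=" in kv)
    if "e_indices" in fields:
        e_idx = np.array([int(x) for x in fields["e_indices"].split(",")])
    else:
        raise ValueError(f"{path}: coupling file lacks an e_indices header")
    i_idx = np.setdiff1d(np.arange(M.shape[0]), e_idx)
    return CouplingMatrix(M, e_idx, i_idx, scheme_tag=fields.get("scheme", "custom"))
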