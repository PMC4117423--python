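"""Phase-locking functional connectivity and structure-function correlation.

Functional connectivity between two nodes is their phase-locking value
(phase uniformity): the modulus of the time-averaged unit phasor of the
pairwise relative phase,

    rho_nm = | < exp(i (phi_n(t) - phi_m(t))) >_t |  in [0, 1].

Trial averaging of the rho matrices removes the spuriously high locking that
a shared oscillation frequency alone produces (relative phases are constant
within a trial even for uncoupled nodes; random initial conditions decorrelate
them across trials).  The structure-function correspondence is the Pearson
correlation between the strictly lower-triangular parts of the structural
adjacency and the functional matrix, avoiding the common diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import StructuralMatrix
from .phase_reduction import PhaseTrace

__all__ = [
    "SynchronyMatrix",
    "StructureFunctionReport",
    "plv_matrix",
    "average_plv",
    "overall_synchrony",
    "structure_function_correlation",
]


@dataclass(frozen=True)
class SynchronyMatrix:
    """Pairwise phase-locking values in [0, 1]; symmetric, unit diagonal.

    ``phasor`` optionally carries the complex mean phasor matrix
    ``G_nm = <exp(i (phi_n - phi_m))>`` behind ``rho = |G|``; trial averaging
    combines the phasors, so locking that stems from a shared frequency with
    trial-random offsets cancels out.
    """

    rho: np.ndarray
    averaged_over: int = 1
    subset: str = "all"
    phasor: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("rho must be square")
        if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
            raise ValueError("rho entries must lie in [0, 1]")
        object.__setattr__(self, "rho", np.clip(r, 0.0, 1.0))

    @property
    def n_nodes(self) -> int:
        return self.rho.shape[0]

    def restricted(self, subset_indices, tag: str = "subset") -> "SynchronyMatrix":
        idx = np.asarray(subset_indices)
        ph = self.phasor[np.ix_(idx, idx)] if self.phasor is not None else None
        return SynchronyMatrix(
            rho=self.rho[np.ix_(idx, idx)], averaged_over=self.averaged_over,
            subset=tag, phasor=ph,
        )


@dataclass(frozen=True)
class StructureFunctionReport:
    """One sweep point: structure-function r and overall synchrony."""

    pearson_r: float
    status: str  # "ok" | "undefined"
    overall_R: float | None = None
    meta: dict = field(default_factory=dict)


def _window_phases(phases: PhaseTrace, window: tuple[float, float], min_periods: float = 10.0):
    sl = np.searchsorted(phases.t, window[0]), np.searchsorted(phases.t, window[1], side="right")
    phi = phases.phi[:, sl[0] : sl[1]]
    if phi.shape[1] < 2:
        raise ValueError("window selects too few samples")
    # rough cycle count from the median phase advance
    adv = np.median(np.abs(phi[:, -1] - phi[:, 0])) / (2.0 * np.pi)
    return phi, adv


def plv_matrix(
    phases: PhaseTrace,
    window: tuple[float, float],
    *,
    min_periods: float = 10.0,
    subset: str = "all",
) -> SynchronyMatrix:
    """Pairwise phase-locking values over a time window.

    The window must span at least ``min_periods`` oscillation cycles (checked
    from the accumulated phase; pass detrended phases with ``min_periods=0``
    to skip the check).
    """
    phi, adv = _window_phases(phases, window)
    if min_periods and adv < min_periods:
        raise ValueError(
            f"window spans ~{adv:.1f} cycles < required {min_periods}; lengthen the window"
        )
    Z = np.exp(1j * phi)
    G = Z @ Z.conj().T / phi.shape[1]
    return SynchronyMatrix(rho=np.abs(G), averaged_over=1, subset=subset, phasor=G)


def average_plv(matrices: list[SynchronyMatrix]) -> SynchronyMatrix:
    """Entrywise mean over trials.

    When every member carries its complex phasor matrix the phasors are
    averaged and the modulus taken afterwards: locking that is constant
    within each trial but has a random offset across trials (shared
    oscillation frequency without coupling) then decays toward the
    random-phasor baseline, which is the purpose of trial averaging.
    Otherwise the moduli are averaged entrywise.
    """
    if not matrices:
        raise ValueError("empty ensemble of synchrony matrices")
    shape = matrices[0].rho.shape
    subset = matrices[0].subset
    for m in matrices[1:]:
        if m.rho.shape != shape:
            raise ValueError("synchrony matrices differ in shape")
    total = sum(m.averaged_over for m in matrices)
    if all(m.phasor is not None for m in matrices):
        G = np.mean([m.phasor for m in matrices], axis=0)
        return SynchronyMatrix(
            rho=np.abs(G), averaged_over=total, subset=subset, phasor=G
        )
    rho = np.mean([m.rho for m in matrices], axis=0)
    return SynchronyMatrix(rho=rho, averaged_over=total, subset=subset)


def overall_synchrony(
    phases: PhaseTrace,
    window: tuple[float, float],
    subset: np.ndarray | None = None,
    *,
    min_periods: float = 10.0,
) -> float:
    """Time-averaged Kuramoto order parameter R over the window.

    ``subset`` restricts the population (typically the excitatory nodes);
    default is all nodes.
    """
    phi, adv = _window_phases(phases, window)
    if min_periods and adv < min_periods:
        raise ValueError(f"window spans ~{adv:.1f} cycles < required {min_periods}")
    if subset is not None:
        phi = phi[np.asarray(subset)]
    R_t = np.abs(np.exp(1j * phi).mean(axis=0))
    return float(R_t.mean())


def structure_function_correlation(
    sc: StructuralMatrix, fc: SynchronyMatrix
) -> StructureFunctionReport:
    """Pearson r between the strictly lower-triangular parts of SC and FC.

    ``fc`` must already be restricted to the nodes matching the structural
    areas (for the paired E/I schemes: the excitatory subset).  Zero variance
    in either triangle yields an explicit "undefined" status, never a silent
    zero.
    """
    if fc.n_nodes != sc.n_areas:
        raise ValueError(
            f"FC has {fc.n_nodes} nodes but SC has {sc.n_areas} areas; "
            "restrict FC to the matching (excitatory) subset first"
        )
    il = np.tril_indices(sc.n_areas, k=-1)
    x = sc.adjacency[il]
    y = fc.rho[il]
    if np.std(x) == 0 or np.std(y) == 0:
        return StructureFunctionReport(pearson_r=np.nan, status="undefined")
    r, _ = stats.pearsonr(x, y)
    return StructureFunctionReport(pearson_r=float(r), status="ok")
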