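"""HDF5 serialization for simulation traces and phase models.

Trace files carry ``/t``, ``/V``, ``/W`` with run metadata as root
attributes; phase-model files carry ``/omega``, ``/K``, ``/shifts`` plus the
partition and provenance attributes.  Matrices travel as plain text through
:mod:`neuromass.connectivity`.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .network_simulator import SimulationTrace, TrialEnsemble
from .phase_reduction import PhaseModel

__all__ = [
    "save_trace",
    "load_trace",
    "save_ensemble",
    "load_ensemble",
    "save_phase_model",
    "load_phase_model",
]


def _write_trace(group, trace: SimulationTrace) -> None:
    group.create_dataset("t", data=trace.t)
    group.create_dataset("V", data=trace.V)
    group.create_dataset("W", data=trace.W)
    for key, val in trace.meta.items():
        if isinstance(val, (int, float, str, np.floating, np.integer)):
            group.attrs[key] = val


def _read_trace(group) -> SimulationTrace:
    meta = {k: (v.item() if hasattr(v, "item") else v) for k, v in group.attrs.items()}
    return SimulationTrace(
        t=group["t"][...], V=group["V"][...], W=group["W"][...], meta=meta
    )


def save_trace(trace: SimulationTrace, path) -> None:
    with h5py.File(Path(path), "w") as fh:
        _write_trace(fh, trace)


def load_trace(path) -> SimulationTrace:
    with h5py.File(Path(path), "r") as fh:
        return _read_trace(fh)


def save_ensemble(ensemble: TrialEnsemble, path) -> None:
    with h5py.File(Path(path), "w") as fh:
        fh.attrs["n_trials"] = len(ensemble)
        for i, tr in enumerate(ensemble):
            _write_trace(fh.create_group(f"trial{i:04d}"), tr)


def load_ensemble(path) -> TrialEnsemble:
    with h5py.File(Path(path), "r") as fh:
        names = sorted(k for k in fh.keys() if k.startswith("trial"))
        return TrialEnsemble(traces=tuple(_read_trace(fh[n]) for n in names))


def save_phase_model(pm: PhaseModel, path) -> None:
    with h5py.File(Path(path), "w") as fh:
        fh.create_dataset("omega", data=pm.omega)
        fh.create_dataset("K", data=pm.K)
        fh.create_dataset("shifts", data=pm.shifts)
        fh.create_dataset("amplitudes", data=pm.amplitudes)
        fh.create_dataset("e_indices", data=pm.e_indices)
        fh.create_dataset("i_indices", data=pm.i_indices)
        fh.attrs["Omega"] = pm.Omega
        for key, val in pm.meta.items():
            if isinstance(val, (int, float, str, bool, np.floating, np.integer)):
                fh.attrs[key] = val


def load_phase_model(path) -> PhaseModel:
    with h5py.File(Path(path), "r") as fh:
        meta = {
            k: (v.item() if hasattr(v, "item") else v)
            for k, v in fh.attrs.items()
            if k != "Omega"
        }
        return PhaseModel(
            omega=fh["omega"][...],
            K=fh["K"][...],
            shifts=fh["shifts"][...],
            Omega=float(fh.attrs["Omega"]),
            amplitudes=fh["amplitudes"][...],
            e_indices=fh["e_indices"][...],
            i_indices=fh["i_indices"][...],
            meta=meta,
        )
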