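# neuromass

Delayed oscillatory neural-mass networks, their phase-oscillator reduction,
and the structure–function relationship of phase-synchronization
"functional connectivity".

## The problem

Anatomical (structural) connectivity predicts which brain areas
synchronize — but not perfectly: functional connectivity estimated from
oscillatory signals is blurred, time-varying, and shaped by conduction
delays as much as by wiring. This package implements, end to end, a
mechanistic account of that discrepancy for networks of Freeman-type
neural masses:

* a fixed-step simulator for the delayed network — per node
  `V'' + (a+b)V' + abV = ab[P + Σ_m C_nm S(V_m(t−τ_nm))]` with a normal-CDF
  activation `S` and an optional exponential synaptic kernel — with
  per-edge delay ring buffers and trial ensembles;
* its linear theory: fixed points (delay-independent), closed-form
  eigenvalues of an isolated excitatory/inhibitory pair under the
  small-delay expansion, the exact transcendental characteristic root as an
  oracle, and the analytic frequency-versus-delay curve `Ω(τ)`;
* the averaged phase reduction
  `φ_n' = ω_n + Σ_m K_nm cos(φ_m − φ_n − Ωτ_nm)` with effective coupling
  `K_nm = −(a_n b_n/2Ω) C_nm S'(V*_m) r_m/r_n` — delays act only as phase
  shifts, and `K` is the explicit structure→function map;
* stationary cluster states of the phase-density continuity equation
  (two-cluster and generalized M-cluster solvers with an independent drift
  verifier and numerical stability classification), and the change of
  variables that maps the homogeneous scheme onto a Kuramoto-type network
  with its synchronization transition;
* the measurement pipeline: common spectral peak detection, zero-phase
  Butterworth band-pass, Hilbert phases, detrending/alignment, circular
  phase distributions, phase-locking-value (PLV) functional connectivity,
  and the Pearson correlation between the lower triangles of the
  structural and functional matrices.

Builders are included for the homogeneous, inhomogeneous and
anatomical coupling schemes, plus a synthetic small-world binary
connectome (66 areas by default) standing in for an empirical cortical
matrix, so nothing needs downloading.

See `docs/methods.md` for the model, derivations, parameter defaults and
the study conditions used by the tests.

## Worked example

Strong homogeneous coupling with a 1 ms constant delay: the simulated
network settles into two phase clusters (all excitatory masses in one, all
inhibitory in the other), and the continuity-equation theory predicts the
measured cluster offset.

```python
import numpy as np
from neuromass.connectivity import build_homogeneous, build_delays
from neuromass.model_core import NetworkParams, find_fixed_points
from neuromass.network_simulator import simulate_ensemble
from neuromass.phase_extraction import extract_aligned_phases, phase_distribution
from neuromass.phase_reduction import reduce
from neuromass.stationary_clusters import (
    classify_stability, compute_constants, drift, solve_two_cluster,
)

net = NetworkParams.balanced(n_pairs=20, c=6.5, seed=7)
C = build_homogeneous(n_pairs=20, c=6.5, k=2.0)
D = build_delays(40, "constant", tau0=1e-3)

ens = simulate_ensemble(C, D, net, duration=4.0, dt=1e-4, n_trials=3, base_seed=42)
aligned, Omega = extract_aligned_phases(ens, window=(1.2, 3.7), e_indices=C.e_indices)
dist = phase_distribution(aligned, C.e_indices, C.i_indices)
print(f"network rhythm: {Omega / 2 / np.pi:.1f} Hz")
print(f"phase clusters detected: {dist.mode_count}")
print(f"measured E-I cluster offset: {np.degrees(dist.circ_mean_i):.1f} deg")

net0 = NetworkParams.balanced(20, 6.5, param_jitter=0.0, seed=7)
pm = reduce(C, D, net0, find_fixed_points(C, net0))
sol = solve_two_cluster(compute_constants(pm), shift=float(pm.shifts[0, 1]))
print(f"predicted offset: {np.degrees(sol.deltas[0]):.1f} deg "
      f"(drift residual {np.max(np.abs(drift(sol.phases, pm))):.1e})")
print(f"stable: {classify_stability(sol, pm)['stable']}")
```

Output:

```
network rhythm: 45.8 Hz
phase clusters detected: 2
measured E-I cluster offset: -77.0 deg
predicted offset: -76.9 deg (drift residual 5.7e-14)
stable: True
```

The rhythm sits in the fast band (the 1 ms delay lowers it from the
zero-delay 62 Hz); the two detected modes are the excitatory and
inhibitory clusters; and the stationary offset solved from the pooled
coupling constants (−76.9°) matches the Hilbert-phase measurement (−77.0°)
with a drift residual at machine precision — the delay changes the rhythm,
not the cluster geometry.

## Command line

```sh
neuromass simulate --config cfg.yaml --out run.h5 --trials 10 --seed 42
neuromass reduce   --config cfg.yaml --run run.h5 --out pm.h5
neuromass clusters --pm pm.h5 --m-max 4 --out clusters.tsv
neuromass measure  --run run.h5 --out stats.tsv
neuromass stability --c 6.0 --tau-grid 0:2.5e-5:5 --out spectrum.tsv
neuromass recipe homogeneous-delay-sweep --out results/
```

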