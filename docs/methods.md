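# Methods

This note documents the model, the derivations the package implements, the
numerical choices, and the study conditions used by the test suite and
`scripts/acceptance.py`.

## The neural-mass network

Each node is a Freeman-type neural mass: the mean membrane potential `V_n`
of a population obeys a driven second-order dynamics

    V_n'' + (a_n + b_n) V_n' + a_n b_n V_n
        = a_n b_n [ P_n + Σ_m C_nm (g ⊛ S(V_m(t − τ_nm))) ]

with rise and decay rates `a_n`, `b_n` (1/s), constant input `P_n`, and a
sigmoidal activation `S(V) = q Φ((V − μ)/σ)` — the normal CDF of the firing
thresholds across the population, scaled by the maximum rate `q`.  The
synaptic kernel `g(t) = γ e^{−γt}` is taken in its memoryless limit
`γ → ∞` throughout the analysis (the simulator also integrates finite `γ`
as an auxiliary first-order state).  `C_nm` couples source `m` into target
`n` (rows are targets); signs follow the source type.  Self-coupling is
zero.

One excitatory/inhibitory pair, mutually coupled at strength `±c`,
represents one area.  The pair's fixed point `V* = P + C S(V*)` is
delay-independent (stationarity makes the delayed argument equal its own
value).  Linearized around `V*`, the pair's eigenvalues solve

    λ² + (a + b + μτ) λ + (ab − μ) = 0 ,   μ = ± i κ,
    κ = a b c √(S'(V*_E) S'(V*_I))

in the small-delay expansion (delayed term Taylor-expanded to first
order), or `λ² + (a+b) λ + ab = μ e^{−λτ}` exactly; the exact root is
located by complex Newton iteration seeded at the τ = 0 closed form and
serves as the test oracle for the expansion (observed error order ≈ 2 in
τ).  Oscillations require `κ` large enough that one conjugate pair has
positive real part; at the defaults below the threshold is `c* ≈ 5.92`.

### Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| `a`, `b` | 220, 720 s⁻¹ | places the pair eigenfrequency in the fast (≈60–70 Hz) band |
| rate jitter | ±5% uniform per pair (both members share the draw) | distributed natural frequencies across areas |
| sigmoid `q, μ, σ` | 1, 1, 1 | order-unity activation with the fixed point on the rising flank |
| `P_E`, `P_I` | `μ ± c q/2` (“balanced”) | puts every fixed point exactly at the sigmoid threshold, where the slope (0.399) and hence the oscillation gain is maximal; for the homogeneous scheme the between-pair E and I inputs cancel, so `V* = μ` holds network-wide and class-wise equality of `V*` is exact |
| `c` (within pair) | 6.5 for network runs | comfortably supercritical for every jittered pair while keeping the limit cycle quasi-harmonic |
| `c` | 6.0 for the frequency–delay comparison | just above threshold; see below |
| `k` strong / weak | 2.0 / 0.3 (aggregate; internally divided by `n_pairs`) | well above / near the locking threshold set by the ±7 rad/s frequency spread |
| `dt` | 1e-4 s (2.5e-5 s for the near-critical pair) | ≥150 steps per period; first-order convergence verified against dt/10 |

## Frequency versus delay

A saturated limit cycle oscillates at the frequency where the effective
loop gain is marginal, so the *linear* eigenfrequency (evaluated with the
fixed-point slope) can only match the simulated spectral peak near the
Hopf point, where the slowly-varying-amplitude assumption (growth ≪
rhythm) holds.  We verified this quantitatively: at `c = 10` the simulated
peak is pinned near the marginal curve `tan(Ωτ) = (ab − Ω²)/((a+b)Ω)` and
deviates from the linear prediction by up to 26%; at `c = 6.0` (growth
rate ≈ 3/s against Ω ≈ 400 rad/s) the prediction matches within 3.3%
across delays `τ ∈ {0, …, 0.1} ms`.  The frequency–delay comparison is
therefore run at `c = 6.0` on that grid — the validity regime of the
theory being tested — with both the predicted and simulated `Ω(τ)`
decreasing in `τ`.

## Phase reduction

Writing `V_n = V*_n + r_n cos(Ω t + φ_n)` and averaging over one period
(rotating wave + slowly varying amplitude) gives

    φ_n' = ω_n − Ω + Σ_m K_nm cos(φ_m − φ_n − Ω τ_nm)
    ω_n  = Ω + (a_n b_n − Ω²) / (2Ω)
    K_nm = −(a_n b_n / 2Ω) C_nm S'(V*_m) (r_m / r_n)

Delays survive only as phase shifts `Ω τ_nm`.  The sign convention was
validated three ways: the isolated pair's eigenmode has the inhibitory
member lagging by π/2 with amplitude ratio `r_I/r_E = √(S'_E/S'_I)`, both
reproduced by simulation; the predicted stationary E–I offset (−77° at
`k = 2`) matches the measured aligned-phase distributions to within half a
degree; and the full-model versus phase-model relative-phase trajectories
agree with circular correlation ≈ 0.99 on a weakly coupled 10-pair
network.  The common frequency `Ω` is solved self-consistently per pair by
Newton iteration on the exact delayed characteristic equation at the mean
delay (sub-threshold pairs fall back to `√(ab)`, the frequency at
oscillation onset); amplitudes default to the analytic eigenmode ratio and
can be replaced by Hilbert-envelope estimates pooled by node type.

## Stationary clusters

For a countable network the zero-noise phase density is a sum of delta
clusters, and stationarity means the bracketed drift vanishes.  Pooling
the homogeneous scheme's coupling into class constants turns two-cluster
stationarity into a scalar condition in `Δ = φ̂_I − φ̂_E` (solved by
bracketed root-finding; at zero shift `cos Δ = (A_II − A_EE)/(Q_EI −
Q_IE)`, whose admissibility is the solvability inequality carried as a
flag).  The `M`-cluster generalization solves the equal-drift system over
pair-respecting memberships by damped least-squares with 32 seeded random
restarts.  Every solution is re-verified through an independent drift
evaluation on the full phase model (residuals ~1e-13) and classified by
the sign of the leading Jacobian eigenvalue with the global-rotation zero
mode excluded.  Equal-delay solutions with `M = 2, 3, 4` clusters all
exist at weak coupling, and the constant-delay shift cancels from the
two-cluster condition, so the state persists at finite common delay.

## Kuramoto mapping

The averaged coupling is sign-structured by source class.  Two exact
rewrites remove the structure: `−cos x = cos(x − π)` folds signs into the
shift matrix, and shifting all inhibitory phases by the stationary
two-cluster offset `Δ` makes the synchronized cluster state read as full
synchrony.  Under the equal-strength simplification (`c` equal to the
between-pair entry, equal slopes and amplitudes) the transformed coupling
magnitudes are all equal; the reported asymmetry (relative spread of
off-diagonal |K|) is zero there and grows monotonically with coupling
inhomogeneity.  Because the transform is a change of variables,
trajectories map back exactly (round-trip error ~1e-14).  With per-pair
frequency jitter the transformed model shows the Kuramoto transition:
order parameter R̄ ≥ 0.95 for entry coupling 0.1 s⁻¹-scale and R̄ < 0.3
at 0.003, across 20 random initial conditions each.

## Measurement pipeline

Welch spectra (≈2.5 Hz bins, peaks filtered at 1% prominence) give the
lowest frequency that peaks for every node; the traces are band-passed
with a first-order bidirectional Butterworth (default ±2 Hz; ±10 Hz with
6 Hz detection bins for the partially synchronized connectome runs);
phases are the unwrapped analytic-signal angles on a window excluding the
first/last 5% of samples; the carrier is removed using a frequency
*refined from the unwrapped phase slopes* (one shared value per ensemble)
— spectral-bin quantization would otherwise smear the aligned
distributions by a full turn over the window; each trial is then shifted
by the circular mean of its excitatory phases.  Histograms use 64 bins on
(−π, π].  Mode counting uses a von Mises kernel density whose
concentration is the resultant-length plug-in floored at 50 (kernel sd ≈
8°) — the plug-in alone assumes unimodality and merges the E and I
clusters — with peaks above 10% prominence; near-uniform samples report
zero modes.

Functional connectivity is the phase-locking value `ρ_nm = |⟨exp i(φ_n −
φ_m)⟩_t|`.  Trial averaging combines the **complex** mean phasors and
takes the modulus afterwards: locking that stems from a shared frequency
with trial-random offsets then decays toward the `1/√n_trials` baseline,
which is the stated purpose of averaging over runs (averaging the moduli
could not achieve it).  Structure–function correspondence is the Pearson
correlation of the strictly lower triangular parts of the binary
connectome and the excitatory-subset FC matrix; zero variance is reported
as "undefined", never silently zero.

## Study conditions of the headline experiments

* **Cluster states (constant delays).**  20–24 pairs, strong coupling
  `k = 2`, delays {0, 1 ms}, 3 trials of 3.5–4 s: two modes (E and I
  clusters), E–I offset ≈ −77°, unchanged by the common delay.
* **Delay widening.**  `k = 1.5`, uniform delays on `1.2 ± w` ms with
  `w ∈ {0, 0.2, 0.4}` ms, 20 paired seeds: seed-averaged excitatory
  circular variance ≈ 0.006 → 0.017 → 0.05, monotone per seed (sign
  test).  Widths are kept small because the within-pair delay disperses
  the pair frequencies at rate ≈ (a+b)/2 per unit delay, which
  desynchronizes the network entirely for `w ≳ 0.5` ms at this coupling.
* **Inhomogeneous coupling.**  Between-pair magnitudes uniform on
  `1.5 ± 1.5` at constant 1.2 ms delay reproduce the circular variance of
  the homogeneous run with a matched `±0.1` ms delay spread; doubling the
  overall strength concentrates both.
* **Connectome sweep.**  66-area Watts–Strogatz connectome (degree 8,
  rewiring 0.1) wiring the excitatory units only (`k·SC/⟨degree⟩`), each
  area keeping its private ±c pair; within-pair delays are zero (delays
  are distance-proportional and a pair is one area).  Between-area E–E
  coupling is cosine-type at the phase level, so its effective sine
  strength is `∝ −K_EE sin(Ωτ)`; with `K_EE < 0` the synchronizing window
  is `Ωτ ∈ (π, 2π)`, i.e. delays of 9–13 ms at ≈64 Hz, and growing the
  mean delay toward the optimum plays the "mean shift toward the pure
  sine point" role.  The width sweep uses uniform delay specs
  (mean ± half-width) = (8.6 ± 0.25), (9.05 ± 0.75), (9.9 ± 1.25) ms at
  `k = 2`, 5 fixed delay matrices × 4 initial-condition trials each:
  seed-averaged structure–function r falls 0.355 → 0.329 → 0.302 while
  overall synchrony rises 0.052 → 0.063 → 0.941.  At `k = 5` and constant
  11 ms delay the FC matrix saturates (median ρ ≈ 1).

Problem sizes (20–25 pairs, 66 areas, 3–4 s runs, 4–20 seeds) are
desk-scale choices; the protocols scale to larger networks unchanged.

## Known limitations

* The phase reduction evaluates slopes at the fixed point, so its coupling
  magnitudes overestimate the saturated effective coupling by ~10% away
  from the Hopf point; relative-phase patterns are insensitive to this,
  absolute locking thresholds less so.
* The continuity-equation layer assumes the exactly homogeneous scheme;
  with jittered rates the pooled constants are means and the drift
  verifier is the arbiter.
* No stochastic input, no amplitude dynamics (amplitudes are held
  constant), no adaptive stepping; delays are rounded to the Euler grid
  (warned above 1% relative error).
* The synthetic connectome reproduces small-world clustering and degree,
  not the lobe/hemisphere organization of an empirical cortical matrix;
  structure–function numbers on real connectomes will differ in value,
  not in protocol.
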