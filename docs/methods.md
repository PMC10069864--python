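# Methods

`mbonsim` implements a connectome-constrained *passive* biophysical model of
a Drosophila mushroom body output neuron (MBON-α3) and the analysis
campaigns built on it.  This note records the model, its assumptions, the
numerical choices, what the synthetic generators do and do not emulate, and
the known limitations.

## The model

The neuron is a tree of cylindrical sections (the EM reconstruction divides
the dendritic tree into 4336 sections; five axon/terminal sections and a
soma are appended for a total of 4342).  Each section becomes one or more
electrical compartments obeying linear cable theory:

    C_i dV_i/dt = −g_i (V_i − e_pas) − Σ_s g_s(t) (V_i − E_rev)
                  + Σ_j a_ij (V_j − V_i) + I_i(t)

with membrane capacitance `C_i = cm·A_i`, leak conductance `g_i = g_pas·A_i`
(`A_i` the lateral cylinder area), and axial conductances `a_ij` from the
series resistance of the two half-compartments,
`R = 4·Ra·(ℓ/2)/(π d²)` per half.  There are no voltage-gated conductances:
the recorded cell fires small (≈4 mV) somatic spikes, but the model is
deliberately passive and all claims are about subthreshold integration.

Kenyon-cell (KC) synapses are conductance transients ("alpha synapses")

    g(t) = strength · gmax · ((t−t₀)/τ_s) · exp(−(t−t₀−τ_s)/τ_s),  t ≥ t₀

peaking at exactly `strength·gmax` at `t₀ + τ_s`, with cholinergic
parameters τ_s = 0.44 ms and E_rev = 8.9 mV.  (A popular variant of this
formula omits the 1/τ_s normalization and then does not peak at gmax; we use
the peak-normalized convention because gmax is *calibrated* to a target
somatic depolarization, which presumes peak = gmax.)

### Parameters

| parameter | meaning | unit | default | origin |
|---|---|---|---|---|
| Ra | cytoplasm resistivity | Ω·cm | 85.41 | fitted to −10 pA step |
| cm | specific membrane capacitance | μF/cm² | 0.6961 | fitted |
| g_pas | passive membrane conductance | S/cm² | 9.399e-6 | fitted |
| e_pas | leak reversal | mV | −55.64 | pre-stimulus baseline |
| τ_s | synaptic time-to-peak | ms | 0.44 | cholinergic KC currents |
| E_rev | synaptic reversal | mV | 8.9 | cholinergic KC currents |
| gmax | peak synaptic conductance | μS | 1.5627e-5 | calibrated to 0.37 mV mean single-KC somatic peak |

Internal units are μm / ms / mV / nA / μS / nF; the conversions from the
specific units above are

    C [nF] = cm·A[μm²]·1e-5,  g_leak [μS] = g_pas·A·1e-2,
    R_axial [MΩ] = 0.04·Ra·ℓ/(π d²).

The steady-state space constant `λ = sqrt(d/(4·Ra·g_pas))` evaluates to
≈950 μm at the mean dendritic diameter (0.29 μm) with the fitted parameters
— several times the longest dendritic path, which is the analytic footprint
of the neuron's electrotonic compactness.  (The source analysis quotes
λ ≈ 1300 μm for the same inputs; the formula does not reproduce that number
and we report what the formula gives.  None of the campaign results depend
on it.)

## Numerics

* **Integrator.**  Backward Euler (Crank–Nicolson via `method=` option) with
  synaptic conductances evaluated at the new time level, so every step is
  one linear tree solve.  The solve is Hines elimination — children are
  eliminated into parents in reverse topological order, O(n) per step — with
  the inner loop jitted by numba.  Default dt = 0.025 ms; halving dt or
  doubling compartments per section moves a standard somatic EPSP peak by
  < 0.5%.  Voltages start at `e_pas` (the exact resting state), so the 30 ms
  equilibration window conventionally simulated before stimuli is exact.
* **Oracles.**  The integrator is tested against the single-compartment RC
  closed form (0.1%), dense matrix-exponential solutions on ≤ 20-compartment
  trees (0.1%), the sealed-end finite-cable cosh profile (1%), and the
  equilibrium / bounds / superposition / reciprocity invariants of a passive
  linear system.  `steady_state` solves the same system exactly with sparse
  LU and serves as the independent steady-state oracle.
* **Passive fit.**  (Ra, cm, log₁₀ g_pas) are searched inside physiological
  bounds (cm 0.5–1.5 μF/cm², g_pas 1e-7–1e-4 S/cm², Ra 30–400 Ω·cm) against
  the mean squared error of the somatic −10 pA step response over
  32.025–228.03 ms (excluding ~2 ms around the step edges).  e_pas is pinned
  to the target's pre-stimulus baseline, not searched.  Strategy: 5 seeded
  Latin-hypercube starts are ranked by objective value and the best 2 are
  polished with Nelder–Mead at `fatol = 1e-12`, ≤ 500 evaluations each.  The
  tight f-tolerance matters: the valley along Ra is shallow (±5% Ra ≈ 1e-5
  mV² on the synthetic stand-in) and looser tolerances stall ~10% from the
  optimum.  scipy's Powell (a true principal-axis method) was rejected
  because a small evaluation budget truncates it mid-line-search.  A
  finite-difference Hessian proxy at the optimum flags rank-deficient
  (degenerate) fits — e.g. on a single compartment, where only τ = cm/g_pas
  and the total conductance are identifiable.
* **Fit targets.**  Recovery tests fit the average of 35 noisy sweeps, as
  the recording protocol does (35 step repetitions per cell).  Fitting a
  single 0.1 mV-noisy sweep leaves Ra biased at the ~6% level: the somatic
  trace of an electrotonically compact cell simply carries little
  information about Ra, and the noise tilts the flat valley floor.
* **Spike detection** (trace analysis): local maxima with ≥ 1 mV prominence,
  2 ms refractory separation, that rise *and* fall by ≥ 1 mV within 1.5 ms.
  The two-sided sharpness requirement distinguishes action potentials from
  passive deflections (which decay with τ_m ≈ 16 ms); it is a heuristic and
  will flag sufficiently large, fast compound EPSPs.
* **Protocol-1 resistances.**  `Rinput = Rseries + Rm` in the uncompensated
  voltage-clamp circuit, so `Rm = |Rinput − Rseries|` (the source protocol's
  wording subtracts in the other order, which would be negative).

## Synthetic data: what it emulates, what it does not

`generate_morphology` grows a random binary-branching tree with
gamma-distributed section lengths, a persistent-random-walk 3D layout and
diameters that decay with path distance from the root (`taper_exponent`),
then rescales lengths and diameters so the whole-cell means match the target
statistics *exactly* (defaults: 4342 sections, mean length 1.24 μm, mean
diameter 0.29 μm, soma 6.45 μm).  The appended axon placeholder is short
(26 μm total) so that small test trees keep the target mean section length;
the real axon geometry is configurable wherever it matters.

`generate_connectivity` draws per-KC contact counts from a 1-truncated
negative binomial (size 6) conditioned to sum exactly to the total —
defaults 948 KCs, 12,770 contacts, hence a mean of 13.47 per KC — with
optional forced outliers (one 38-contact KC) — and places sites uniformly
over dendritic sections.  Two optional knobs exist for sensitivity tests:
`distal_bias` (placement weighted by distance) and `cluster_radius_um`
(each KC's contacts confined near a random anchor, emulating the spatial
correlation of contacts along a real KC axon).  By default placement is
uniform and independent, so per-KC site sets are statistically identical to
random site draws — a real difference from the anatomy, where KC contacts
cluster.  Variance comparisons between "anatomical" and "random" synapse
sets are therefore only meaningful with clustering enabled.

`generate_recording` adds i.i.d. Gaussian voltage noise (optionally
averaging n sweeps).  Real recording noise is colored and includes electrode
artifacts; the generator is only meant for fit-recovery tests.

A green test on synthetic data establishes that the *pipeline* reproduces
the qualitative pattern (compactness, linearity, saturation) under the
stated summary statistics — not that it reproduces the archived neuron's
quantitative values, which require the archived reconstruction
(`mbonsim.reproduction`, `data/archive/`).

## Campaign conventions

* All synapses of a trial share one onset (a single volley; a jitter option
  is deliberately absent — the source campaigns use simultaneous
  activation).  Horizon: 30 ms settling + 60 ms post-onset, which contains
  the peak with margin (τ_s = 0.44 ms, τ_m ≈ 16 ms).
* Trials sample KCs (or sites) uniformly without replacement; per-trial RNG
  substreams are spawned from the campaign seed, so campaigns are
  bit-reproducible from (config, seed).
* The desk-scale stand-in used throughout the tests: 500 sections, 100 KCs,
  1347 synapses (mean 13.47/KC kept), baseline ensemble 5 KCs (5% of the
  population, as 50 of 948), ±25% manipulations rounded to {4, 5, 6} KCs and
  {75, 100, 125}% strength, 200 trials, gmax calibrated to the 0.37 mV
  single-KC target.  Sub-proportionality of KC-count manipulations is judged
  against the realized activated-synapse ratio, since with 100 KCs the
  38-contact outlier makes trial synapse counts deviate noticeably from the
  n_kcs ratio.
* Statistics: ordinary one-way ANOVA for multi-group comparisons, unpaired
  Student t-test for pairwise (Welch optional), OLS for the
  peak-vs-synapse-count slope — scipy implementations, cross-checked against
  textbook formulas in the tests.

## Limitations

* No active conductances, spike generation, synaptic depression/facilitation
  or failures; strength multipliers are static per campaign.
* The soma is a single cylinder (length = diameter); the soma-to-neurite
  link is geometric only unless configured.
* The axon section dimensions are placeholders pending the reconstruction
  supplement's values; they barely affect dendro-somatic integration but do
  affect proximal-neurite absolute amplitudes.
* `fit_passive` is a multi-start local search, not a global optimizer.
* Quantitative reproduction of the archived neuron (mean single-KC peak
  0.37 mV, 50-KC ensemble mean ≈ 15 mV, slope ≈ 0.0185 mV/synapse,
  single-synapse somatic spread < 1 μV) requires the archived SWC/JSON
  exports, which are not distributable with this package.
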