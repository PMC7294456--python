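# Methods

## Model

The circuit is a three-layer feedforward network. Olfactory receptor
neurons (ORNs) are inhomogeneous Poisson sources; the antennal lobe (AL)
contains 35 glomeruli, each with one projection neuron (PN) and one
inhibitory local interneuron (LN); the mushroom body (MB) contains 1000
Kenyon cells (KCs). PN, LN and KC share one set of leaky
integrate-and-fire parameters (capacitance 289.5 pF, leak 28.95 nS, rest
and reset −70 mV, threshold −57 mV, refractory 5 ms, hence
τ_m = 10 ms): the model is deliberately generic, so none of its effects
can be traced to cell-type-specific membrane parameters.

Membrane equations (per population, currents in pA):

    c_m dv_P/dt = g_L(E_L − v_P) + g_OP(E_E − v_P) + g_LP(E_I − v_P) − I_A
    c_m dv_L/dt = g_L(E_L − v_L) + g_OL(E_E − v_L) − I_A
    c_m dv_K/dt = g_L(E_L − v_K) + g_PK(E_E − v_K) − I_A

Synaptic conductances decay exponentially (τ_E = 2 ms excitatory,
τ_I = 10 ms inhibitory) and jump by the synaptic weight at each
presynaptic spike. Two structural points deserve emphasis:

* **The LN→PN conductance `g_LP` is a single shared state variable.**
  Every LN spike (from any glomerulus, including a PN's own) increments
  it, and it is applied identically to every PN. This is the model's
  "global, unspecific" lateral inhibition; it is not a per-PN quantity.
* **Pooled ORN drive.** All 284 ORNs of one type converge on one
  glomerulus, so the drive is sampled directly as Poisson *counts* per
  0.1 ms step with mean `284 · r(t) · dt` — exact by the superposition
  property of Poisson processes, and ~10⁴× cheaper than simulating
  9940 independent generators. The same realized counts drive the PN
  and the LN of a glomerulus, preserving their input correlation.
  Counts (not Bernoulli thinning) matter because the expected count per
  step reaches ≈ 1.7 at the 60 Hz peak rate.

Adaptation is a spike-triggered hyperpolarizing current (a
phenomenological stand-in for calcium-activated potassium currents):
each own spike adds ΔI_A = 132 pA, decay time τ_A = 389 ms, plus an
Ornstein–Uhlenbeck channel-noise term with stationary variance
σ_I² = 87.1 pA². In conditions without SFA the current is replaced by a
static compensation (380 pA in PN/LN, zero in KC) chosen to preserve
the spontaneous rates; note 380 pA ≈ τ_A·ΔI_A·8 Hz ≈ 410 pA, the mean
adaptation current of an 8 Hz-firing adapting neuron.

Lateral-inhibition strength is the dimensionless α (w_LP = α·w₀,
w₀ = 1 nS), with feedforward compensation w_OP = w₀(1 + b·α). The slope
b = 0.04 is shipped as a constant (it back-solves the canonical
condition table: 1 + 3b = 1.12); `calibrate_b` re-derives it by grid
search over stimulus-free simulations if wanted.

PN→KC wiring is Bernoulli with connection probability 12/35 per pair
("on average 12 inputs per KC"). The binomial in-degree spread is part
of the mechanism — KCs with many inputs respond preferentially — so a
fixed in-degree variant was deliberately not used. The mean in-degree is
exposed (9/12/15) for connectivity sweeps.

## Numerics

Forward Euler at dt = 0.1 ms, vectorized over neurons in a compiled
kernel. Update order per step: (1) conductances decay (exact
exponential factor) and receive boundary delta-increments — ORN counts
of the step, plus network spikes detected at the end of the previous
step; (2) adaptation currents decay (Euler) and receive noise;
(3) voltages take one Euler step; (4) spikes are detected at the step
end (v ≥ V_T), with reset, refractory-countdown start, and the ΔI_A
jump. During the 5 ms refractory period the voltage is clamped at the
reset while conductances and adaptation currents continue to evolve and
accumulate input; the minimal inter-spike interval is therefore
τ_ref + dt. A sentinel check aborts the run with a diagnostic if the
state becomes non-finite.

The OU noise increment is applied on a 1 ms grid (every 10 steps) with
variance scaled by the interval, `√(2 σ_I² · 10·dt / τ_A)·N(0,1)`.
Because the OU correlation time (389 ms) is three orders of magnitude
longer than the noise grid, the process statistics at the resolutions
that matter (membrane τ_m = 10 ms and above) are unchanged; the
stationary-variance test verifies 87.1 pA² to within a few percent.
This choice makes the α-sweep roughly 5× faster.

An independently written scalar per-neuron Python integrator mirrors
the same discretization and serves as the oracle in the equivalence
test (noise off, miniature network, max |Δv| < 10⁻⁹ mV and identical
spike trains). An exponential-Euler voltage update was evaluated and
produced statistically indistinguishable rates; plain Euler was kept.

Trials are initialized cold (v = E_L, I_A = 0, conductances 0) and run
unrecorded for 2000 ms under spontaneous drive before the 3000 ms
recorded window (odor step at 1000–2000 ms, half-open interval on the
time grid). Every (condition, realization, odor, trial) combination
draws from an independent `numpy SeedSequence` substream of the master
seed, so results are bit-reproducible and order-independent. In the
α-sweep the *same* substreams serve every α (common random numbers),
which pairs the comparison across α and sharpens the location of the
correlation minimum at fixed replication.

## Analysis conventions

* Population rate: spike counts in 10 ms bins averaged over neurons and
  trials.
* Sparseness: modified Treves–Rolls measure `s = 1 − ⟨a⟩²/⟨a²⟩` on
  non-negative activities; *population* flavor uses the 1000 per-KC
  spike counts over the full 1 s stimulus window, *temporal* flavor the
  KC population rate in 20 × 50 ms bins over the same window. An
  all-zero vector is undefined and reported as missing (NaN) with a
  warning, never as 0. The implementation normalizes by the maximum
  first (the measure is scale-invariant), which guards against
  overflow/underflow in the squares.
* Pattern correlation: Pearson correlation between per-neuron evoked
  spike-count vectors of two odors (default pair Δk_S = 2), computed
  per trial (then averaged over trials and realizations) or on
  trial-averaged patterns (then averaged over realizations). Patterns
  with zero variance yield missing values that are excluded from
  averages and counted, keeping high-α sweep points interpretable.
* Activated fraction: per-trial fraction of KCs with ≥ 1 spike in an
  epoch (stimulus second, spontaneous second, or first 50 ms
  transient), then trial mean and SD.
* Decoding: Gaussian naive Bayes (scikit-learn) on per-neuron features
  in 60 × 50 ms bins, stratified threefold cross-validation with one
  fold assignment reused across bins, maximum-a-posteriori prediction;
  reported accuracy is the fold mean (SD across folds, matching the
  uncertainty band convention). Feature sources: PN counts, KC counts,
  or KC adaptation-current amplitudes (bin mean of the 1 ms-sampled
  trace; a bin-end-sample variant is available). KC count features are
  mostly zero; a variance floor proportional to the largest feature
  variance keeps the Gaussian likelihood defined, and a bin with no
  variance anywhere falls back to the class prior explicitly (chance
  for balanced classes). Default odor set: k_S ∈ {0, 2, …, 12}, seven
  classes, chance ≈ 0.14.

## What the synthetic data does and does not emulate

All inputs are generated internally; there is no recorded data. The
ORN model captures spontaneous rates, step-like odor responses, and
graded receptor overlap between odors, but not receptor transduction
dynamics, ORN adaptation, or concentration series (the activation
amplitude is fixed at 40 Hz). Passing tests therefore demonstrate the
circuit-level transformation (dense → sparse, decorrelation, odor
trace in adaptation currents) under idealized drive, not quantitative
agreement with any particular recorded dataset.

## Problem sizes

The default test suite and the acceptance script use reduced
replication chosen to keep a full run in the minutes range on one CPU:
the α-sweep uses 10–15 trials × 2–3 network realizations per α
(the full grid is 50 × 5), decoding uses 20 trials per odor (full: 50),
and sparseness contrasts use 10 trials per condition. Spontaneous-rate
estimates use 10–20 s of simulated time. At these sizes the sampling
error of the KC pattern correlation per α is ≈ 0.01–0.02, which is of
the same order as the difference between the sweep's flattest points —
the reported argmin can shift between α = 3 and α = 4 at reduced
replication.

## Known limitations

* The KC operating point sits a little below the published one at the
  identical printed parameters: activated-KC fractions come out at
  ≈ 5–7% (published: 9% ± 3% SD) and the spontaneous KC rate at
  ≈ 0.001–0.002 Hz (published ≈ 0.03 Hz, stated tolerance ± 0.03).
  Both are within the stated spreads but systematically low; the
  α-sweep correlation minimum is correspondingly shallow between
  α = 3 and 4. Integration-scheme variants (exponential Euler) and a
  reinterpretation of the channel-noise magnitude were tested and
  rejected as explanations; the residual is attributed to untracked
  details of the original simulation environment.
* No synaptic delays, no short-term plasticity, no MB feedback
  (APL-type) neuron, single uniglomerular PNs only — absent from the
  modeled circuit by design.
* The adaptation "odor trace" is read out directly from the model's
  state variable; in an experiment this corresponds to calcium imaging
  rather than spike recordings.
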