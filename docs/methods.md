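# Methods

## Scope and model family

The package simulates one postsynaptic neuron driven by `n` excitatory
spike sources through plastic synapses whose weight factorizes as
`W = P·q`: `P ∈ (0,1]` is the presynaptic factor (baseline vesicle release
probability) and `q ∈ (0,1]` the postsynaptic factor (quantal amplitude,
scaled by the maximal quantal conductance `q_max`). Long-term plasticity
may write into `P`, into `q`, or into both; the point of the package is to
compare these loci of expression under otherwise matched conditions.

## Neuron models

**LIF** (minimal scenarios): `τ_V dV/dt = (E_v − V) + g·(E_e − V)` with
τ_V = 20 ms, E_v = −74 mV, threshold −54 mV, reset −60 mV, 1 ms refractory
period (V clamped at reset), excitatory reversal E_e = 0 mV. The synaptic
conductance `g` is dimensionless (units of the leak conductance) and decays
exponentially with τ_g = 5 ms. The excitatory drive is depolarizing; a
sign that made it hyperpolarizing would contradict every behaviour the
models are meant to produce.

**AdEx** (biologically tuned scenarios): C = 281 pF, g_L = 30 nS,
E_L = −70.6 mV, Δ_T = 2 mV, V_T = −50.4 mV, subthreshold adaptation
c_z = 4 nS with τ_W = 144 ms, spike-triggered adaptation b = 80.5 pA, reset
to E_L. The synaptic term is `−g_e·V` (0 mV reversal). Spikes are detected
when V escapes past `V_T + 5·Δ_T`; the exponential argument is capped at 16
to avoid overflow between blow-up and detection. The deterministic runaway
point of the free membrane lies a few millivolts above V_T (where the
exponential current first beats the leak); with synaptic drive, threshold
crossing is what matters and the detection point only truncates the
(sub-millisecond) upstroke.

**Integration**: forward Euler at dt = 0.1 ms for the membrane and
adaptation equations; exact exponential updates for all conductance, trace
and short-term-plasticity decays. Halving dt moves first-spike times by
well under 0.2 ms in a standard volley (tested).

## Transmission mechanisms

* `none` — deterministic increment `P·q·q_max` per spike.
* `stochastic` — binomial release over N = 5 independent sites,
  increment `(k/N)·q·q_max` with `k ~ Binomial(N, P)`. Expected increment
  `P·q·q_max`; the coefficient of variation falls with P, so presynaptic
  potentiation makes transmission more reliable, not just stronger.
* `stp` — Tsodyks–Markram dynamics with depression τ_D = 200 ms and
  facilitation τ_F = 50 ms, representative of pyramidal-to-pyramidal
  connections. At a spike the facilitation jump `p_v ← p_v + P(1−p_v)` is
  applied first, release uses the updated `p_v` and the pre-depression `r`
  (the common convention: facilitation affects the triggering spike; the
  alternative order is available behind a flag), then `r ← r(1−p_v)`.
  Transmission under STP is a deterministic amplitude modulation
  (`p_v·r·q·q_max`), not a stochastic draw. Under a regular train the
  per-interval recursions are affine and their fixed point is closed-form
  (`stp_steady_state`), which both the tests and the facilitation-crossover
  analysis use as the oracle. With these constants the synapse is net
  depressing except at small baselines (crossover well below 0.3) — more so
  at higher rates.

`q_max` is not a free dial: it is calibrated per neuron model so that ~20
simultaneous average-strength inputs (P = q = 0.5) drive the membrane from
rest to threshold (bisection on a deterministic volley; `calibrate_q_max`).
The frozen values are 0.41616 (LIF, leak units) and 9.13194 nS (AdEx).

## Plasticity rules

**Additive pair STDP** with τ = 20 ms, c_pot = 0.005, c_dep = −0.00525
(depression-dominated by 5%). Conventions: Δt = t_pre − t_post; causal
pre-before-post pairs potentiate; exact coincidences (same time step) fall
on the depression branch. The all-pairs double sum is implemented online
with exponential traces; on a pre spike the depression term uses the
postsynaptic trace including a same-step post spike, on a post spike the
potentiation term uses the presynaptic trace excluding same-step pre
spikes. This ordering makes the online engine exactly equal (to machine
precision) to the brute-force double sum, which the tests assert on random
trains.

*Locus allocation.* The raw increment `d` is expressed so the total weight
change is identical across loci at matched state (P = q): post → `Δq = d`
(ΔW = P·d); pre → `ΔP = d` (ΔW = q·d); both → the common increment
`Δ = −½[(P+q) − √((P+q)² + 4·P·d)]`, the root of `(P+Δ)(q+Δ) − Pq = P·d`.
If the discriminant is negative (a depression too large to realize), Δ is
clamped so the factors stop at the floor. Bounds: single-locus variables
cap at 1, giving a maximal weight change Δ_tot = P⁰(1−q⁰); for the shared
locus both variables cap at `√(P⁰q⁰ + Δ_tot)` so the maximal weight change
is the same. A floor of 1e-4 on P and q prevents an absorbing silent
state. Initial values default to P⁰ = q⁰ = 0.5.

*Release gating (stochastic mechanism).* Plasticity at a synapse requires
transmitter release: under binomial transmission, a presynaptic spike's
participation in the pair rule — its depression increment and its
contribution to the presynaptic trace — is weighted by the released
fraction `k/N` of that spike. The expectation of the gate is `P`, so the
matched-increment comparison between loci is unbiased at P = q, while
potentiated synapses learn faster and depressed synapses change more
slowly. The deterministic mechanisms are not gated.

**Biologically tuned rule** (constants fitted to layer-5 pyramidal
connections): traces `x_j⁺` (per input, τ = 66.6 ms), `y⁺` (τ = 230.2 ms)
and `y⁻` (τ = 32.7 ms), each incrementing by 1 at its spike. At each pre
spike of input j: `ΔP_j = −d₋·y⁻·y⁺ + d₊·x_j⁺·y⁺` with d₋ = 0.1771,
d₊ = 0.15480. At each post spike: `Δq_j = c₊·x_j⁺·y⁻` with c₊ = 0.0618,
then heterosynaptic scaling `Δq_j ← Δq_j − α·⟨Δq⟩` (α = 0.5) to stop
runaway postsynaptic potentiation. All updates evaluate traces as they
stood before the triggering spike's own increments. The rule expresses LTP
both pre- and postsynaptically but LTD only presynaptically; `block_locus`
zeroes one side while keeping the fitted ratios of the other (the
α-scaling is applied at post spikes, the only times Δq ≠ 0). P and q are
clipped to (1e-4, 1].

## Synthetic stimuli

**Latency paradigm.** 375 ms trials; each source fires a Poisson burst of
25 ms at 100 Hz starting at a source-specific delay drawn once from
Normal(100 ms, 15 ms) and clipped so the burst fits in the trial; burst
spikes are redrawn every trial, delays are not. The membrane, conductance
and short-term-plasticity variables are reset to rest at each trial onset;
long-term weights and plasticity traces persist. The delay spread (15 ms,
not printed anywhere authoritative) was chosen so the volley spans a few
STDP time constants; the mean delay serves as the latency reference.

**Correlation paradigm.** Continuous stimulation; half of the inputs share
pairwise spike-count correlation `c` at timescale τ_corr = 20 ms, the
other half are independent Poisson at the same rate. Correlated trains use
a calibrated multiple-interaction process: a mother Poisson train is
thinned independently into each child with copy probability `c_copy`, and
every copied event is jittered by Uniform(0, s). Jittering attenuates the
same-bin count correlation by `ρ = 1 − s/(3·τ_corr)`, so the generator
sets `s = min(τ_corr, 3·τ_corr·(1−c))` and `c_copy = c/ρ ≤ 1`; the
realized correlation then equals `c` over the whole range while each
train's marginal rate is preserved (verified empirically in the tests to
±0.05). Very strong correlations therefore come with proportionally
tighter synchrony — an identifiability constraint of this construction,
not a modelling statement. What the generator does **not** emulate:
correlations carried purely by slow rate co-fluctuations (without spike
coincidences), oscillatory or inhomogeneous rates, and inhibitory inputs.
Conclusions that hinge on coincidence-free correlation structure are
outside what passing tests establish.

**Competition scenario.** All inputs correlated at level c; half express
pair-STDP presynaptically, half postsynaptically; after every plasticity
event the summed weight is rescaled multiplicatively to its initial value,
each synapse's factor being applied to its plastic side (P for the
presynaptic half, q for the postsynaptic half), iterated so that clipping
does not break the conservation (held to 1e-9). The output per
(c, rate) cell is the final difference of mean weights between the halves.

## Analysis

Per-trial metrics: latency (first post spike minus the mean-delay
reference; missing if no spike — missing trials are excluded from
averages, not imputed), duration (last minus first spike) and intraburst
frequency ((n−1)/duration). Displayed/analysed latency series use the
3-point centered moving average (shrunken windows at the edges; missing
entries ignored). Learning speeds are compared as linear least-squares
slopes over the early learning phase (first 50–100 trials).

For the correlated/uncorrelated separation analysis each input is reduced
to the temporal mean and (population) variance of its weight over the
final half of the run — the steady phase; the window is configurable. A
linear least-squares classifier (labels ±1, prediction by sign, intercept
included) is trained on a stratified random half of the inputs and scored
on the other half; a singular design falls back to the training majority
label. The train/test split is seeded per realization.

## Reproducibility and problem sizes

Every experiment is a pure function of (config, seed); seeds are managed
with `numpy.random.SeedSequence` spawning, and all stochasticity —
including the binomial release draws consumed inside the compiled kernel —
is pre-drawn from seeded generators, making runs bit-reproducible. The
compiled engine is cross-checked in the tests against the pure-Python
reference implementations of the membrane step, the short-term-plasticity
map and the pair-rule all-pairs sum.

Default desk-scale sizes (the `reduced` presets, also used by the test
suite and the acceptance script): latency — 100 inputs, 100 trials,
10 seeds; correlation — 100 inputs, 100 s; competition — 60 inputs, 100 s
(long enough to reach the quasi-steady state that the end-of-run
comparison presumes); frequency scan — 100 inputs, 100 s, 3 seeds per
rate over 10–120 Hz. The `paper` presets are larger (200 inputs, 150
trials, 200 s).

## Known limitations

* With the calibrated `q_max` and a clamped total weight, the competition
  scenario operates at high output rates and both halves tend to saturate
  their caps; the presynaptic half's advantage (release-gated learning
  accelerating as P grows) is then offset by the renormalization, which
  lowers the presynaptic half's release probability — and with it its own
  learning rate — whenever net potentiation is rescaled away. The
  direction of the competition outcome at moderate correlation and rate is
  therefore sensitive to the renormalization convention, and the shipped
  convention does not produce a presynaptic win there (see the competition
  test).
* Because the multiple-interaction process carries correlation as (near-)
  coincident spikes at any rate, the tuned model can read out correlations
  even at 10–20 Hz — at those rates the synchronous volleys are
  presynaptically depressed by the post-before-pre triplet term, and the
  resulting (sign-reversed) group separation is easily detected by the
  classifier. The classification-vs-rate curve consequently peaks at low
  rates rather than in an intermediate band (see the frequency-scan test
  and acceptance output); under a correlation construction without
  rate-independent synchrony this low-rate channel would be absent.
* Single neuron, excitatory inputs only; no dendritic structure, no
  inhibition, no changes in the number of release sites, no quantal
  variability of q beyond binomial site statistics.
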