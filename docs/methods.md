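# Methods

`topoplast` simulates topographic-map formation between two 16×16 sheets of
neurons ("source" and "target") whose feedforward and lateral connectivity
is shaped by two continuously operating plasticity processes: additive
pair-based STDP on existing synapses, and a structural rewiring rule that
forms synapses distance-dependently and removes them weight-dependently.
This note documents the model, the choices the implementation makes where
the design was genuinely open, and what the tests do and do not establish.

## Geometry

Neurons sit at integer coordinates on a rectangular grid with periodic
boundary conditions; grid spacing is 1 unit and ids map row-major
(`id = y·width + x`). All distances are Euclidean with per-axis wrap
`min(|Δ|, L−|Δ|)`, and the two layers are treated as spatially coincident,
so one metric serves both projections. Only distances enter the model, so
the choice of origin and orientation is immaterial.

## Neuron model

Conductance-based leaky integrate-and-fire:

    τ_m dV/dt = (V_rest − V) + g_exc (E_exc − V) + g_inh (E_inh − V)

with dimensionless conductances (normalised by the leak conductance) that
decay exponentially (τ_exc = τ_inh = 5 ms) and jump by the synaptic weight
g_syn on spike arrival. Defaults: V_rest = V_reset = −70 mV, V_thr = −54 mV,
E_exc = 0 mV, τ_m = 20 ms, τ_refract = 5 ms, Δt = 1 ms, axonal delay 1 ms.

Integration is exponential-Euler: per step, V relaxes toward the
instantaneous steady state (V_rest + g_exc E_exc + g_inh E_inh)/(1+g_exc+g_inh)
with effective time constant τ_m/(1+g_exc+g_inh). This is exact for
conductances held constant over the step and stays within 0.1 mV of a dense
Runge–Kutta solution over 100 ms in the tests.

**Refractory semantics.** During the 5 ms refractory period the neuron is
clamped at V_reset and *receives no synaptic input*: conductance increments
arriving while refractory are discarded (existing conductance still
decays). This is the package default because it is what the model's
description of the refractory period implies, and because it reproduces the
reference Case 1 target rate (≈21 Hz; letting input accumulate instead
yields ≈28 Hz with other statistics unchanged). The accumulate variant —
the common behaviour of general-purpose simulators — remains available via
`NeuronParams(refractory_discard_input=False)`.

**E_inh.** The inhibitory reversal potential is a free parameter needed
only by the lateral-inhibition variant. The default −70 mV (= V_rest,
purely shunting inhibition) follows the common conductance-LIF convention;
sensitivity runs at −80 and −90 mV changed the inhibition-variant results
negligibly, because inhibitory fan-in self-limits (see below).

## STDP

Classical additive pair rule, all-to-all pairing via exponential traces:
Δw = +A₊·e^(−Δt/τ₊) for pre-before-post (Δt = t_post − t_pre > 0),
−A₋·e^(Δt/τ₋) for post-before-pre, 0 at Δt = 0, clipped to [0, g_max].
A₋ is derived from the depression/potentiation area ratio
B = A₋τ₋/(A₊τ₊); defaults A₊ = 0.1, B = 1.2, τ₊ = 20 ms, τ₋ = 64 ms,
g_max = 0.2. B > 1 biases toward depression, which the removal rule then
converts into pruning. Amplitudes are interpreted as fractions of w_max
(`absolute_update=True` switches to bare conductance increments).

**Timing details.** The trace bookkeeping consumes traces before
incrementing them within a step, so exactly coincident pairs contribute
nothing — a property test checks equality with the explicit double sum
over spike pairs. A spike reaches the neuron's own synapse instantly as a
presynaptic event but, with the default back-propagation delay, the
postsynaptic event is seen one step late; the self-pairing therefore lands
at lag 0 and drives nothing. Disabling `backprop_delay` makes every
self-spike a post-before-pre pair at −1 ms — the strongest possible
depression — and autapses are then driven to the floor and pruned; the
flag has no significant effect on anything else.

**Inhibitory synapses** (lateral-inhibition variant) are plastic by
default, with the same rule applied to the conductance magnitude
(`SimConfig(inh_plastic=False)` keeps them static). The plastic variant
both matches the reference behaviour better and produces the interesting
self-limiting dynamics: inhibitory lateral synapses end up anticorrelated
with their targets, are depressed, and prune down to a small persistent
population (~4 per neuron) that still bounds the target rate.

## Structural rewiring

At f_rew = 10 kHz and Δt = 1 ms, 10 attempts run per step (slow rewiring:
one attempt every ⌊1000/(f_rew Δt)⌉ steps). Each attempt draws one target
neuron and one of its S_max = 32 slots uniformly:

* **Empty slot — formation.** A partner is drawn uniformly from the
  neurons that spiked in the *previous* step, pooled over both layers
  (abort if none); a uniform draw avoids any index bias. The synapse forms
  with probability p_form·exp(−δ²/2σ_form²) — feedforward: p = 0.16,
  σ = 2.5; lateral: p = 1, σ = 1 — at full strength g_max, delay 1 ms.
* **Occupied slot — elimination.** Removal probability p_elim_dep = 0.0245
  if g_syn < θ_g = g_max/2, else p_elim_pot = 1.36×10⁻⁴ (a ~180-fold
  preference for pruning depressed synapses). Nothing is formed in its
  place within that attempt.

All attempts in a step see the same previous-step spike pool and mutate
the table sequentially in attempt order. Probabilities are evaluated in
double precision directly from the kernel. The slot capacity bounds fan-in
at 32 (12.5% of one-layer all-to-all); with formation and removal in
equilibrium, occupancy settles near 10–11%.

Connectivity fractions are always reported against the one-layer
all-to-all count N² = 65 536 (so a full table is 12.5%), matching how the
capacity is quoted as "12%" in the literature the model follows.

## Input

A layer of Poisson sources. Uncorrelated protocol: every neuron at
f_mean = 20 Hz. Correlated protocol: a Gaussian bump
r(i) = f_base + f_peak·e^(−δ(s,i)²/2σ_stim²) with f_base = 5 Hz,
f_peak = 152.8 Hz, σ_stim = 2; the centre s is redrawn uniformly over the
256 grid positions every t_stim = 20 ms. The default peak keeps the
layer-mean rate at exactly 20 Hz; `rescale_f_peak` recomputes the peak for
any σ_stim from the torus Gaussian sum, so sweeps hold the mean input rate
fixed (σ_stim = 0.5 pushes the peak neuron above 2 kHz).

Spikes are sampled per 1 ms step with probability 1 − e^(−rΔt) and at most
one spike per neuron per step, mirroring the one-event-per-step resolution
of address-event systems; the cap is only material in the punctiform-bump
corner.

## Initial connectivity

* `topographic` — for each target neuron, partners are drawn uniformly and
  accepted through the formation kernel until 16 feedforward + 16 lateral
  afferents exist (rejection sampling reproduces the kernel's acceptance
  law exactly); weights start at g_max. Multapses arise freely and lateral
  autapses are expected (p_form_lat = 1 at δ = 0). One shared map (one
  seed) is reused across validation trials.
* `random_p` — round(p·n/2) feedforward plus as many lateral partners per
  neuron, uniform over the grid (p = 0.10 → 13 + 13).
* `one_to_one` — a single feedforward synapse from the co-located source
  neuron; `empty` — no synapses (formation builds everything).

## Receptive-field metrics

For a target neuron with afferents at positions x_i and weights w_i, the
preferred location is the candidate x minimising the weighted spread

    σ_aff(x) = sqrt( Σ w_i δ(x, x_i)² / (2 Σ w_i) ),

searched in two stages: all integer grid locations, then a 0.1-unit
lattice within ±1 unit of the integer winner (ties break in row-major scan
order; the ±1 window covers the integer lattice spacing, and a brute-force
full-lattice oracle test bounds the error at 0.05). The divisor 2 makes
σ_aff a per-axis standard deviation — an isotropic field with per-axis
width s measures σ_aff ≈ s — which is the normalisation under which the
generated initial map reproduces the reference values (mean σ_aff ≈ 2.35,
AD ≈ 0.81 for σ_form−ff = 2.5). AD is the plain toroidal distance from the
preferred to the ideal location (the co-located source neuron for
feedforward fields, the neuron itself for lateral ones).

Weighted variants use g_syn; "conn" variants set weights to one, so
multapses count with multiplicity. Neurons with no afferents of a
projection are excluded from means (their count is reported). Shuffled
controls: weight shuffling permutes a neuron's weights within the same
projection (preserving topology and the weight multiset); connectivity
shuffling regenerates each neuron's per-projection synapse counts through
the formation sampler. Paired per-neuron comparisons use two-sided
Wilcoxon signed-rank tests (identical vectors report p = 1).

## Engine

Per step, in fixed order: stimulus relocation/sampling → delivery of the
previous step's spikes through the 1-step delay ring (conductance
increments + STDP depression at arrivals, potentiation at visible
postsynaptic spikes) → membrane integration → the rewiring batch against
the previous step's pooled spike set → recording. One seeded generator
drives all randomness; identical configuration and seed reproduce rasters,
event logs and snapshots bit-for-bit. Conductance increments are applied
before the decay within a step. The batched rewiring in the engine draws
random numbers in exactly the same order as the single-attempt module
function and is its vectorised form; a test replays the logged event
stream onto the initial table and requires it to reproduce the final
connectivity exactly.

Snapshots are taken at t = 0, at the configured interval (default 12 s)
and at the end. Rewiring events are logged per non-abort event and can be
aggregated into 3 s formation/removal chunks; population rate series use
1.2 s chunks.

## Experiment suite and reference behaviour

* **Validation (Cases 1–3, 300 s, shared topographic map).** Case 1
  (STDP + rewiring + correlated input) refines mean σ_aff−conn from ≈2.35
  to ≈1.6–1.7 and σ_aff−weight to ≈1.5, with target rate ≈21 Hz,
  feedforward fan-in ≈15.7 and mean weight ≈0.81 g_max. Case 2 (no
  rewiring) freezes connectivity while STDP alone reaches σ_aff−weight ≈
  2.0 and a distance-weight profile falling with distance. Case 3
  (uncorrelated input, excitatory lateral) refines σ but the deviation AD
  rises — the instability signature: lateral excitation sustains target
  activity that competes with the feedforward projection.
* **Development (600 s, from one-to-one or random 10%).** Occupancy grows
  to a ≈11% plateau (hard bracket [6%, 12.5%] set by the capacity and the
  formation/elimination balance), feedforward fan-in ≈18, final
  σ_aff−conn ≈ 1.5–1.6.
* **Lateral inhibition (Case 3 input, 600 s).** Bounded target rate
  (~8–9 Hz, no escalation), stable map: σ_aff−conn converges slowly to
  ≈1.9, AD_conn ≈ 0.75. The reference single-trial value for this
  variant's spread is somewhat lower (≈1.74); the trajectory here is still
  decreasing at 600 s, and the exact level is the one quantity of the
  suite where this implementation and the reference runs differ by more
  than the usual trial spread. The experiment duration is 600 s
  because the variant's qualitative signature (feedforward fan-in
  collapse to ≈5 in the excitatory control) only completes on that
  horizon.
* **Sweeps.** Single-run grids over (B, τ₋) and (σ_stim, σ_form−lat), each
  cell seeded as seed_base ⊕ cell index so execution order is irrelevant.
  A mapping is flagged unstable when final feedforward fan-in < S_max/4 or
  the last-tenth population rate exceeds 5·f_mean (an operational proxy
  for "self-sustaining activity").

## What the synthetic conditions do and do not show

All inputs are generated (Poisson sources, seeded initial maps); there is
no recorded biological data anywhere. Passing tests therefore demonstrate
that the *mechanism* — competitive Hebbian refinement embedded into
connectivity by weight-gated structural turnover — behaves as described
under the stated idealisations: point neurons, a single stimulus bump,
one-step delays, a rigid slot capacity, and stationary input statistics.
They say nothing about biological topographic maps beyond the model's own
claims, and the punctiform-stimulus corner depends on the one-spike-per-
step sampling cap.

## Numerical and scale choices

Default validation runs use 300 simulated seconds and development/
inhibition runs 600 s, the horizons on which the respective statistics
plateau; trial counts default to 1 for table-style reports and 10 for
mean ± SEM aggregates. The acceptance script runs single trials for the
long simulations and three seeds for the (fast) initial-map statistics.
Weights are double precision throughout; probabilities are evaluated
exactly rather than through lookup tables. Degenerate inputs are defined:
empty afferent lists are excluded from metric means, an empty spike pool
aborts a formation attempt, and a zero-rate stimulus yields a silent,
structurally frozen network.

## Known limitations

Single stimulus bump (no binocular/two-source input); no distance-based
delays; no triplet or homeostatic STDP; the rewiring attempt schedule is
timer-driven, not spike-driven; layers must share one grid shape. The
lateral-inhibition spread discrepancy above is the one known quantitative
gap to the reference results.
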