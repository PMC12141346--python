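# Methods

This note documents the model implemented by `rlsm`, the choices made
where the design was genuinely open, and what the synthetic benchmark
does and does not establish.

## Neuron and synapse dynamics

All neurons are leaky integrate-and-fire units,
`tau_m dV/dt = -(V - V_rest) + R_m I(t)`, integrated by forward Euler at
`dt = 1 ms` (configurable). Defaults: `tau_m = 20 ms`, `R_m = 30`
(dimensionless gain), `V_th = 15 mV`, `V_rest = 0 mV`. A spike is
recorded at the end of the step in which `V` crosses threshold; the
potential hard-resets to `V_rest` and the neuron is refractory for
`t_ref = 2 ms` (a conventional default; the closed-form unit tests set
`t_ref = 0`). Forward Euler is first-order, and the suite verifies the
subthreshold trajectory converges to the analytic solution with O(dt)
error.

Synaptic transmission is an exponential postsynaptic-current kernel:
each spike adds its weight to a current decaying with `tau_syn` (5 ms
excitatory, 10 ms inhibitory). Spikes emitted at step `t` reach
recurrent targets at `t + 1` (one `dt` of axonal delay); external input
spikes inject in their own step. A stochastic facilitation/depression
model (Bernoulli release with activity-facilitated probability and a
depletable, exponentially recovering resource pool) is available behind
the same interface to enrich reservoir dynamics with probabilistic
release; the deterministic kernel is the default so that every
acceptance-relevant computation is exactly reproducible.

## Reservoirs

Each liquid has 135 LIF neurons on a 15x3x3 integer grid, split exactly
108 excitatory / 27 inhibitory. Ordered pairs connect independently
with probability `C_xy exp(-(d/lambda)^2)` (Euclidean grid distance,
`lambda = 2`, base probabilities EE|EI|II|IE = 0.3|0.2|0.1|0.4 indexed
pre->post). Weight signs follow the presynaptic type; magnitudes are
Uniform(0.05, 0.15) — unspecified by the underlying model, chosen to
keep the reservoir subcritical (no self-sustained activity without
input) at the default drive. Input channels project only to excitatory
neurons with probability 0.3 at weight 0.5. A Monte-Carlo test over
1,000 seeded builds confirms the realized wiring frequencies track the
distance rule within 3 binomial standard errors at every cell whose
expected count supports a normal-approximation band (n*p >= 5; below
that the band is narrower than a single count and the check is
ill-posed).

The two reservoirs share parameters but use independent structure seeds.
The second reservoir's "input channels" are the WTA winner neurons
(probability 0.3, weight 0.5), which keeps the WTA->liquid-2 projection
inside the ordinary input-wiring contract.

## WTA layer and the three-factor rule

The WTA layer has 20 excitatory winner neurons (one per SHD class; the
count is configurable and deliberately exceeds the 3 classes of the
synthetic task) and 5 inhibitory interneurons. Winners excite all
interneurons (weight 1.5) and interneurons inhibit all winners (weight
-3.0); these two magnitudes were set so that the layer is active but
sparse under default reservoir drive — disabling inhibition measurably
increases winner spike counts, which a test asserts.

Plasticity on the all-to-all reservoir->winner projection:

* `x_pre` decays with `tau_pre = 300 ms` and jumps by 1 per presynaptic
  spike.
* When winner `j` fires: `dw_local = eta (x_pre - x_tar)(w_max w)^mu`
  with `eta = 1e-4`, `x_tar = 20`, `w_max = 1`, `mu = 1`. The literal
  `(w_max w)^mu` factor is the default; a `weight_dependence =
  "conventional"` switch selects the soft-bound `(w_max - w)^mu` form
  for comparison.
* The update is folded into `w` (clamped to `[0, w_max]`), and the
  winner's afferent column is immediately renormalized to
  `alpha = 15` (synaptic scaling), then clamped again. The final clamp
  can in principle bind when scaling pushes a single weight past
  `w_max`; with 135 afferents summing to 15 this does not occur in
  practice, and the instrumented training run asserts column sums stay
  at `alpha` to 1e-9 relative tolerance after every update.
* `e_trace` decays with `tau_trace = 500 ms` and accumulates every
  `dw_local` — also when the local update is *not* applied to the
  weights (feedback phase), where it is the only record of recent
  correlations.

Per-sample bookkeeping: `x_pre` and `e_trace` reset at sample
boundaries, so the end-of-sample eligibility snapshot reflects only the
sample just processed (a carry-over flag exists).

Update order within a step is fixed and mirrored by an independent
scalar oracle test: decay `e_trace`; decay/increment `x_pre`; update
synaptic currents (this step's presynaptic spikes feed forward, the
previous step's winner/interneuron spikes carry the lateral loop);
integrate neurons; then apply local updates for winners that fired.

## Reward system

After each feedback-phase sample the readout's prediction is compared
with the label. On a match (any rewarded mode) every synapse receives
`k * e_trace`, is clamped, and columns are rescaled to `alpha`. The
scale `k` maps the sample's peak `|e_trace|` to the homeostatic mean
weight `alpha / n_pre`: eligibility magnitudes (~1e-3 under the default
constants) are otherwise far below the weight scale and the reward path
would be numerically inert; a fixed `k` can be configured instead. On a
miss, `strict` mode shrinks every plastic weight by `gamma w` with
`gamma = 1e-5 = eta/10` (only "much smaller than eta" is prescribed);
`forgiving` does nothing. The strict decay is *not* followed by
rescaling — a uniform multiplicative shrink per column would be exactly
cancelled by renormalization to `alpha`, so rescaling is re-applied only
after reinforcement updates, which restores the column sums.

During the feedback phase local updates feed the eligibility trace only
and the reward path owns the weights. This makes the `none` mode a true
baseline (weights bit-identical through phase 2) and matches the reading
of the global update as the sole weight path once feedback begins; a
flag restores online local updates in phase 2.

## Readout and protocol

Features are per-neuron firing rates (Hz) of the second reservoir over
one sample; the classifier is multinomial logistic regression (L-BFGS,
tolerance 1e-6), with argmax prediction and ties broken toward the
lowest class index. One pass is made over the seed-shuffled training
split; feedback starts halfway (`feedback_onset_fraction = 0.5`). The
phase-1 readout is fitted on the features collected during phase 1 and
frozen while it drives rewards. Before test evaluation the readout is
refitted on all training samples with features *recomputed under the
final frozen weights*: fitting on features collected while the weights
drifted mixes incompatible representations and systematically penalizes
exactly the modes that learn in phase 2 (measured: forgiving 0.585 vs
none 0.659 with stale features; 0.689 vs 0.633 with recomputed ones).

Across seeds the reservoir structure is fixed while WTA initial weights
(Uniform(0, w_max), column-scaled to `alpha`) and sample order are
re-randomized; since the first reservoir is deterministic given the
dataset, its per-sample rasters are computed once and shared across
runs — a pure cache with no effect on results.

## Synthetic benchmark

The generator emulates the structure of event-based spoken-digit data:
each class owns a fixed random template of (channel, time) events drawn
per channel as Poisson processes at 20 Hz; samples apply 20 ms Gaussian
jitter, 20% per-event dropout, and 5 Hz per-channel Poisson background.
The 20 Hz template rate was chosen so that the hottest reservoir
neurons' presynaptic traces straddle `x_tar = 20` (about 12% of
(sample, neuron) pairs above target) — the regime the learning constants
presuppose; at substantially lower drive `x_pre` never reaches the
target and every local update is depressive, leaving the eligibility
trace without class structure. Defaults: 4 classes (the replication
task uses 3), 70 channels, 40 training and 15 test samples per class,
300 ms samples. Train and test share class templates but draw disjoint
noise.

What the benchmark shows: the full pipeline — reservoirs, WTA with the
three-factor rule, reward gating, readout, statistics — runs end to end,
and reward feedback (both modes) improves test accuracy over the
unsupervised baseline in the mean over 20 seeds, with a significant
one-sided Mann-Whitney comparison. What it does not show: performance
on real speech. The templates have no phonetic micro-structure, no
variable sample durations, no speaker variability, and the problem is
far smaller than the 20-class, 8,156-sample benchmark; absolute
accuracies and effect sizes here do not transfer. The SHD loader and
CLI support running the identical protocol on the real dataset.

## Numerical and statistical choices

* All simulation state is float64; non-finite potentials, currents or
  eligibility traces raise immediately rather than propagate.
* Synaptic scaling of an all-zero afferent column (a dead winner) is a
  hard error by contract; the multiplicative literal update form cannot
  reach it from valid initial weights.
* Mann-Whitney U uses midranks for ties. Small instances are exact:
  tied pools are enumerated over all group assignments (up to 2e5
  combinations); tie-free small instances use the exact count
  distribution. Larger instances use the tie-corrected normal
  approximation with continuity correction. The enumeration bound
  exists because exact enumeration at, e.g., 20-vs-20 (~1.4e11
  assignments) is not computable; the replication's 20-seed comparisons
  therefore use the asymptotic path, standard practice at that size.
* Problem sizes were scaled to desk scale deliberately: 3 classes,
  120/45 train/test samples, 20 seeds per mode (~10 minutes total).
  The per-seed pairing of initial weights across modes follows the
  original protocol of comparing feedback mechanisms on identical
  initializations.

## Known limitations

* The exact stochastic synapse formulation the architecture was
  originally built on lives in an external reference; the implemented
  facilitation/depression model is a documented stand-in preserving its
  qualitative role, and the deterministic kernel is used everywhere
  results must be exact.
* `mu`'s value and role are underdetermined in the source material
  (`mu = 1` literal form by default; both readings are one flag apart).
* Strict decay applies to all plastic synapses; a flag restricting it to
  synapses with nonzero eligibility exists but is untested science.
* Single-epoch training; epoch count is configurable but the protocol
  was only studied at one pass.
* The replication follows the original protocol of holding the dataset
  fixed while re-randomizing initializations across trials. The size
  (and occasionally the sign) of the feedback benefit varies across
  synthetic template draws: probing five alternative dataset seeds at
  six runs each gave mean gains between about -11 and +9 percentage
  points. The reported comparison is therefore a qualitative statement
  about the default study conditions, not a claim that feedback helps
  on every possible task instance.
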