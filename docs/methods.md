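# Methods

This note documents the model implemented by `spikecolearn`, the parameter
choices that matter, and what the synthetic benchmark does and does not
demonstrate.

## Pipeline overview

An input digit passes through four stages:

1. **Feature extraction.** Four fixed oriented kernels (horizontal,
   vertical, two diagonals; band weight +1, elsewhere 0) are
   cross-correlated with the image (valid mode, stride 1; no kernel flip —
   the kernels are near-symmetric, so the convention is cosmetic but stated
   for reproducibility). Each raw map is max-pooled with non-overlapping
   windows, dropping incomplete border rows/columns, so a 28-side image
   with kernel k and pool p yields 4·⌊(29−k)/p⌋² channels — 576 for the
   default k=4, p=2.
2. **Latency coding.** Pooled features are min–max rescaled to [0, 255]
   jointly across the four maps, converted to a raw delay in [0, 255] by
   the configured coder (default `linear`: delay = 255 − V; exponential,
   inverse and power variants are pluggable pure functions), then mapped
   linearly onto the simulation window [0, 100 ms). Brighter features
   always fire earlier; each channel spikes at most once.
3. **Cluster simulation.** Each cluster's decode layer is 10 LIF neurons
   fully connected to the channels. Simulation is clock-driven
   (dt = 0.1 ms) and fully deterministic.
4. **Decoding.** The second decode layer is a deterministic spike-count
   accumulator: layer-2 neuron j sums the spike counts of every cluster's
   layer-1 neuron j. Prediction is the argmax; ties break by earliest
   first-spike across clusters, then lowest index. Implementing layer 2 as
   an accumulator rather than more LIF neurons is a deliberate choice: it
   is the simplest contract that interprets the clusters' output, and it is
   exactly testable. Evaluation never injects teacher signals.

## Neuron model

Membrane dynamics follow `τ_m dv/dt = −(v − v_rest) + R·I(t)` with spike,
reset and absolute refractory period. Input spikes inject exponentially
decaying currents (`psc_tau`), weighted by the (alive) synapse. Defaults
are textbook values: τ_m = 10 ms, v_rest = −65 mV, v_thresh = −50 mV,
v_reset = −70 mV, t_ref = 2 ms, psc_tau = 2 ms, R = 1 mV per weight unit.
All are exposed in the run configuration.

The cluster simulator propagates the exponential-PSC convolution exactly
over each step (the membrane trajectory samples the continuous solution at
grid points), so halving dt changes spike placement only through event
binning; the per-neuron `step_lif` uses the generic exponential-Euler step
with zero-order-held current, which is exact for the free decay used in
the closed-form tests. A single synapse of weight w produces a peak
depolarization of `R·w·τ_s/(τ_m−τ_s)·(e^(−t*/τ_m) − e^(−t*/τ_s))` ≈
0.134·R·w mV, which the test suite uses to verify the threshold boundary
analytically.

## Bipolar supervised learning

Training one labelled spike train is a closed loop:

1. simulate teacher-free; record the fired set M;
2. if M = {label}, stop (converged);
3. build teacher signals — one encouraging signal for the label neuron
   (70 ms), emitted whether or not it fired, and one punishing signal
   (35 ms) per erroneously fired neuron;
4. update weights and repeat, up to `max_inner_iters` = 50.

The update rule is pair-based additive STDP shaped by the teachers:

* **Encouragement** potentiates each alive synapse onto the label neuron
  by the causal kernel against the forced post-spike:
  `Δw = a_plus · exp(−(t_teach − t_pre)/τ_plus)` for every input spike
  before the teacher time. Input spikes after the forced spike contribute
  nothing (the forced spike is a reward event, not evidence against later
  inputs), so an encouraging signal can never reduce the summed weight
  onto its target.
* **Punishment** depresses each alive synapse onto an erroneously fired
  neuron by `punish_scale · |stdp_delta(pre, actual posts)|`, removing
  drive in proportion to how strongly that synapse's timing explains the
  erroneous spikes. A punishing signal can never increase the summed
  weight onto its target.

Two design points deserve emphasis, because they make the loop's
convergence criterion meaningful:

* The fired set M is recorded **teacher-free** each iteration. The teacher
  currents themselves (suprathreshold depolarizing pulse at 70 ms; strong
  hyperpolarizing pulse at 35 ms) are fully implemented in the simulator,
  but a punishing current suppresses exactly the spikes whose anti-STDP
  depression drives learning, and a loop conditioned on teacher-laden
  firing can report convergence that disappears the moment the teachers
  are removed. Conditioning on teacher-free behaviour makes
  "converged ⇒ the net, unaided, fires only the label neuron" true by
  construction.
* The encouraging signal is always emitted for the label neuron, even when
  it did not fire: the forced post-spike is the only mechanism that can
  potentiate a silent label neuron.

### Plasticity parameters

Defaults: a_plus = 0.2, a_minus = 0.1, τ_plus = τ_minus = 20 ms,
w ∈ [−50, 50], punish_scale = 0.5, initial weights uniform on [0, 5].
Three of these are load-bearing and were chosen from the failure modes of
the obvious alternatives:

* **Amplitudes** of 0.2/0.1 make one update a first-order correction.
  Amplitudes large enough to flip a decode neuron in one or two updates
  turn per-sample convergence into last-sample dominance: each sample's
  inner loop rewrites the layer and held-out accuracy collapses.
* **punish_scale = 0.5** compensates for an asymmetry of the anti-STDP
  magnitude: `|stdp_delta|` is dominated by the causal (a_plus) term, and
  several neurons are punished for every one encouraged, so unscaled
  punishment removes drive much faster than encouragement rebuilds it and
  the trained net drifts toward silence.
* **A negative weight floor** (w_min = −50) is required, not cosmetic:
  some classes activate a strict superset of another class's channels (an
  all-segments glyph contains every stroke of a plainer one), and a
  threshold unit with non-negative weights cannot fire on the subset class
  while staying silent on its superset. Repeated punishment carves
  effectively inhibitory weights on the surplus channels, which is exactly
  the anti-feature such pairs need.

### Encoding contrast floor

Channels whose rescaled feature intensity falls below
`min_intensity` = 20 (raw units of 255) emit no spike. Without the floor,
background noise puts nearly every channel's spike at the tail of the
window; those spikes carry no class information, yet the inner loop must
silence them anew for every sample, and the resulting depression swamps
learning. The floor keeps trains sparse (roughly 100–300 events of 576
channels on the synthetic data) and is consistent with the strongly
contrast-enhanced feature maps the oriented kernels are meant to produce.
Strokes crossing an oriented band score an order of magnitude above the
floor, so no real feature is lost.

## Structural learning

After a cluster's training passes, synapse i is eliminated iff
`|W(i) − W_init(i)| < w_change` (strict, so threshold 0 prunes nothing).
`W_init` is the construction-time snapshot and is never refreshed, and
pruning only clears the alive mask — weights are untouched — which makes
pruning idempotent, monotone in the threshold, and exactly equivalent to
zeroing the weight as far as simulation is concerned. A dead synapse is
never updated again. `prune_sweep` applies each threshold of a grid to a
fresh copy of a trained ensemble and reports accuracy, surviving-synapse
count and proportion per row. The sweep is mechanism-faithful, but its
threshold units are tied to this package's weight scale and are not
directly comparable to thresholds reported for other simulators' weight
conventions.

## Ensemble training

`train_ensemble` encodes the training set once, builds T structurally
identical clusters, draws T bootstrap subsets (sampling with replacement,
`n_sub` samples each), and trains cluster t on subset t for `iterations`
passes (default 3; the third pass still improves accuracy noticeably).
Cluster t's weights are initialized from a sub-seed derived as
(seed, t), and training one cluster touches nothing else, so the result is
independent of training order and safe to parallelize. Defaults follow the
cluster-count and subset-size working point of the underlying method:
T = 15, n_sub = 1000.

## Synthetic data

`synth_digits` renders each class as a fixed seven-segment-style stroke
glyph (intensity-255 strokes, 2-pixel thickness, on a black field),
translated by up to ±1 pixel per axis and overlaid with clipped Gaussian
pixel noise (σ = 10 intensity units). The generator is deterministic per
seed and byte-identical across platforms. It emulates the gross statistics
the encoder cares about — bright oriented strokes on a dark background,
28×28, 10 classes — but **not** the within-class shape variability, stroke
thickness variation, or curvature of handwritten digits. Accuracy on this
benchmark therefore demonstrates that the co-learning machinery works
(encoding separates the classes, the bipolar rule converges, pruning
preserves function at moderate thresholds); it does not predict accuracy
on handwritten data, for which the `train`/`eval`/`prune-sweep` CLI accepts
user-supplied MNIST IDX files.

Benchmark problem sizes used by the test suite: a 10-class disjoint-channel
fixture (one constructed spike train per class) for exact convergence
properties, and a T = 3 ensemble with 300-sample bootstrap subsets over
1,000 synthetic digits (100 per class), evaluated on 200 held-out digits —
about a minute of training on one core, reaching ~95% held-out accuracy.

## Numerical and edge-case conventions

* Spike times are stamped at the start of the crossing step and always lie
  in [0, window). Refractory neurons clamp to v_reset and ignore input.
* `stdp_delta` treats simultaneous pre/post spikes (Δt = 0) as
  depressing, matching the strict "pre before post" causality condition
  for potentiation; empty trains contribute zero.
* A sample whose inner loop hits the iteration cap is logged and reported
  as non-converged — an outcome, not an error.
* If no decode neuron fires anywhere during decoding, the prediction falls
  back to label 0 and is flagged `no_spike`.
* An image whose feature stack is constant encodes to an empty spike
  train.
* Accuracy is accumulated in exact rational arithmetic and reported as a
  percentage rounded to two decimals.

## Known limitations

* Teacher signals act on the plasticity rule through their idealized
  effect (forced post-spike time / natural-spike depression); the injected
  current path, while implemented and tested, is not used by the default
  training loop.
* The main processing layer relays encoded events directly to the decode
  synapses rather than re-spiking them through its own LIF dynamics; no
  dynamics or learning are defined for that layer, so a relay is the
  minimal faithful reading.
* No synaptogenesis: structure only ever loses synapses.
* Single-layer feature extraction by construction; kernels are fixed, not
  learned.
* The per-sample inner loop optimizes to zero margin on the current
  sample; generalization rests on small learning rates, multiple passes,
  and ensemble averaging rather than on any explicit margin objective.
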