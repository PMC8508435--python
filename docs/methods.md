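# Methods

This note records the model, the protocol, the synthetic data model, and
the numerical/design choices the package makes where the design was
genuinely open.

## Model

The classifier maps an RGB image (pixels scaled to [0, 1], bilinear
resizing where needed) through a convolutional stem to a set of primary
capsules, then through one densely connected capsule layer to two class
capsules whose norms are the class scores.

**Full geometry (299×299×3).** Stem: conv 32/3×3/s2 → conv 32/3×3 →
conv 64/3×3 (same padding) → maxpool 3×3/s2 → conv 80/1×1 →
conv 192/3×3 → maxpool 3×3/s2 → conv 512/9×9/s2 (linear).  Each
convolution except the last is followed by batch normalisation and ReLU;
paddings are valid except the third convolution, whose size-preserving
behaviour forces same padding.  The 14×14×512 output is reshaped into
6272 16-D primary capsules, squashed, and routed (one iteration) into two
64-D class capsules.  The shape engine (`compute_layer_shapes`) verifies
this arithmetic without allocating weights.

**Reduced geometry (48×48×3).** The full stem cannot process 48-px input
(the 9×9 stride-2 final convolution underflows under valid padding), so
the reduced configuration keeps the stem structure with filter widths
8/8/16/20/48 and a 3×3 final convolution into 256 channels, giving 16
primary capsules of 16-D.  This is the configuration used for CPU-scale
experiments and most tests.

**Routing.** Coupling logits start at zero; each iteration computes the
softmax across output capsules per input capsule, aggregates the votes,
squashes, and (on all but the last iteration) adds the scalar agreement
`û·v` to the logits.  The reported configuration uses a single iteration,
in which the coefficients remain uniform by construction; this is
implemented literally.

**Loss.** Separate margin loss with `m⁺ = 0.9`, `m⁻ = 0.1`.  The
down-weighting `λ` of absent-class terms is not fixed by the protocol
description; the package defaults to 0.5 (the original capsule-network
convention) and exposes it.  A binary-cross-entropy-on-lengths mode is
selectable (`loss="bce"`), since the protocol description also mentions
binary cross entropy; margin loss is the default.

**Decoder.** An optional fully connected reconstruction head
(512 → 1024 → 56·56·3 sigmoid by default, loss weight 5e-4) reads the
class capsules with the non-target capsule zeroed (true class during
training, predicted class at inference) and adds a weighted
sum-of-squared-errors term against a downsampled copy of the input.  It
is off by default: classification results do not require it, and it is
exposed purely as an opt-in regulariser.

## Training engine

No tensor/autodiff framework is used; the engine is numpy with
hand-derived backpropagation (im2col convolution, batch normalisation,
max-pooling with argmax scatter, squash, capsule layer, length head).
Gradients are checked against central finite differences in the test
suite.  Within a backward pass the routing coefficients are treated as
constants of the forward pass — exact for one routing iteration (the
default), the standard approximation otherwise.

Numerical details:

* squash is computed as `s·‖s‖/(1 + ‖s‖² + 1e-12)`, an algebraically
  equivalent form that is exact at the origin; the same epsilon keeps the
  backward pass finite there.
* Softmax is max-stabilised.
* Batch norm uses epsilon 1e-3 and running-average momentum 0.9.  These
  are engine constants, not protocol values; the momentum is chosen so
  the inference-time statistics converge within the few hundred update
  steps of a desk-scale run (with 0.99 the running estimates lag the
  batch statistics badly at this scale and eval-mode predictions
  collapse).
* Xavier/Glorot-uniform initialisation throughout, from a single integer
  seed; building twice with the same seed is bit-identical.
* Optimizers: plain SGD (momentum 0 — no momentum value is part of the
  protocol), RMSProp (rho 0.9), ADAM (0.9/0.999), all with their
  protocol learning rates (0.01 / 0.001 / 0.001).

## Protocol

* **Balancing:** the minority class is oversampled with freshly augmented
  copies (sources drawn uniformly with replacement) until class counts
  differ by at most one; the majority class and the test fold are never
  touched.  Inside cross-validation, balancing is applied to the training
  portion only — required to avoid leakage.
* **Augmentation:** a draw combines rotation (default range ±180°,
  reflect padding to avoid black corners), independent horizontal and
  vertical flips, and a random crop of 80–100% of each side resized back
  bilinearly.  Crop parameters are package choices; the protocol names
  the transformation kinds but not their ranges.
* **TTA:** each test image yields 10 augmented replicates; the original
  participates in the vote alongside them (11 votes; a flag can exclude
  it).  Class-capsule lengths do not sum to one, so each view's pair of
  lengths is normalised by its sum (falling back to (0.5, 0.5) when both
  vanish) before the element-wise mean; an exact tie goes to nevus.
* **Plateau decay:** for SGD the learning rate is multiplied by 0.2 when
  the monitored quantity has not improved for `patience` epochs
  (default 10, floor 1e-6).  The monitored quantity is validation loss on
  a stratified 10% split carved from the training data — the protocol
  says "performance" without naming it.
* **Cross-validation:** 3 independent stratified 10-fold partitions;
  per-(repeat, fold) MCC and AUC rows are averaged.  Fold assignment,
  epoch shuffling and augmentation draws are all seeded.
* **Model selection:** methods are ranked per dataset (higher score →
  lower rank number, mid-rank ties); average ranks validate against the
  published optimizer-comparison row.  Borda aggregation assigns
  `M − 1 − position` points per ranking.  Per-dimension consensus orders
  of the 4×4 capsule-dimension grid are obtained by averaging the
  grid's average ranks over the configurations sharing a value; under
  this marginalisation the class-caps order reproduces the published
  64 > 32 > 48 > 16 exactly, while for primary caps it yields
  16 > 24 > 32 > 8 (published: 16 > 32 > 24 > 8) — best and worst agree,
  and the exact Borda input used for that row is not recoverable from the
  published grid.

## Synthetic data

The generator renders a radial-harmonic blob
`r(θ) = R(1 + Σ a_k sin(kθ + φ_k))` over a skin-tone background: harmonic
amplitudes control border irregularity, one half is radially inflated by
`asymmetry_shift`, and angular pigment patches control colour
variegation.  Nevi draw from low ranges (amplitude sum ≤ 0.04, asymmetry
≤ 0.05, ≤ 1 patch in light browns), melanomas from high ranges (0.12–0.22,
0.15–0.30, 3–6 patches in dark browns/black/red/blue-grey); `difficulty`
linearly interpolates the melanoma ranges onto the nevus ranges, so 0
means disjoint ranges and 1 indistinguishable classes.  Gaussian pixel
noise (default sd 0.02) is clipped to [0, 1].  All distributions are
package inventions, config-exposed so tests pin them.

What passing tests show — and do not show: the learning-capability
experiment (width-reduced network, 200 difficulty-0 images at 48 px,
10 epochs, held-out MCC ≥ 0.9 with TTA never costing more than 0.05, in
≥ 4 of 5 seeds) demonstrates that the architecture, loss, augmentation
and evaluation machinery learn and compose correctly.  It says nothing
about dermoscopy-scale performance: real lesions have hair, rulers,
specular artefacts, acquisition variation and far subtler class overlap,
none of which the generator simulates.

## Problem sizes

The default test suite and experiments use the reduced 48-px network,
30–200 synthetic images, and up to 10 training epochs — sizes chosen so
the full suite runs in well under a minute per experiment on one CPU
while still exercising every code path, including learning to a
non-trivial held-out criterion.  The full 299-px geometry is exercised
weight-free through the shape engine and is buildable (and trainable, at
commensurate cost) through the same API.

## Known limitations

* Training through more than one routing iteration uses the
  constant-coefficient gradient approximation.
* The numpy engine is single-threaded BLAS-bound; it is meant for
  desk-scale experiments, not for the full 11-dataset study.
* The pixel-space dataset statistics (intra-/inter-class distance,
  silhouette) depend on the distance space; the package fixes Euclidean
  distance on flattened [0, 255] pixels, which reproduces the order of
  magnitude of published per-dataset values but is not guaranteed to
  match them, since the space those were computed in is not specified.
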