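# Methods

## Overview

The package implements a two-stage lesion-analysis pipeline for grayscale
mammogram-like images — segmentation, then three-class typing — with both
networks' training hyperparameters chosen by a foraging-behaviour
metaheuristic. The primary experimental substrate is a synthetic phantom
generator; the pipeline also accepts images loaded through the MIAS/CSV
readers. This note records the modelling assumptions, the parameters that
matter, the numerical choices, and what the desk-scale experiments do and
do not demonstrate.

## Segmentation network

A U-Net with:

* **Encoder blocks** — residual multi-scale atrous units: the block output
  is `relu(IN(conv1x1(x) + Σ_d conv3x3_d(x)))` over dilation rates
  (1, 2, 4), where IN is instance normalisation. Parallel dilations
  realise the "multi-scale" element: each block sees neighbourhoods of
  three effective sizes at no extra depth.
* **Bottleneck** — one post-norm transformer encoder block over the
  flattened spatial tokens with a learned, zero-initialised positional
  embedding and multi-head self-attention (4 heads, reduced if the
  channel width is not divisible).
* **Decoder** — nearest-neighbour ×2 upsampling; each skip connection is
  gated by an additive attention gate (`skip * sigmoid(psi(relu(Wg·g +
  Wx·skip)))`) before concatenation.
* **Head** — 1×1 convolution to a single-channel logit map; sigmoid.

"Hidden neurons" (5–255) is interpreted as the base channel width; level ℓ
uses `width · 2^ℓ` channels capped at 512. The head is a sigmoid, not a
softmax, because the mask has a single foreground class.

**Training loss.** Dice loss (smoothing constant 1) plus binary
cross-entropy on logits. The hyperparameter fitness rewards exactly Dice
and pixel accuracy, and this pairing is the standard choice for mask
supervision. An epoch runs `min(steps_per_epoch, available batches)` Adam
steps (batch 4, lr 1e-2) over a seeded shuffle.

**Fitness S1 = 1/(Dice + Arcy)**, computed on a validation split with
Dice averaged per image (not pooled over pixels) and accuracy computed
pixel-wise against the ground-truth mask. A 0 denominator returns a 1e9
sentinel. The standalone `s1_objective` splits its input 80/20 by its own
seed; inside the pipeline, fitness is evaluated on the run's fixed
validation split instead.

## Classification network

A DenseNet over the fixed class order (normal, benign, malignant):

* dense blocks (3 blocks × 4 layers) whose 3×3 convolutions cycle through
  dilation rates (1, 2, 4);
* squeeze-and-excitation channel attention after every block
  (reduction 4) — the network's attention element;
* 1×1 + average-pool transitions halving channels and resolution;
* global average pooling into a 3-way softmax head.

"Hidden neurons" maps to the dense growth rate `g = max(4, hidden // 8)`,
the canonical DenseNet width knob; the stem emits `2g` channels. The input
is a **2-channel tensor (image, mask)**: the upstream segmenter's mask
localises the lesion while the raw image preserves appearance, and a
normal case degrades gracefully to an empty second channel. Classification
runs on the full frame, not a mask crop. Argmax ties break toward the
earlier class in the fixed order.

Training uses categorical cross-entropy, Adam, lr 1e-2, at the tuned batch
size. **Fitness S2 = 1/Arcy + XY** uses multiclass accuracy and the
malignant-vs-rest false-positive rate (textbook form) — malignant false
alarms being the clinically meaningful error. Arcy = 0 returns the 1e9
sentinel.

A linear-activation regression head is *not* implemented: no regression
target exists anywhere in the method's definition, so adding one would be
guesswork.

## The optimizer (MML-EOO)

Per-iteration schedule, for iteration r of R:

| quantity | formula | range |
|---|---|---|
| oyster size | `O = 5 − r·(2/R)` | [3, 5], linear decay |
| opening time | `J = ((O−3)/2)·10 − 5` | [−5, 5] |
| calorie gain | `Q = ((O−3)/2)·2 + 0.6` | [0.6, 2.6] |
| bird energy | `D = (r−1)/(R−1) − 0.5` for r > 1, else −0.5 | [−0.5, 0.5] |

The *current energy requirement* N has no closed form in the method's
description; it is identified with D, the only computed bird-energy
quantity. This makes `J + N` the exploitation/exploration switch and
reproduces the described sign behaviour (J and N negative late in the
run).

**Position update.** While `J + N > 0`:
`P ← P + O·f·(P_best − P)` with f drawn independently per dimension
(clamped to bounds). Otherwise the multiplicative update `P ← P·Q` is
applied in lower-bound-shifted coordinates (so no sign flips) and folded
back into the box by reflection, which is the appropriate boundary rule
for a multiplicative map that can overshoot. The composition of the two
update equations into a single loop is not uniquely recoverable from the
method's prose; this branch rule is the package's documented
reconstruction, consistent with a monotone cost curve under greedy
acceptance.

**Loop.** Uniform seeded initialisation; optionally the first candidate is
placed at the internal-bounds midpoint (used by the pipeline so the search
can never end worse than the mid-range default configuration — a
conventional "seed the default" practice). Per candidate, propose →
evaluate → keep the better; global best is elitist. The evaluation count
is exactly `pop·(iter+1)`. Fitness values are cached on the decoded
parameter tuple because decoding is many-to-one and an evaluation costs a
network training. The maximum-iteration symbol in the energy formula is
taken to be the same R as in the size schedule.

**Search-space codec.** Integer dimensions decode by nearest integer,
categorical dimensions by nearest 1-based index, ties rounding down (so
the midpoint of an even-length choice list decodes to the lower median);
continuous dimensions pass through with clamping. Continuous dimensions
exist for benchmarking the optimizer on standard test functions.

## Synthetic phantoms

Each sample emulates the statistical structure the method assumes, at a
configurable size (default 128×128; the recovery experiments use 64×64):

* **Breast region**: half-ellipse against a dark (0.02) exterior, chest
  wall at the left edge; semi-axes 0.88/0.44 of the image size.
* **Lumpy background**: Poisson-random impulses smoothed at three Gaussian
  scales (2, 4, 8 px at 128, scaling with size), normalised to mean 0.45,
  sd 0.07 inside the region — the standard stochastic stand-in for
  anatomical texture.
* **Lesions**: benign = radially symmetric steep-edged bump
  `A·exp(−(d²/r²)²)`; malignant = a 0.8r core plus 6–12 narrow radial
  spicules (width ≈ 0.012·size, length 1.6–2.6r) at 0.7A amplitude. Radii
  default to 5–11 % of the image size; peak contrast A defaults to 0.45.
* **Mask**: pixels where the noiseless lesion contribution exceeds half
  its peak; all-zero for normal samples. Lesion centres are rejected
  unless a 2.8·r_max disc fits inside the breast region, so masks always
  lie within it.
* **Noise**: additive Gaussian, sd 0.03, clipped to [0, 1].

The generator is deterministic given its seed (one child seed per
sample). It does **not** emulate pectoral muscle shadows, film artefacts,
dense-tissue heterogeneity, calcification clusters, or realistic lesion
texture; passing the recovery experiments therefore demonstrates that the
implementation learns and the pipeline is wired correctly, not that the
method attains any particular performance on clinical mammograms.

## Metric modes

The ten confusion-count metrics are served in two modes. `standard` is the
default and uses textbook definitions. `as_printed` preserves a variant
formula set (FPR = FP/(FN+FP), NPV = TN/(FP+TN), specificity =
TN/(FN+TP), F1 = 2·TP/(2·(TP+FP+FN))) so results computed under those
forms can be audited; the deviations are most plausibly transcription
slips, which is why they are not the default. Complement identities
(FNR = 1−sensitivity, FDR = 1−precision) hold in both modes. 0/0 cells
yield an `Undefined` float sentinel (serialised as `"undefined"`) rather
than raising, so batch reports stay machine-readable. Dice and Jaccard of
two empty masks are defined as 1.0 — perfect agreement on absence.

## Numerical choices

* Float64 throughout the autodiff engine; gradients validated against
  central finite differences (relative tolerance 1e-3 at step 1e-4, which
  is roundoff-dominated, not truncation-dominated).
* He-style initialisation from a per-model seeded generator; identical
  seeds give bit-identical weights, training traces and reports. Parallel
  conv branches are additionally rescaled by 1/√(#branches) so their sum
  preserves activation variance.
* Every residual conv block carries an instance norm (per-sample,
  per-channel spatial normalisation, no running statistics, hence
  deterministic and train/eval-identical). Without it, the few-step desk
  training stalls at many seeds: activation scales then depend on the
  init draw and the sigmoid head can start saturated. Decoder norms and
  the bottleneck layer-norms use a widened eps = 1e-2, bounding each
  norm's gain on near-constant fields at 10.
* The positional embedding is zero-initialised (it is learned during
  training). An untrained network therefore has no spatial symmetry
  breaker at all: a constant input maps to an exactly constant
  probability field, which is also a contract the tests assert.
* Adam (β = 0.9/0.999, eps 1e-8), lr 1e-2 for both networks.
* Mask threshold 0.5 by default; thresholds 0 and 1 behave as ≥
  comparisons.
* Dice-loss smoothing constant 1.0.

## Pipeline protocol

70/15/15 train/validation/test split. Hyperparameter fitness is evaluated
on the validation split only; the report on the test split only. Search
evaluations run under a reduced surrogate budget (default: ≤2 epochs, ≤8
steps/epoch) because the printed training ranges at ~500 evaluations are
not desk-feasible; the final models train at the full configured budget.
The two searches run sequentially (segmenter first), mirroring the
narrative order of the method; population is capped at 10 and iterations
at 50 unless explicitly overridden. All stage seeds are spawned from the
single run seed. Failures abort with the stage name and persist a partial
report.

Problem sizes used by the shipped experiments: 100 phantoms at 64×64 for
the recovery runs (five epochs, width 8 segmenter / width 32 classifier);
population 4 × 5 iterations with narrow ranges for the micro end-to-end
run; population 10 × 50 iterations for the optimizer benchmark on the 5-D
sphere and Rastrigin functions against equal-budget (510-draw) random
search.

## Known limitations

* Desk-scale training (tens of Adam steps) has visible seed-to-seed
  variance in final Dice; the recovery experiments fix their seeds as part
  of the study conditions.
* The optimizer's second half (the multiplicative exploration branch)
  rarely improves the best candidate; greedy acceptance makes it harmless
  but most progress happens in the exploitation phase.
* The MIAS reader rasterises centre+radius circles into discs — an
  explicit approximation of true lesion outlines, flagged per sample.
* Checkpoints store raw parameter arrays (npz + JSON sidecar); no
  cross-version migration is attempted.
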