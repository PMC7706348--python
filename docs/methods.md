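# Methods

## The segmentation model

The target class is small (~900 px² at the study's imaging geometry), much
brighter than its surroundings, and sparse (well under a third of the image).
Two complementary detectors are combined:

**Global Otsu threshold.** The 256-bin histogram of the luma image is split
at the level maximizing between-class variance ω₀ω₁(μ₀−μ₁)²; foreground is
the strictly-greater, high-intensity class. Assumptions: bimodality between
a bright target class and a darker background, and that brightness alone
over-segments (bright non-targets are expected and tolerated at this stage).
No morphological cleanup is applied — noise removal is the next stage's job.

**Patch-based CNN.** A binary classifier on 31×31×3 blocks, applied with a
sliding window, labels each pixel through the patch centered on it. The
window size is chosen to cover a whole average target, so the classifier
sees full context; the price is blocky boundaries (over-recognition around
true targets). Architecture: VGG-style 3×3 conv + ReLU stacks, 2×2/stride-2
max pooling after each block, fully connected layers ending in 2 softmax
channels. The default configuration is deliberately small —
conv 16 → pool → conv 32 → pool → fc 64 → fc 2 — sized for CPU training on
desk-scale data; the full-depth topology is expressible through `NetConfig`.

**Combination (Bin+CNN).** Pixel-wise AND of the two masks. It is the unique
operation that simultaneously "limits the threshold mask to where context
agrees" and "limits the blocky context mask to the threshold's contours".
Set-theoretic consequences (asserted in code and tests): TP and FP of the
combined mask never exceed those of either parent, so precision rises and
recall can only fall; the method wins when the parents' errors are disjoint
— contour noise for the threshold, boundary blocks for the classifier.

## Training recipe

Minibatch SGD with momentum on softmax cross-entropy: batch 100, momentum
0.9, initial learning rate 0.01, decay to 10% of the current rate when the
held-out validation error plateaus, at most 100 epochs. A seeded
`val_fraction` (default 0.2) split provides the validation set.

Two operational choices deserve note:

* **Plateau detection.** "Validation error stable" is read as
  `plateau_patience` (default 5) consecutive epochs without improvement.
  The detector arms only after the error has improved at least once:
  a freshly initialized network can sit at a saddle for many epochs with a
  *flat* validation error, and decaying there freezes training permanently.
* **Initialization scale.** Weights are Gaussian with zero mean and biases
  zero. The classical fixed σ = 0.01 is calibrated to full-width VGG layers
  (fan-ins of thousands); at the default desk-scale widths it attenuates
  activations ~20× per layer and stalls learning for dozens of epochs. The
  default is therefore fan-in-scaled σ = √(2/fan_in) per layer
  (`init_std="auto"`), which makes the initial signal scale
  width-independent; a fixed σ (e.g. 0.01) can be requested explicitly.

All arithmetic is float64 and every random draw comes from an explicitly
seeded generator, so training and inference are bit-reproducible on a given
platform. Max pooling routes gradients to the first arg-max of each window,
keeping the backward pass deterministic and finite-difference checkable
(the test suite verifies backprop against central differences at 10⁻³
relative error).

## Superpixels, merging, ground truth

Real-image training sets are anchored on regions: SLICO oversegmentation
(delegated to scikit-image, 10 iterations, adaptive compactness) followed by
greedy agglomeration of the region adjacency graph — repeatedly fusing the
adjacent pair with the smallest Euclidean distance between area-weighted
mean Lab colors until exactly the requested region count remains, ties
broken by the smaller label pair. The production configuration is 15,000
superpixels merged to 1,500 regions per image; tests exercise the same 10:1
ratio at desk scale. A connectivity post-pass guarantees the partition
contract (gap-free labels, 4-connected segments) regardless of library
internals; the returned segment count can deviate from the request (±20% is
typical; tiny requests on small images deviate more because minimum-size
merging dominates). Ground truth is superpixel-quantized: a mark anywhere
inside a flower lights up its whole superpixel.

Merged-region centroids are snapped to the nearest member pixel when a
non-convex region's centroid falls outside it, so a centered patch always
overlaps its region.

## The synthetic scene generator

Emulates the imaging regime, not the optics: a low-frequency Gaussian-field
canopy (green-dominant, luma clipped to [40, 140], correlation length 16 px),
anti-aliased elliptical flower clusters (vertical axis squashed ×0.75 to
mimic the camera's depression angle, ±2 px soft edge, luma 225–255), and
small bright distractors (4–40 px², same luma range as the flowers — they
are indistinguishable by pixel value, distinguishable by extent). Default
scene: 256×256 px, 5 flowers, 40 distractors.

Flower areas are lognormal with mean 900 px² and CV 0.45, clipped to
[300, 1980] px²: apparent cluster size varies strongly with distance and
viewing angle, and this variability is what teaches the classifier that
partially covered windows are still flowers. The *recorded* center of each
flower is a seeded draw from the inner 70% of its radius rather than the
exact centroid, emulating merged-region centroids, which do not sit at the
bloom's geometric center. Both choices matter: with uniform sizes and exact
centers the classifier never sees off-center bright mass, under-recognizes
boundaries, and the combination loses its premise.

Intense illumination multiplies all channels by 1.7 and clips, pushing the
background's bright tail into the flower range — the regime where a global
threshold degrades most. The generator guarantees (and tests assert) a
flower/background luma margin ≥ 60 levels under soft and ≥ 20 under intense
illumination.

All randomness flows from the scene seed through named substreams
(background, placement, colors, distractors, annotation), so extending one
stream never perturbs the others.

What the generator does *not* model: petal-level flower structure, occlusion
by leaves, large bright background objects (sky gaps, whole sun-lit
branches), temporal correlation across a time-lapse series, and camera
optics. Passing benchmarks here therefore demonstrate the method's internal
logic — that intersecting contours with context beats either alone when
their errors differ — not field-ready accuracy on plantation imagery.

## Benchmark protocol and problem sizes

The standard desk-scale protocol (`flowerseg.benchmark`): training set from
12 flower scenes (one positive per planted flower, ~60 positives) plus 4
flower-free scenes × 60 random negatives; default network trained 30 epochs;
evaluation on 20 fresh scenes per illumination regime with sliding-window
stride 4 (grid labels filled to the nearest center). Stride 1 is the
fidelity-maximizing setting; stride 4 is the protocol default and agrees
with stride 1 on ≥90% of pixels on these scenes. Training, evaluation and
scene seeds all derive from one benchmark seed via fixed offsets.

## Numerical details and edge cases

* Otsu ties (several thresholds attaining the maximum) return the smallest
  threshold — deterministic, and favors the larger foreground at the
  recall-preserving stage. Single-valued images are degenerate: threshold =
  that value, empty foreground, variance 0.
* Luma is rounded half-up; the grayscale projection is configurable
  (single channels available) with luma the default.
* Patches crossing the image border are completed by NumPy-style `reflect`
  padding (edge pixel not duplicated), identically in training and
  inference.
* Exact softmax ties (P = 0.5) classify as negative.
* Empty-vs-empty mask comparison scores F1 = IoU = 1 (agreement
  convention); any other zero denominator reports the metric as undefined
  (`None`/`null`).
* Masks serialize as {0, 255} single-channel PNG; {0, 1} files are accepted
  on read; files with more than two distinct values are rejected.
* Model checkpoints are zip archives of named parameter arrays with fixed
  timestamps, so identical parameters give byte-identical files.

## Known limitations

* The NumPy CNN is CPU-bound; full-resolution (1920×1080) stride-1
  inference is possible but slow — use stride > 1 or crop.
* The greedy Lab merge is one reading of "combining similar regions"; the
  original merging rule behind the 15,000 → 1,500 reduction is not
  specified in this package's sources.
* Superpixel counts are approximate by construction; requesting very few
  segments on small images can undershoot the ±20% band.
* The synthetic benchmark is a mechanism test, not a field validation (see
  above).
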