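# Methods

`deepcount` studies count regression without detection: a convolutional
network is trained exclusively on synthetic scenes with exact count
labels and predicts the number of fruit in an image as a single real
number, "at a glance". The package has four scientific pieces — the
scene generator, the counting network, the training recipe, and the
evaluation statistics — plus an area-based baseline that represents the
classical alternative.

## Synthetic scenes

A scene is rendered on a square canvas (default 128 px, 8-bit RGB) in a
fixed order:

1. **Background.** The canvas is filled with 40–80 green and brown
   circles of random size (5–25 % of the image side) and jittered color,
   then blurred with a Gaussian filter (σ = 2 px). This emulates
   defocused foliage and soil.
2. **Fruit.** The count is drawn uniformly from [1, 40]; each fruit is a
   disk with radius uniform in 3–12 % of the image side, colored ripe
   red (probability 0.7) or half-ripe orange, with per-fruit color
   jitter. Disks are shaded radially (darker rim) and carry a small
   specular highlight offset toward a global per-scene light direction;
   with probability 0.25 a fruit is darkened as if in shadow. Fruits are
   drawn after the blur, so their edges stay crisp against the soft
   background. Overlap arises naturally from draw order: later disks
   occlude earlier ones.
3. **Foliage occlusion.** With probability 0.2 per fruit, a green blob
   (0.6–1.3 fruit radii, centered 0.3–1.1 radii away) is drawn over the
   fruit layer.
4. **Illumination.** A smooth multiplicative brightness field
   (amplitude 0.3) modulates the whole image.

**Label semantics.** The label is the exact number of fruit disks drawn.
Occluded fruit count, provided at least `min_visible_fraction` (default
0.25) of the disk's pixels survive on top: visibility is measured by
pixel ownership (later fruit and occluders overwrite earlier pixels). A
fruit buried below the floor is re-placed at a fresh position and the
ownership map re-resolved, so labels never refer to invisible objects;
in pathological crowding the stubborn fruit is drawn last and its
occluder dropped. This keeps the supervision honest while still
producing heavily overlapped scenes.

**Determinism.** A scene is a pure function of (config, seed). Per-image
seeds are derived from the dataset master seed and the image index via
`numpy.random.SeedSequence`, so datasets are order-independent,
resumable, and byte-identical across reruns.

**What the generator does not emulate:** perspective and 3-D geometry,
leaves with realistic shape, specular soil, camera noise, color
constancy effects, green (unripe) fruit, and the domain gap to real
photographs. Passing tests on these scenes therefore demonstrate the
counting architecture and training recipe under controlled clutter, not
field performance on real images.

## Counting network

The network is a narrowed Inception-ResNet regressor. Stem: 7×7 conv
(stride 2, SAME, 64·wm maps) → 3×3 max pool (stride 2, VALID) → 1×1
conv (80·wm) → 5×5 conv (192·wm). Two modified Inception-ResNet-A
blocks follow; each runs three parallel branches (1×1 32·wm;
1×1 32·wm → 3×3 32·wm; 1×1 32·wm → 3×3 48·wm → 3×3 64·wm), concatenates
them, and projects back to the block width with a linear 1×1 convolution
(192·wm — the defining narrowing of the block) before the residual
addition and rectification. A reduction block (max-pool branch; 1×1 →
3×3 stride-2 middle branch at 128·wm; 1×1 192·wm → 3×3 128·wm → 3×3
128·wm → stride-2 3×3 128·wm right branch; all stride-2 stages VALID)
halves the spatial extent and widens the features by 256·wm. Two more
A blocks operate at 448·wm channels (their projections are forced to
448·wm by the residual shape constraint — the narrowing applies to the
pre-reduction blocks). Head: 3×3 average pool (stride 2, VALID) →
flatten → fully connected 768·wm → ReLU → dropout (keep 0.65) → fully
connected 1. Batch normalization follows every convolution; ReLU follows
every batch normalization except the linear projection inside the A
block. `wm` is a width multiplier (1.0 = full scale) that exists so the
same architecture can be exercised at desk scale.

Where the architecture has genuinely open details, the package fixes
them as follows: the stem's unspecified widths are 80 and 192 (the
latter forced by the first residual addition), the middle reduction
branch is 1×1(128) → 3×3(128, stride 2), the right branch kernels are
1×1 then 3×3s, the head average pool uses stride 2, and the hidden fully
connected layer is rectified before dropout.

The shallow comparison network is two convolutions and two fully
connected layers: 5×5/2 conv (16) → 3×3/2 max pool → 5×5 conv (32) →
3×3/2 max pool → fc 64 → fc 1, with batch normalization after each
convolution. It is deliberately small: it represents the "just regress
on coarse features" alternative.

## Engine

No deep-learning framework is used: the graph is executed by a NumPy
engine (float32, NHWC). Convolutions run as im2col views feeding one
BLAS matrix product each way; pooling gradients are scattered over the
(small) window-offset loop; batch normalization uses the standard
whitened-gradient backward pass. Gradient correctness is pinned by
central-difference tests on a maxpool-free graph (max pooling is checked
against an explicit argmax-routing oracle instead, because finite
differences are invalid across winner switches).

## Training recipe

Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) at a constant learning rate 1e-3,
mean-squared-error cost on the raw count, Glorot-uniform initialization
(variance 2/(fan_in+fan_out); zero biases; batchnorm scale 1/shift 0),
dropout keep 0.65 on the hidden fully connected activations, 3 epochs,
batch 64 (a convention; 16/32/64 perform equivalently on this task).
Labels are treated as reals during optimization; predictions are rounded
half-up only for reporting integer counts, never inside the loss.

Two numerical choices matter at small step counts:

- **EMA schedule.** Evaluation uses an exponential moving average of the
  weights. A fixed decay of 0.999 would leave the shadow weights
  dominated by the random initialization for the first ~1000 steps, so
  the effective decay follows the TensorFlow convention
  `min(decay, (1+t)/(10+t))`.
- **Batchnorm recalibration.** Running statistics collected during
  training trail the rapidly moving weights (the gap is worth several
  MSE points after a 3-epoch run). After training, the running
  statistics of both the raw and the EMA weights are replaced by
  averaged batch statistics over up to 16 frozen-weight forward passes
  of training data.

Divergence (non-finite loss) raises immediately with the step index.
With a fixed config seed the whole run — initialization, shuffling,
dropout masks, and therefore the loss history — is bit-reproducible.

## Evaluation statistics

Per-image accuracy is `pa = (1 − |pc − ac|/|ac|)·100`. It is symmetric
in over/under-counting, equals 100 only for an exact count, and is not
clamped: a prediction more than twice the actual count goes negative,
and clamping would silently inflate means. Images with an actual count
of 0 are rejected (the formula divides by the count); the default scene
configuration starts the count range at 1 for this reason. Mean accuracy
is reported on rounded predictions; MSE/RMSE on raw ones (both
conventions are switchable). The predicted-vs-actual relationship is
summarized by ordinary least squares of predicted on actual counts with
R² = 1 − SS_res/SS_tot.

## Area-based baseline

RGB is converted to YCbCr (BT.601 full range); fruit pixels satisfy
Cr ≥ 150 and Cb ≤ 120 (the generator's ripe and half-ripe hues on the
0–255 chroma axes); the mask is cleaned by a radius-1 opening then a
radius-2 closing; the count is total fruit pixels divided by a
calibrated per-fruit unit area. Calibration grid-searches 50 log-spaced
candidates between 0.25× and 4× the mean segmented area per fruit,
minimizing the summed absolute count error on calibration scenes, ties
toward the smaller area. The method's structural failure is occlusion:
overlapped fruit contribute less than a full disk of area, so crowded
scenes are undercounted regardless of calibration — which is exactly why
the learned counter is interesting.

## Problem sizes

The bundled `smoke` profile (32 px scenes, counts 1–10, width 0.25, 200
train images) exercises the full pipeline in about a minute. The
acceptance runs use width multiplier 0.5, 64 px scenes, 4,000 training
and 400 test images, 3 epochs — a configuration one quarter the linear
scale of the full setting (width 1.0, 128 px, 24,000/2,400) that the
architecture is defined for. The full-scale configuration is available
through the `paper` profile.

## Known limitations

- Purely synthetic evaluation: no claim is made about real photographs.
- The NumPy engine is single-process and CPU-bound; full-scale training
  is possible but slow (hours, not minutes).
- At 64 px, fruit radii fall to 2 px and crowded scenes (counts near 40
  with a quarter-visibility floor) are ambiguous even in principle;
  see the accuracy analysis in the training diagnostics before reading
  small MSE differences as architectural signal.
- The area baseline's thresholds are matched to the generator's palette;
  real imagery would need re-tuning.
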