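# Methods

## Overview

`gadnet` classifies single-neuron fluorescence crops as GAD67-positive
(GABAergic interneuron) or GAD67-negative. Two classifiers are implemented on
identical data splits: a small fully convolutional network (the method of
interest) and a PCA + RBF-SVM pipeline (the conventional baseline). Everything
upstream of the classifiers — plane selection, per-plane normalization,
instance splitting, area filtering, cropping — is deterministic image
processing; everything downstream — fold assignment, balancing, scoring,
paired testing — is deterministic given a seed.

## Synthetic data model

Real stained sections are not bundled, so the generator builds micrographs
with the statistical structure the method is designed to exploit:

- **Geometry.** Cells are ellipses with random orientation, axis ratio
  0.65–1.0 and area ~ N(320, 60²) px², placed without overlap except for a
  configurable fraction of touching pairs, whose centers sit at 92% of the sum
  of the two support radii along the contact direction so their masks fuse
  into one connected component without merging deeply. Interiors have a soft
  Gaussian rim falloff. Area and circularity are therefore class-independent
  by construction.
- **Channel 1 (GAD67-analog).** Within-cell mean intensity ~ N(5200, 800²)
  for positive and N(2400, 650²) for negative cells (arbitrary 16-bit units):
  separated but overlapping marginals — informative, not perfectly so.
- **Channels 2–3 (NeuN/Nissl analogs).** Both classes draw within-cell means
  from the same N(3000, 700²), so the marginal histograms are
  class-indistinguishable. Each cell carries a smooth zero-mean unit-SD
  spatial texture; channel 2 adds `+A·t(x)` and channel 3 adds `±A·t(x)` with
  the sign set by the class (`A = 500 × joint_signal_strength` a.u.). The
  class therefore lives only in the *joint* within-cell correlation of the two
  channels — invisible to any single-channel summary.
- **Heterogeneity.** A fraction `joint_flip_fraction = 0.1` of cells carries
  the opposite correlation sign for their class. This imposes an irreducible
  error floor on classification from the joint signal alone, so the
  two-channel score saturates near 0.88–0.90 rather than at 1.0. The
  amplitude (500) and flip fraction (0.1) were calibrated once, while
  designing the generator, so that the channel-ablation ordering of the
  emulated regime holds: marker-channel combinations score highest, the
  NeuN+Nissl pair is strong but below them, single non-marker channels are
  weak, and the SVM baseline lands near 0.7.
- **Acquisition effects.** 10 z-planes share one 2-D scene; a multiplicative
  gain drifts linearly from 0.9 to 1.1 across planes; additive Gaussian noise
  (SD 120) and a 500 a.u. background are applied per plane; planes are
  quantized to the 16-bit integer grid at generation time so disk round-trips
  are bit-exact.

What the generator does **not** model: optical PSF and defocus across planes,
photobleaching, staining chemistry, morphological class differences, spatial
intensity gradients within a section. Passing tests on this data show the
pipeline's mechanics and its sensitivity to a joint two-channel signal; they
do not certify performance on real tissue.

## Preprocessing

- **Plane selection.** Default: the first and the last plane of the stack.
  Both planes of a physical cell become separate samples but always share one
  cross-validation fold (leakage prevention).
- **Normalization.** Affine per plane and channel: `(mean − SD) → 0`,
  `(mean + SD) → 1`, statistics over all pixels of the plane; no clipping.
  A constant plane maps to all 0.5 with a warning.
- **Segmentation.** External masks (e.g. from a pre-trained U-Net) pass
  through, relabeled consecutively. The internal fallback — Otsu threshold on
  the NeuN-analog channel, hole filling, 8-connected labeling — exists so the
  pipeline runs without an external segmenter; it is not a U-Net substitute
  for dense tissue.
- **Erosion–dilation splitting.** Per label: erode with a radius-1 disk
  (up to 10 iterations) until the region disconnects; dilate each component
  by the same number of iterations; intersect with the parent support;
  contested pixels go to the nearest eroded core, ties to the lower child id.
  Regions that vanish or never split pass through unchanged. Only masks are
  edited — image pixels are untouched. A brute-force erosion-scan oracle in
  the tests pins these semantics.
- **Area filter.** Regions strictly smaller than 180 px² are discarded, both
  before and after splitting ("smaller than 180" read as strict, so 180
  survives).
- **Statistics and crops.** Histogram-ready per-cell statistics (per-channel mean,
  area, circularity = 4π·area/perimeter²) use *raw* planes; crops for
  learning are tight bounding-box rectangles from *normalized* planes, not
  masked to the ROI. The perimeter estimator is the contour-weighted one of
  `skimage.measure.perimeter` (axis steps 1, diagonal steps √2); discrete
  circularity can slightly exceed 1 and is reported unclipped.

## Dataset assembly

- **Folds.** 20% of cells (floor) form a validation hold-out; the remaining
  cells are split into five equal segments. Assignment is by cell, never by
  crop, and is deterministic under the seed.
- **Balancing.** Within each fold's training set only, the majority class is
  randomly downsampled to 1:1 and re-weighted by the downsampling factor, so
  weighted effective class counts equal the pre-balance counts and the
  softmax outputs stay probability-calibrated. The hold-out and the fold test
  segments keep their natural ratio.
- **Batching.** Batches of 8, shuffled per epoch, zero-padded bottom/right to
  the largest height and width within the batch (content anchored top-left).

## The FCN

Three blocks of convolution (3×3, same padding, stride 1) → batch
normalization (ε 1e-3, running-stat momentum 0.99) → ReLU → dropout (0.25),
with 16/32/64 feature maps; 2×2 max pooling after blocks 1 and 2; global max
pooling after block 3; a 2-way linear projection with softmax. There is no
fully connected hidden layer, so the parameter count is independent of the
input size and any crop ≥1×1 can be classified. Feature counts, kernel size,
dropout and pooling placement are configurable in `FcnSpec`; the defaults are
the smallest standard choices consistent with a three-block design and
CPU-scale training.

Training minimizes sample-weighted two-class cross-entropy with Adam
(lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7) or SGD (lr 0.0001, momentum 0). The
default schedule is 500 epochs; the experiment harness uses a 50-epoch preset
(the point of checkpointing is that extra epochs change little: the weights
from the epoch with the lowest validation loss are restored at the end).
During cross-validation the fold's test segment drives checkpointing, while
final scores come from the untouched 20% hold-out; the two roles are kept
separate deliberately. All randomness (Glorot-uniform initialization, epoch
shuffles, dropout masks) flows from seeded generators, so a full training run
is bit-reproducible. Forward and backward passes are hand-written NumPy
(im2col convolutions); a numeric gradient check in the test suite verifies
the backward pass against central finite differences.

Numerical notes: zero-padded batch margins pass through same-padding
convolutions and can acquire nonzero activations via the convolution bias and
batch-norm shift before global max pooling — identical behavior to the usual
framework implementation of this architecture, and harmless in practice.
Batch normalization uses batch statistics in training and running statistics
in evaluation, so evaluation is deterministic. A prediction tie (0.5/0.5)
goes to the negative class.

## The PCA-SVM baseline

Crops are flattened row-major per channel, concatenated, and zero-padded to
the longest *training* vector; oversize validation crops are truncated with a
warning (the training set defines the feature space; validation can never
enlarge it). PCA is fitted on the training portion only and keeps the minimal
component prefix with cumulative explained variance ≥95%; validation rows are
transformed with the same fit. The SVM is RBF with C = 1, balanced class
weights, and `gamma = 1/(n_dims × var)` where the variance is over all
entries of the projected training matrix — the "scale" convention.

## Evaluation

Per-class precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
mean, each class taken as positive in turn; undefined 0/0 ratios are reported
as 0 with a degenerate flag. The weighted F1 weights the per-class F1 scores
by the class sizes of the evaluated set. Model comparison uses the classical
paired t-test over the five fold-wise hold-out scores (df = 4), Bonferroni-
adjusted by the number of simultaneous combination comparisons (default 7).
Zero-variance difference vectors are handled explicitly (t = 0, p = 1 when
the mean difference is also zero; ±∞, p = 0 otherwise).

## Problem sizes

The experiment harness and the reproduction script use ~600 cells in a
1024×1024 frame (≈1,150 crops after two-plane extraction), the 50-epoch
preset, and all seven channel combinations × two models × five folds — about
10–15 CPU-minutes end to end. These sizes are the package's desk-scale
defaults; every component accepts larger inputs unchanged.

## Known limitations

- The internal Otsu fallback under-segments dense tissue; external masks are
  expected for real data.
- The erosion-dilation splitter separates touching *pairs* reliably; chains
  of three or more deeply fused cells may split incompletely (single-pass,
  not recursive, by design — matching the scan oracle).
- The synthetic joint-signal mechanism (correlation sign) is one concrete
  instantiation of "class identity in the joint two-channel pattern"; real
  NeuN/Nissl covariation is richer.
- Batch-norm statistics on batches of 8 with heavy padding are noisy; the
  checkpoint rule absorbs most of the resulting epoch-to-epoch jitter.
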