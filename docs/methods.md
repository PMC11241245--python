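# Methods

This note records the modelling choices, numerical conventions and known
limitations of the package, in the order data flows through it.

## Stain normalization

Reinhard normalization matches an image's per-channel mean and standard
deviation, computed in a perceptually decorrelated color space, to those
of a reference image. We implement the transfer in CIELAB under the D65
white point as provided by scikit-image; the conversion functions are
pluggable arguments of `fit_target` / `normalize`, so the original lαβ
space can be substituted without touching the transfer logic, and the
space used is recorded in the serialized `StainTarget`. Statistics are
population statistics (divide by N). Two numerical conventions:

* A source channel whose standard deviation is below 1e-6 (numerically a
  constant plane) is shifted to the target mean without scaling, with a
  warning; scaling would divide by zero. A *reference* image with such a
  channel is rejected outright at fit time.
* Output values are clipped into the 8-bit gamut, never wrapped.

The normalization obeys three testable properties up to 8-bit
quantization (±2 per channel): self-normalization is the identity,
normalizing twice with one target equals normalizing once, and the
output's Lab mean/std land within 1.0 of the target's.

The repository ships no real reference tile. `reference_tile()` generates
a fixed synthetic H&E-like image (labelled synthetic in its docstring)
that stands in for the expert-selected reference; any user-supplied
reference image is accepted via `fit_target` or the CLI.

## Dataset pipeline

Images live in a `magnification/class/image` tree with the eight BreakHis
sub-type labels. Enumeration is lexicographically sorted and filtered by
an extension whitelist, so indexing is deterministic. The 70/20/10
train/validation/test split is stratified per class with floor rounding
for train and validation and the remainder to test — the only rounding
scheme whose train counts, tripled, reproduce the published balanced
per-class targets (1812/1896/1881/1653). The split is at image level, not
patient level, matching the magnification-dependent image-level protocol;
patient-level grouping is out of scope. Splitting is driven entirely by
one seed.

Balancing follows the oversampling rule: per-class target `3 ×
max_class_count` over the training split, each class served cyclically
(`i mod class_count` over the sorted file list; the source algorithm
writes the same loop 1-based), AugMix applied only to classes strictly
smaller than the largest, the geometric transform applied to every
training item. One epoch therefore yields exactly `n_classes × target`
items. Validation and test streams receive preprocessing and
standardization only.

Preprocessing resizes the shorter side to the configured side length
(384 default; small sides for fixtures) and center-crops, then applies
stain normalization when a target is configured. Standardization is
`(x − μ_c)/σ_c` per channel on [0, 1] tensors with the ImageNet channel
statistics as defaults (the canonical constants of ImageNet-pretrained
backbones), overridable via `ChannelStats`.

Augmentation conventions:

* Geometric: horizontal/vertical flips each with probability 0.5,
  rotation uniform in [−45°, 45°], translation up to 10% per axis,
  scale in [0.8, 1.2], shear in [0°, 10°], composed as one affine map
  about the image center with bilinear resampling. Borders exposed by
  the affine map are filled with the image's mean color rather than
  black: tissue fills the frame in this domain, and black fill would
  inject artificial global-intensity shifts that swamp texture cues.
* AugMix: `width` (default 3) chains of depth 1–3 (uniform) drawn from
  {rotate, shear, translate, posterize, solarize, autocontrast,
  equalize}, with chain magnitudes scaled by `severity/10` (default
  severity 3, so severity 0 degenerates to the identity); chains are
  blended with Dirichlet(α=1) weights and the blend is convexly combined
  with the original via a Beta(α, α) weight. These hyperparameters are
  unstated in the source protocol; the defaults are the AugMix paper's
  common settings and all are configurable.

## Network

No deep-learning framework is part of the environment, so the package
carries its own numerical substrate: a reverse-mode autodiff engine over
numpy arrays (`histonet.autodiff`) with im2col-lowered convolutions (BLAS
matmuls), einsum-based depthwise convolutions, batch normalization with
the closed-form backward pass, SiLU/sigmoid/ReLU, reductions,
concatenation, dropout and a fused softmax-cross-entropy. Every operator's
gradient is verified against central differences in the test suite.
Inference can run without graph construction (`no_grad`).

The backbone follows the EfficientNetV2-S composition contract: stem
3×3/2 → Fused-MBConv stages (expansion 1/4/4, layers 2/4/4) → MBConv+SE
stages (expansion 4/6/6, SE squeeze 0.25 of block input, layers 6/9/15),
strides 2·1·2·2·2·1·2 and channels 24/24/48/64/128/160/256. The channel
progression and the 12×12 final map at 384×384 input are asserted by the
architecture-contract test, so any drift in the composition is caught.
Because no pretrained weight source is available offline, building with
`pretrained=True` raises an explicit error; all training here starts from
random initialization. Residual blocks zero-initialize their final
batch-norm gain so each block starts as the identity — without this the
40-block stack needs many epochs before the loss moves at all.

One CBAM block refines the final 256-channel map: channel attention with
a shared two-layer bottleneck MLP (reduction ratio 16, minimum hidden
width 1), then spatial attention with a 7×7 same-padded convolution over
the channel-mean and channel-max planes. Exactly one block is inserted,
before the classifier. The head is a 1×1 convolution to 1280 channels,
global average pooling, dropout (p=0.2, configurable, 0 disables), two
hidden fully connected layers of width 1024 with SiLU between them, and
the class logits. `width_scale < 1` shrinks every channel count (rounded
to a multiple of 8, minimum 8) for CPU-feasible tests; it is never a
reference-configuration setting.

Ablation variants remove exactly one component: `cbam` (block bypassed),
`fc_layers` (single-layer head), `stain_norm`, `balance_aug` (no
equalization — each class is served its own count, tripled by the
geometric transform, preserving the imbalance), or `all_aug` (each image
once per epoch, preprocess + standardize only).

## Training

The loss is mean cross-entropy with probabilities clipped at 1e-12; the
optimizer is SGD with optional momentum (default 0 — the descent rule is
stated plain) and decoupled weight decay (added to the update, not the
loss; which coupling the reference protocol used is unstated, both are
supported). Reference hyperparameters: lr 0.001, weight decay 0.01,
batch 16, ≤50 epochs, early-stopping patience 25. "Improvement" means a
validation loss lower by at least 1e-8. The plateau scheduler multiplies
the learning rate by 0.1 after `scheduler_patience` (default 5, unstated
in the source protocol) non-improving epochs. The best-validation-loss
weights are restored after training; per-epoch history goes to CSV and a
run manifest to JSON.

The desk-scale runs in the tests use a from-scratch recipe (lr 0.02–0.03,
momentum 0.9, no weight decay, scheduler patience equal to the epoch
budget): the reference values are a fine-tuning recipe for pretrained
weights, which do not exist here, and a 10-epoch from-scratch run needs a
hotter, uninterrupted schedule. The reference values remain the
`TrainingConfig` defaults.

## Evaluation

All rates are one-vs-rest from the confusion matrix and reported in
percent: precision TP/(TP+FP), sensitivity TP/(TP+FN), specificity
TN/(TN+FP), F1 the harmonic mean of precision and sensitivity; accuracy
is trace/total; macro rows are unweighted class means and weighted rows
support-weighted means. For single-label data the support-weighted
sensitivity equals accuracy; every report asserts this identity.
Zero-denominator rates are reported as 0 with a warning (the source
protocol is silent). The multiclass Jaccard index is the macro average of
per-class TP/(TP+FP+FN), and AUC is one-vs-rest trapezoidal integration
of the sensitivity versus (1−specificity) curve, macro-averaged over
classes present in the data; both reduction schemes are recorded in the
report metadata since the source reports single numbers without naming a
scheme. The test suite cross-checks every metric against scikit-learn
and against brute-force tallies.

## Grad-CAM

The heat map for class k at a layer is the ReLU of the sum of the layer's
channels weighted by the spatially pooled gradient of logit k, bilinearly
upsampled to the input size and min-max normalized into [0, 1] (a
constant map normalizes to zeros). The default target layer is the CBAM
output, where the model's spatial focus is formed; the backbone output
and the 1280-channel head map are also selectable. Maps are deterministic
for fixed weights and input.

## Synthetic fixtures

The generator emulates the BreakHis layout: a pink eosin-like background
with purple hematoxylin-like soft-edged elliptical "nuclei", per-class
blob density/size/eccentricity ranges, optional per-class background
tints (color-coded mode), a global RGB cast for stain-shift experiments,
and full byte-level determinism under one seed. Density ranges are
disjoint between classes, so a mean-darkness threshold separates
neighbouring classes at ≥99% (verified by test); the color-coded tints
are strong enough that a linear classifier on mean RGB is perfect, which
is the construction's contract for the learning-sanity task. A `hard`
mode narrows the density gaps to exercise the confusion-matrix paths.

What the fixtures do **not** model: spatial tissue architecture,
chromatin texture, magnification semantics, patient structure, scanner
noise. Passing the desk-scale tests therefore demonstrates that the
pipeline, optimization and evaluation machinery are correct — not that
the architecture reaches any particular accuracy on real histopathology.

## Desk-scale problem sizes

The test suite exercises the pipeline at reduced sizes chosen as the
smallest that still demonstrate each property: unit fixtures of 8–12
images per class at side 32; the learning-sanity task with 3 classes ×
40 images at side 64 and width scale 0.25 (10 epochs); the augmentation
ablation on an imbalanced 40/14/14 fixture at side 32 and width scale
0.125 with a 50/20/30 split, giving a deliberately tiny training set and
a test set large enough (22 items) for a stable directional comparison.
The ablation compares the full pipeline against `all_aug` dropped, where
the lost oversampling equalization starves the minority classes — the
directional analogue of the reference ablation, with no numeric claim.
The architecture contract runs one real forward pass at the full
384×384/width-1 configuration (seconds on CPU).

## Known limitations

* No pretrained weights: transfer learning, and with it the reference
  accuracies, are out of reach offline; all runs are from scratch.
* numpy-based training is single-threaded BLAS-bound; the full-width
  configuration is buildable and runnable but not trainable at scale.
* Batch-norm running statistics lag the fast-moving weights of short
  hot-schedule runs, so early-epoch validation metrics are noisy; the
  best-checkpoint rule absorbs this.
* The Lab white point and value ranges of the original study's stain
  tool are unstated; the ±2 quantization and 1.0 statistics tolerances
  absorb plausible variants.
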