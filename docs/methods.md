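# Methods

This note records the model, the defaults that matter, and the design
choices made where the design was genuinely open. Nothing here states a
result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline model

The pipeline classifies a labeled image collection in five stages:
min-max normalization to [0, 1] (per image, over all pixels and channels);
a stratified 60/25/15 train/validation/test split; nine-fold augmentation of
the training set; fused feature extraction; iterative feature selection; and
one of three classification heads. A single master seed fans out to
per-stage child seeds (the i-th 32-bit word of `SeedSequence(master)`,
masked to int31), so each stage has an independent stream and can be
replayed alone.

### Stationary-wavelet augmentation

The 2-D stationary wavelet transform (SWT) is undecimated: every
approximation/detail plane keeps the input's spatial size, and with
periodic boundary handling the transform commutes with circular shifts.
Decomposition uses the Daubechies db2 filter, three levels, applied to each
of the three channels independently, giving coefficient arrays of shape
(h, w, 3, 3). Inputs whose sides are not divisible by 2³ are
reflect-padded, with the padding recorded and cropped on reconstruction;
the default 256×256 path needs no padding.

Which three SWT products become augmentation images is a design choice:
we use the per-level approximation planes App₁..App₃, min-max rescaled back
to [0, 1]. The detail planes are near-zero-mean, high-frequency residues
that make poor standalone images; the approximations retain the anatomy at
increasing smoothing scales. Each of the three approximation images then
receives exactly one random translation, one rotation, and one shear
(bilinear interpolation, zero fill, values clipped to [0, 1]), each drawn
independently per (image, operation) from a single seeded stream. The nine
derived images **replace** the original rather than extend it: with the
reference class size of 2456 that yields exactly 22,104 augmented images
per class, matching the ×9 bookkeeping the split table implies.

Default ranges: translation ±10 px, rotation ±90°, shear ±30°. These are
stated for 256×256 inputs; on smaller synthetic images the same pixel
ranges are proportionally harsher, which the end-to-end tests accept
deliberately (it stresses extractor robustness).

### Split rule

Per class of size m: train = ⌊0.60·m⌋, test = ⌊0.15·m⌋, validation takes
the remainder. This floor/remainder convention is fixed by the reference
counts 4094 → 2456/1024/614 and is checked exhaustively for m = 3..500.

### Feature generation and fusion

Extractors are black boxes satisfying a contract: a deterministic map from
one image (resized to the extractor's input size) to a fixed-length real
vector, 1000 dims by default. Fusion is ordered horizontal concatenation;
the block map records each extractor's column range so selected indices
remain attributable. Adapters for ImageNet-pretrained networks can
implement the contract, but the library never requires their weights.

The shipped stand-in extractor is synthetic: per channel it computes
center-disk intensity moments and an 8-bin histogram, a radial
power-spectrum profile of the Hann-windowed plane over six frequency
annuli, two-level SWT subband energies, and a 4×4 patch-mean map, then
projects the statistic vector to 1000 dims through a fixed seeded Gaussian
matrix. The spectral/histogram statistics were chosen to survive the
geometric augmentation (translation- and rotation-invariant, tolerant of
zero-filled borders); the seeded projection makes extractors with different
seeds near-orthogonal, emulating the "several independent feature banks"
structure without pretending to be a neural network.

### Selectors

* **NCA** learns a diagonal weight vector (one non-negative weight per
  feature) — not a full matrix — because the downstream use is per-feature
  ranking. Features are standardized first; weights start at 1 plus a tiny
  (1e-3) seeded jitter; optimization is gradient ascent with a backtracking
  line search, so the recorded objective trace is non-decreasing. The
  objective f(w) = Σᵢ Σ_{j∈Sᵢ} p_ij is bounded by n and saturates once the
  stochastic nearest-neighbor rule separates the classes; iterating past
  saturation lets irrelevant weights drift, so the stopping tolerance
  (objective gain < 1e-4 per accepted step) deliberately halts at
  saturation onset. Ranking is by final weight².
* **Chi-square** uses the classical deviation statistic Σ(O−E)²/E on a
  class × bin contingency table; continuous features are discretized into
  10 equal-width bins over their observed range (the discretization is a
  design choice; any strictly monotone transform preserving bin occupancy
  preserves every score). Constant features score 0. Margins with zero
  count are dropped rather than divided by.
* **mRMR-FCQ** greedily maximizes F/mean|ρ|: one-way ANOVA F-statistic
  against the class over mean absolute Pearson correlation with the
  already-selected set. The first pick has an empty redundancy set; its
  quotient is defined as the raw F-statistic (redundancy treated as 1),
  matching standard FCQ practice. Ties break to the lower feature index.
  Zero-variance features are excluded from candidacy and logged; they and
  any features beyond `k_max` are appended by descending relevance so the
  ranking remains a full permutation.

### Iterative wrapper (iNCA / iChi2 / iMRMR)

The wrapper scans top-k prefixes of a ranking over the grid k_min..k_max
(default 32..d, step 4; the endpoint is always included) and keeps the k
with minimal loss, ties to the smaller k. The default loss is the
misclassification rate of a 1-nearest-neighbor classifier under seeded
stratified 5-fold cross-validation — a light, deterministic proxy.

Inside the full pipeline the scan data are augmented images, and the nine
variants of one source are near-duplicates; within-set CV is then trivially
optimistic (a variant's nearest neighbor is its sibling) and degenerates to
zero loss at every k. The pipeline therefore scores the scan on the
untouched validation split instead: the 1-NN is trained on the top-k
columns of the augmented training matrix and its error measured on the same
columns of the validation matrix. This is what the validation split exists
for; the tabular API keeps the CV default.

### Classification heads

* **1-D CNN.** The head consumes a selected feature *vector*, so
  convolutions run along the feature axis with 'valid' boundaries — the
  only shape-consistent reading of a kernel-2, stride-1, three-layer
  (256/128/64 filters) architecture with average pooling (2, stride 2)
  after the first two layers and a softmax dense layer. The implementation
  is plain numpy (im2col + matmul, float32), trained with softmax
  cross-entropy and an adaptive-moment optimizer (lr 1e-3, batch 64,
  ≤100 epochs). Inputs are standardized with training statistics; weights
  use seeded He initialization. Early stopping: patience 8 on the monitored
  loss (validation when provided, else training) or training cross-entropy
  below 1e-2, at which point the classifier's decisions are converged. The
  default architecture needs at least 11 input features to keep one valid
  position in the last conv layer.
* **LDA.** The scalar pooled-variance formulation (class means plus one
  within-class variance) extended per-feature to a shared diagonal
  covariance — a Gaussian-Bayes discriminant that recovers the scalar
  formula at d = 1. Priors are empirical class frequencies; a zero pooled
  variance is floored at 1e-12 with a warning. Predictions are invariant
  under global feature translation and training-set duplication.
* **SVM.** Soft-margin SVM (C = 1), Gaussian RBF kernel, one-vs-one
  multiclass with majority vote (via scikit-learn's SVC). "Auto scaling"
  resolves γ to 1/(d·Var(X)) over the training matrix; 1/d is exposed as
  the `auto` alternative.

### Evaluation

Stratified k-fold (default 10) cross-validation; metrics are accuracy and
macro-averaged precision/recall/F1 reported as percentages with three
decimals, aggregated as minimum/maximum/average over folds. Macro averaging
is the natural choice for the balanced three-class design. Per-class error
of omission is 100·FN/n, identically 100 − recall%. When feature selection
is part of the evaluated pipeline it is refit inside each fold's training
split by default (no leakage); a select-once-on-all-data mode exists for
comparison with pipelines that select globally, and the discrepancy between
the two protocols is the user's to mind.

## Synthetic data

`make_image_dataset` composites, over a shared soft elliptical "thorax"
mask: a class-specific brightness level, a class-specific oriented smooth
sinusoidal shading, and band-pass-filtered Gaussian noise at a
class-specific spatial frequency and contrast. The deterministic components
outweigh the per-image noise, so classes are separable even by raw-pixel
nearest-neighbor distance — the floor any competent pipeline must clear.
What the fixtures do **not** emulate: anatomy, acquisition physics,
inter-patient variability, label noise, or class imbalance. Passing tests
on these fixtures validates the pipeline's mechanics and statistics, not
clinical performance.

`make_feature_table` plants `n_informative` columns whose class means are
shifted by `effect` (in noise-SD units, adjacent classes ≈ `effect` apart)
among standard-normal noise columns, recording the planted indices.
Recovery experiments use 10 informative of 100 columns, effect 4.0, 100
samples per class, 5 seeds — large effect, moderate n: selectors should
recover ≥ 9/10 planted columns and heads should exceed 95% 10-fold CV
accuracy there.

## Problem sizes

Default test and acceptance runs use desk-scale inputs chosen once: 8×8
images for the 2456-per-class counting run (the arithmetic is
size-independent; 2³ divides 8 so the 3-level undecimated transform needs
no padding), 32–64 px images elsewhere, 100–600 fused feature columns, and
100–200 samples per class for tabular experiments. A full-scale clinical
experiment (thousands of radiographs, ImageNet-pretrained extractors, a
66,312 × 3000 fused matrix) is out of scope by design; clinical accuracy
cannot be demonstrated on synthetic data and is not asserted anywhere.

## Known limitations

* The stand-in extractor is not a neural network and its features are far
  weaker than pretrained-CNN features; end-to-end synthetic accuracy
  (≈ 0.9 on 9 test images in the worked example) is a mechanics check, not
  a performance claim.
* NCA uses a diagonal metric; feature interactions visible only to a full
  linear transform are invisible to it.
* The chi-square discretization (10 equal-width bins) is crude for heavy-
  tailed features; scores are exactly invariant only under transforms that
  preserve bin occupancy.
* The numpy CNN is single-threaded and intended for selected-feature
  vectors (tens to a few thousand dims), not images.
* Geometric augmentation uses zero fill; extractors that are sensitive to
  border statistics will see a train/test shift, which is visible with
  aggressive rotation ranges on small images.
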