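# Methods

This note records the models, conventions, and design choices behind
`optophen`, and what the synthetic experiments do and do not show.

## Coordinate model

Spot coordinates live in three linked spaces: full-resolution
reference pixels (where the vendor pipeline reports barcode centers),
the down-sampled reference image (one global `downsample_scale`,
typically 0.040–0.044), and the registered microscopy image (the
down-sampled reference scaled by `registration_scale`, default 3,
before registration). Mapping composes the two scalings and rounds
half-away-from-zero; the chain is associative (two scalings equal one
scaling by their product). Conventions, fixed and documented: 0-based
indices, (x = column, y = row), a spot center at the center of its
pixel, and the center of an even-sized ROI window at index
(size//2, size//2).

Landmark registration replaces an interactive workflow with
programmatic least-squares estimation: the similarity (rigid +
isotropic scale) fit is the closed-form Procrustes solution; the
affine fit is the ordinary least-squares solution of the 6-parameter
model, solved directly from the design matrix [x y 1]. The affine
residual MSE can never exceed the similarity MSE on the same landmarks
(nested models); degenerate inputs (coincident or collinear points)
are rejected. Spots whose ROI window would overrun the image are
dropped with a warning — edge spots carry truncated, unrepresentative
windows, and silently padding them would bias texture statistics.

## ROI features

Validity masking keeps pixels in [2000, 65535): below 2000 is
background, and since values above 65535 are unrepresentable in 16-bit
data, saturation is interpreted as v = 65535 (excluded). Abundance is
the per-channel mean over valid pixels only; a spot with any fully
masked channel is excluded with a warning rather than imputed.

Ratio normalization divides channels 1, 2, 3 and 5 by channel 4 to
cancel multiplicative factors shared by all channels (source power,
working distance, detector drift). The normalized 5-vector keeps the
raw channel-4 abundance in its fifth slot: this preserves both the
normalization and the 5-feature abundance vector, and keeps overall
brightness available to the classifier. A `raw` mode returns the plain
means. Note an intrinsic property of ratio features: because all four
ratios share one denominator, fluctuations of the reference channel
induce residual positive correlation among them even after the shared
field cancels; the decorrelation experiment therefore reports the
*drop* in mean |off-diagonal| correlation, which isolates the
illumination effect.

Texture is summarized by the 13 classical Haralick statistics of the
symmetric gray-level co-occurrence matrix at distance 1, computed per
direction (0°, 45°, 90°, 135°) and averaged — making the features
invariant to 90° image rotations. Quantization is a fixed linear
binning of the valid range [2000, 65535) into 64 levels, identical for
every ROI so features are comparable across spots; masked pixels get a
sentinel level whose GLCM rows/columns are discarded before
normalization, so no invalid pair contributes. The sum-variance
statistic is centred on the sum-average (the standard correction of
the original formula's typo); entropies use natural logarithms with
0·log 0 = 0. Degenerate single-level ROIs make the correlation and
first information-measure denominators vanish; both are set to 0 by
policy and logged. Texture is computed on raw channel ROIs (pixelwise
ratio images would require per-pixel division by a noisy channel-4
value, amplifying noise); abundance uses the ratio normalization.

## Phenotyping

Counts are library-size normalized to the median spot depth and
log1p-transformed — a deterministic, standard recipe recorded in the
output metadata. Clustering is Lloyd's k-means with k-means++
initialization and 10 restarts on all genes (no PCA by default; a flag
exists), Euclidean distance; k is chosen by the mean silhouette
coefficient over a scan. Marker z-scores compare each cluster mean to
the mean and standard deviation *across the k cluster means*
(ddof 0): this makes the two-cluster case exactly antisymmetric and is
robust to unequal cluster sizes. Zero-variance genes get z = 0; top-50
lists break ties lexicographically by gene id.

## Statistics

Each spot is treated as an independent sample. Per channel:
Shapiro–Wilk normality screening, a tie-corrected Kruskal–Wallis
omnibus test, then all k(k−1)/2 pairwise two-sided Mann–Whitney U
tests. The Bonferroni multiplier is the full family size —
channels × pairs — which is 60 under the 6-cluster, 4-channel design.
Mann–Whitney uses the exact null distribution when both groups have at
most 8 untied observations, otherwise the tie-corrected normal
approximation with continuity correction. Significance is called at
corrected p < 0.001.

## Classifier tiers

Features are standardized to zero mean and unit variance with
statistics fitted on training folds only (constant features pass
through centred, with a warning). The SVM tiers use an RBF kernel with
balanced class weights — under-represented phenotypes would otherwise
be absorbed by the majority class — and a small inner grid search over
(C, γ), inside stratified 5-fold cross-validation; metrics are
reported per fold as mean ± sd, and held-out predictions pooled so
each spot is predicted exactly once.

The CNN tier operates on 8-bit RGB tiles composed from channels 1, 3
and 5 (the NADH-dominant, lipofuscin-dominant and SHG signals). The
16→8-bit window is fixed globally at the validity range, not
per-tile, so absolute brightness remains informative. The default
tile mode extracts a native-resolution context window centred on the
spot (surrounding tissue included, no interpolation); a crop-resize
mode that upscales a 70-px disc window is also provided. The network
itself is a compact two-block CNN (3×3 conv + ReLU + 2×2 max-pool,
twice; dropout 0.25; a dense ReLU layer; softmax head) implemented in
numpy and trained with Adam at batch size 16, early stopping on
validation loss with patience 6 (best weights restored), and
learning-rate halving on plateau. Training batches are augmented with
random 90° rotations and mirror flips — label-preserving symmetries
for tissue, which has no preferred orientation; augmentation is what
lets a small network generalize from a few hundred tiles.
Cross-validation is stratified k-fold with an inner ~1/9 validation
split of the training portion (≈80/10/10 per fold at 10 folds). The
backprop implementation is verified against central finite differences
in the test suite.

## Synthetic data

The generator emulates the study geometry exactly: circular 55 µm
barcode discs spaced 100 µm on a Cartesian grid at 1.28 µm/pixel
(adjacent centers 78 px apart), coordinates emitted in full-resolution
reference space with downsample scale 0.044 and registration scale 3,
so the whole mapping chain is exercised and round-trips to within one
pixel.

Counts are negative binomial (dispersion r = 2, background mean 5)
with disjoint 20-gene "programs" per cluster elevated 4-fold — enough
structure that k-means recovers the assignment essentially perfectly,
which is the regime the labels require. Images carry, inside each
disc, a cluster/channel-specific mean modulated by (i) a unit-variance
Gaussian-random-field texture (white noise smoothed at a configurable
correlation length — the minimal stationary texture whose GLCM
statistics vary monotonically with correlation length), (ii) i.i.d.
white detector noise, and (iii) ONE smooth multiplicative illumination
field, exp(a·f) with f built from three random low-frequency plane
waves, applied identically to all five channels so that the channel-4
ratio cancels it exactly. An optional per-tile brightness factor
mimics mosaic-stitching artifacts (off by default). Inter-disc pixels
sit at a sub-threshold background level, exercising the validity mask.

Two named study conditions:

* `SynthConfig()` defaults — clusters differ in both channel means and
  texture; used for clustering-recovery and general integration tests.
* `texture_coded_config()` — all clusters share identical channel
  means; correlation lengths 2/4/8 px code the three phenotypes, with
  texture amplitude 0.35, detector noise 0.15 and spot-level
  illumination jitter 0.2. Abundance distributions overlap (mean
  information is absent; only dispersion differs), d = 1 GLCM
  statistics are partially degraded by the white noise, while
  multi-scale pooled features remain informative. This produces the
  tiered ordering the three classifiers are designed to expose:
  abundance SVM ≈ 53%, texture SVM ≈ 87%, CNN ≈ 97% weighted accuracy
  (seeded 20×20 run) — the qualitative pattern
  *abundance < texture < learned multiscale features*.

What passing these tests shows — and does not. The generator's
textures are stationary Gaussian fields and its phenotypes are coded
by a single spatial-scale parameter; real tissue contrast involves
structured morphology (glands, fibers, cell clusters), spatially
correlated phenotypes, staining/fixation artifacts and inter-patient
variation, none of which are modelled. Synthetic accuracies therefore
validate the machinery and its relative ordering, not expected
performance on patient specimens.

## Problem sizes and numerical choices

Seeded experiments use a 20×20 grid (400 spots) for the classifier
ordering, 15×15 (225 spots) for decorrelation and clustering recovery,
and 32-px tiles with 5-fold CV for the CNN — sizes chosen so a full
reproduction runs on a single CPU in minutes while keeping per-class
fold counts comfortably stratifiable. The CNN supports the full
10-fold protocol via `cnn_folds`. All seeds (generator, fold
assignment, network initialization, batch shuffling, dropout) are
config-controlled; identical configs give bit-identical artifacts.

Known limitations: no spatially-aware clustering or batch correction;
no mixed-effects treatment of patient-level correlation (spots are
independent samples by design); no intensity-based or deformable
registration; the Haralick distance is fixed at 1 (multi-distance
texture is an easy extension); the CNN is a from-scratch small network
rather than a large pretrained backbone, so its absolute accuracy on
real data should not be extrapolated from the synthetic runs.
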