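# optophen

Optical phenotyping of tissue: predicting transcriptomically defined
tissue phenotypes from label-free multichannel microscopy.

Spot-barcoded spatial transcriptomics (Visium-style) ties a gene
expression vector to each 55 µm capture disc on a slide, spaced 100 µm
apart in a Cartesian grid. When the same section is imaged by
multiphoton microscopy (four autofluorescence channels plus second
harmonic generation, ~1.28 µm/pixel, 16-bit), each spot also has an
image neighbourhood. `optophen` implements the full analysis that links
the two:

1. **Co-registration** — barcode centers are mapped from
   full-resolution reference coordinates into registered-microscopy
   pixels via two scale factors (`center = round(x · s_downsample ·
   s_registration)`), with landmark-based similarity and affine
   transform estimation for residual alignment.
2. **Phenotype definition** — k-means clustering of median-depth
   normalized, log1p-transformed counts, with silhouette-score scanning
   over k and per-cluster marker z-scores
   `z(g, c) = (x̄_c(g) − x̄(g)) / s(g)` over the k cluster means
   (top-50 up/down lists per cluster).
3. **Image features** — per-spot 70×70 ROIs, validity masking
   (2000 ≤ v < 65535), channel *abundance* (masked mean), ratio
   normalization of channels 1, 2, 3, 5 by channel 4 (cancelling
   multiplicative illumination shared across channels), and the 13
   classical Haralick GLCM texture statistics per channel
   (5 abundance features; 5 + 13×5 = 70 with texture).
4. **Statistics** — inter-channel Pearson correlation before/after
   normalization, Shapiro–Wilk normality screening, Kruskal–Wallis
   omnibus tests and pairwise Mann–Whitney U tests with Bonferroni
   correction over the whole family (6 clusters × 4 channels → ×60).
5. **Classification** — three tiers: an RBF SVM on abundance, an RBF
   SVM on abundance+texture (stratified 5-fold CV, balanced class
   weights, per-fold standardization), and a small convolutional
   network on RGB tiles composed from channels 1/3/5 (stratified k-fold
   CV with inner validation splits, batch 16, early stopping with
   patience 6, LR-on-plateau, flip/rotation augmentation).
6. **Evaluation** — one-vs-rest ROC/AUC (equal to the rank statistic
   U/(n₊n₋)), confusion matrices, precision/recall/F1 with weighted
   averages, and spatial back-projection of predictions as two-ring
   glyphs (inner disc = predicted, outer ring = true class).

A synthetic-data generator (`optophen.synthgen`) produces co-registered
image stacks, barcode tables and negative-binomial count matrices with
known phenotype structure, so every stage is testable end to end.

## Worked example

```python
from optophen import texture_coded_config, simulate_dataset, map_barcode_to_image
from optophen import roi_features as rf, classify

ds = simulate_dataset(texture_coded_config(seed=1))      # 20x20 grid, 3 phenotypes
mapped = map_barcode_to_image(ds.barcodes, image_shape=ds.stack.shape, roi_size=70)
rois = rf.extract_rois(ds.stack.data, mapped[["x", "y"]].to_numpy())
ft = rf.build_feature_table(rois, mapped["barcode"].to_numpy(),
                            ds.assignments, with_texture=True)
svm = classify.train_svm(ft, n_folds=5, seed=0, kind="svm_texture")
print(svm.summary())
```

prints

```
svm_texture: weighted accuracy 87.0% +/- 5.35% over 5 folds
```

i.e. the texture-feature SVM recovers the three texture-coded
phenotypes in 87% of held-out spots, averaged over five stratified
folds (± the fold-to-fold standard deviation). On the same dataset the
abundance-only SVM reaches ~53% (the phenotypes share identical channel
means, so only dispersion information remains) and the tile CNN ~97%,
reproducing the characteristic ordering
*abundance < texture < multiscale CNN*.

The same pipeline runs from the shell:

```bash
optophen simulate --seed 1 --out run/data
optophen full-run --seed 1 --out run
```

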