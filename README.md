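# histocode

Histogram-of-concepts encoding and decision-fusion classification of
whole-slide histopathology images (WSIs), with fully supervised, weakly
supervised (MIL and EM discriminative-patch selection) and unsupervised
(visual-codebook) tile representations, and class-specific
permutation-importance heatmaps.

## The problem

A WSI is far too large to classify directly, and slide-level diagnoses
(e.g. separating dysplastic from non-dysplastic Barrett's esophagus, and
both from squamous tissue) depend on minority regions: most tiles of a
diseased slide contain ordinary benign tissue. `histocode` treats each
slide `X_i = {x_1, ..., x_n}` as a bag of fixed-size tissue tiles and
builds its representation in three steps:

1. **Tile mapping.** A function `M` maps each tile's learned feature
   vector `f(x) ∈ R^E` onto a vocabulary of K *concepts* `V = {c_1..c_K}`:
   - *fully supervised* (FS): concepts are the slide classes; `M` is a
     softmax tile classifier trained on annotation-mask labels;
   - *MIL*: same classifier, but every tile inherits its slide's label;
   - *EM*: MIL refined by an expectation-maximization loop over hidden
     per-tile indicators `z` that select discriminative tiles;
   - *codebook* (KM/GMM): concepts are clusters of autoencoder
     embeddings — k-means centroids (hard assignment) or a Gaussian
     mixture with posteriors
     `p(c_m | f(x)) = π_m N(f(x)|μ_m,Σ_m) / Σ_k π_k N(f(x)|μ_k,Σ_k)`.
2. **Slide encoding.** The slide histogram averages the tile mappings:
   `h_k = (1/|X_i|) Σ_x p(c_k | f(x))` (soft) or the normalized
   assignment counts (hard).
3. **Decision fusion.** An SVM or random forest classifies the
   histograms; evaluation is patient-grouped 10-fold cross-validation
   with per-class one-vs-rest accuracy, AUC, precision, recall and F1,
   support-weighted averages, and 95% t-intervals over folds clipped to
   [0, 1].

For interpretability, tile-level class probabilities give heatmaps
directly on the class-based routes; on codebook routes, per-concept
permutation importances `I_{c_m}(C)` are propagated to tiles as
`I_x(C) = Σ_m p(c_m | f(x)) · I_{c_m}(C)`.

Because real esophageal cohorts cannot be redistributed, the package
ships a seeded synthetic-cohort generator (`histocode.synthetic`) that
reproduces the statistical shape of the problem — patient-grouped slides,
near-white background, shared benign texture, and minority
class-discriminative lesion tiles — with known per-tile ground truth, so
every stage is testable end to end.

## Worked example

`examples/02_encode_and_classify.py` runs the unsupervised route end to
end on a 24-slide cohort (autoencoder → 16-component GMM codebook → soft
histograms → SVM fusion):

```
24 slides, 1224 tissue tiles retained
histogram matrix: (24, 16) — every row sums to 1.0

weighted cross-validated metrics (mean [95% CI]):
           accuracy: 1.000 [1.000, 1.000]
                auc: 1.000 [1.000, 1.000]
          precision: 1.000 [1.000, 1.000]
             recall: 1.000 [1.000, 1.000]
                 f1: 1.000 [1.000, 1.000]
   overall_accuracy: 1.000 [1.000, 1.000]
```

Every held-out slide is assigned its true class: the three planted
texture populations yield cleanly separated concept histograms. The
other examples generate cohorts (`01`), run EM patch selection and
report its lesion-recovery Jaccard (`03`), render a permutation-
importance heatmap (`04`), and compare representation routes under one
shared fold assignment (`05`).

## Layout

- `src/histocode/synthetic.py` — seeded cohort generator and PNG/CSV round-trip
- `src/histocode/tiling.py` — tile extraction, tissue filtering, grayscale, augmentation
- `src/histocode/tile_models.py` — tile classifier and autoencoder (seeded numpy backend)
- `src/histocode/concept_mappers.py` — FS/MIL tile sets, smoothing, EM selection loop
- `src/histocode/codebook.py` — k-means / Gaussian-mixture codebooks, posteriors
- `src/histocode/encoding.py` — soft/hard slide histograms
- `src/histocode/slide_inference.py` — fusion classifiers, patient-grouped CV, model grid, PCA
- `src/histocode/interpretability.py` — permutation importance, tile propagation, heatmap rendering
- `docs/methods.md` — model assumptions, parameter defaults, numerical choices, limitations
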