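# Methods

## Model

A whole-slide image is modeled as a bag of non-overlapping fixed-size
tiles. The pipeline is the classic bag-of-concepts construction: a tile
mapper produces, for every retained tissue tile, either a probability
vector over K concepts or a single concept index; the slide histogram is
the average of those vectors (soft) or the normalized concept counts
(hard); a conventional classifier (RBF-SVM or random forest) operates on
the histograms. The central assumption is that class identity is
expressed in the *composition* of tile-level patterns, not in any single
tile — which is why decision fusion over the full histogram is preferred
over max-pooling tile votes, and why the encoding is robust to a
minority of misclassified tiles.

Five mappers are implemented. Fully supervised (FS) and MIL mappers are
softmax tile classifiers differing only in where labels come from
(annotation masks vs. bag labels). The EM mapper wraps the MIL
classifier in an expectation-maximization loop over hidden per-tile
indicators z: initially all tiles are discriminative (z = 1); each
M-step retrains the classifier from scratch on the selected tiles with
bag labels; each E-step Gaussian-smooths the slide-class probability
over the tile lattice and re-thresholds z; iteration stops when fewer
than `epsilon` of the indicators flip. The unsupervised mappers embed
tiles with an autoencoder and cluster the embeddings into a visual
codebook: k-means centroids for hard assignment, a diagonal-covariance
Gaussian mixture for soft assignment via component posteriors computed
in log space.

## Tissue filtering and preprocessing

A pixel is tissue when its grayscale intensity is below 0.9 (near-white
= glass); a tile is kept when at least 50% of its pixels are tissue.
The sliding-window stride defaults to the tile size (a partition);
partial edge windows are dropped. RGB input is converted to grayscale
with Rec. 601 luminance weights, which cancels luminance-neutral
per-slide color casts; an optional per-tile intensity standardization
exists but is off by default. Training-time augmentation draws from the
8 square symmetries (optional horizontal flip × 90° rotations), which
preserve the intensity multiset exactly.

## Tile models

The feature extractors are seeded feed-forward networks written directly
on numpy (ReLU hidden units, inverted dropout, Adam, softmax/sigmoid
heads), operating on block-mean-downsampled grayscale tiles. The `desk`
preset (downsample 2, one 128-unit hidden layer, dropout 0.5 on the
classifier head) trains in seconds on one CPU and separates the
reference textures essentially perfectly; a `paper-head` preset widens
the dense head to 1024 units. Full-scale convolutional backbones are
deliberately out of scope for this backend: every pipeline stage above
the mapper interface is backbone-agnostic, so any model with the same
contracts (probabilities summing to 1; fixed-length embeddings) can be
substituted. Training is bit-reproducible from `(seed, data order)`.
Classifier training weights classes inversely to their tile counts
("balanced"). This matters for EM: selection shrinks benign-class bags
(via the top-1 fallback) while diseased bags contribute many mislabeled
benign tiles, and an unweighted M-step can then relabel the shared
benign texture as a diseased class and never prune it. The autoencoder
(default E = 32, MSE loss, sigmoid output) has no dropout and no
augmentation.

## EM selection defaults

The smoothed-probability threshold defaults to 0.5 and the lattice
smoothing bandwidth to σ = 0.5 (kernel truncated at 3σ, renormalized
over present cells so constants are preserved and missing tiles are
ignored). The threshold must exceed the posterior a non-discriminative
tile receives under bag labels — approximately the class prior (~1/K for
a texture shared by all bags) — otherwise every tile stays selected and
the loop never prunes; 0.5 is the natural "more likely than not"
choice. A narrow kernel regularizes isolated misclassifications without
averaging scattered minority lesions into their benign surroundings: at
σ = 1 a lone lesion tile keeps only ~16% of its own evidence and falls
below any workable threshold. If no tile clears the threshold the
single maximum cell is kept, so no slide contributes an empty bag.
Convergence: `epsilon` = 0.01 flipped fraction, at most 10 iterations;
on the reference cohort the loop converges in 3.

## Codebooks

GMM codebooks use diagonal covariances floored at 1e-6 (small-sample
stability at large K), are initialized from a k-means fit with the same
seed, and use a single restart. Posteriors are computed with
log-sum-exp normalization. Hard assignment breaks distance ties toward
the lowest centroid index. Default codebook sizes for classification
follow the reference selections (150 for GMM, 200 for KM + SVM, 100 for
KM + RF); interpretability analyses instead use a compact K = 16
codebook, because single-feature permutation importance dilutes toward
zero when each concept carries ~1/150 of the histogram mass on a
desk-scale evaluation set of under a hundred slides.

## Evaluation

Cross-validation is patient-grouped: patients are shuffled and dealt
round-robin into k folds (sizes differ by ≤ 1), and every slide inherits
its patient's fold, so no patient straddles folds. Per-class metrics
are one-vs-rest within each held-out fold; "accuracy" per class is
binarized accuracy (the only reading under which per-class accuracy
differs across classes); weighted averages use true-class supports; the
report also carries plain multiclass accuracy as `overall_accuracy`.
Fold means get 95% t-intervals, clipped into [0, 1]. A fold where a
class's AUC is undefined is excluded from that class's AUC mean with a
warning. In the model grid, tile-level models are trained on a
patient-grouped 20% of the cohort and cross-validation runs on the
remaining slides, mirroring the usual separation between representation
learning and classifier evaluation and preventing tile-level leakage
into the folds; all models in one grid run share a single fold
assignment. The label-permutation chance control is evaluated with the
random-forest fusion classifier on `overall_accuracy`, whose chance
level is 1/K; margin-based SVM fits under permuted labels show the
well-known pessimistic bias of cross-validated permutation tests and
sit below chance.

## Permutation importance

Per-concept importance for class C is the mean increase, over R = 10
shuffles of that histogram column across slides, of the one-vs-rest 0/1
error for C on the evaluation set. One-vs-rest error makes the
importance class-specific, as the tile propagation formula requires; raw
(unnormalized) importances are used. A constant column has importance
exactly 0. Heatmap rendering min-max normalizes per slide and class
(all-equal maps render at uniform mid-scale), leaves filtered cells
transparent, and maps high importance to the red end of the colormap.

## Synthetic cohort

The generator emulates the statistical structure of a 3-class esophageal
cohort, not its biology. Class textures are oriented sinusoidal
gratings (frequencies 3, 5, 7 cycles/tile; orientations spread over
180°) around mid-gray with additive Gaussian noise (`texture_noise`,
default 0.1); background tiles are near-white and fail the tissue
filter by construction. The first class ("squamous") doubles as the
shared benign tissue: diseased slides carry exactly
`round(lesion_fraction × n_tissue)` lesion-texture tiles (default 30%)
and benign texture elsewhere, so weak-supervision routes face the
intended minority-discriminative bags. Slides-per-patient cycles
deterministically through the configured range and labels are assigned
round-robin, making per-class slide counts seed-invariant; all pixel
content is a pure function of the parameters. Defaults: 30 patients,
2–4 slides each, 8×8 lattice of 64-px tiles, 20% background. RGB mode
multiplies the texture by a per-slide random gain vector normalized to
unit luminance, so grayscale conversion cancels the cast up to
clipping.

What the generator does *not* emulate — nuclear morphology, texture
gradients within a lesion, magnification pyramids, annotation noise,
heavier class overlap — bounds what passing tests show: they validate
the pipeline's mechanics (exact encodings, selection dynamics, fold
hygiene, localization) under a separable cohort, not clinical
performance. Raising `texture_noise` is the single knob for making the
cohort arbitrarily harder, and the nearest-centroid degradation check
keeps that knob honest.

## Problem sizes

Tests and the acceptance script run at the default cohort scale
(~90 slides, ~4,600 retained tiles); unit tests use a 12-slide cohort of
32-px tiles with proportionally more training epochs, since a 100-tile
training set sees only a handful of optimizer steps per epoch. Exact
oracle checks (histogram arithmetic, GMM posteriors) use 1,000 random
cases each.

## Known limitations

- The dense backend caps realistic tile sizes at desk scale; it is a
  stand-in architecture, not an attempt at state-of-the-art tile
  classification.
- Stain handling is grayscale conversion only; sparse-NMF stain
  normalization is out of scope.
- The EM variant implements the single-threshold selection rule only,
  not class-level percentile thresholds.
- GMM codebooks with K far above the number of distinct tissue patterns
  fragment clusters; classification is unaffected but per-concept
  importances spread thin (hence the compact interpretability codebook).
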