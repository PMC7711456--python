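"""The unsupervised route end to end: autoencoder embeddings, GMM
codebook, soft histogram encoding, and cross-validated decision fusion.

Prints the weighted per-class metrics with their 95% confidence
intervals over patient-grouped folds.
"""

import numpy as np

from histocode import encoding
from histocode.codebook import fit_gmm_codebook
from histocode.slide_inference import evaluate_cv
from histocode.synthetic import CohortParams, generate_cohort
from histocode.tile_models import train_autoencoder
from histocode.tiling import extract_and_filter_tiles

slides, truth, manifest = generate_cohort(
    CohortParams(n_patients=12, slides_per_patient=(2, 2), seed=0)
)
tiles_by = {
    s.slide_id: extract_and_filter_tiles(s.image, 64, slide_id=s.slide_id)
    for s in slides
}
all_tiles = [t for s in slides for t in tiles_by[s.slide_id]]
print(f"{len(slides)} slides, {len(all_tiles)} tissue tiles retained")

cae = train_autoencoder(all_tiles, embed_dim=32)
codebook = fit_gmm_codebook(cae.embed_batch(all_tiles), K=16, seed=0)
mapper = encoding.codebook_mapper(cae, codebook)
H = np.stack(
    [encoding.encode_soft(tiles_by[s.slide_id], mapper, s.slide_id).values
     for s in slides]
)
print("histogram matrix:", H.shape, "— every row sums to",
      float(H.sum(axis=1).round(12).max()))

report = evaluate_cv(
    H, [s.label for s in slides], [s.patient_id for s in slides],
    kind="svm", k=6, seed=0, model_id="GMM-SVM",
)
print("\nweighted cross-validated metrics (mean [95% CI]):")
for row in report.weighted.itertuples():
    print(f"  {row.metric:>17}: {row.mean:.3f} [{row.ci_low:.3f}, {row.ci_high:.3f}]")
# Values of 1.0 mean every held-out slide was assigned its true class:
# the three planted texture populations produce cleanly separated
# concept histograms.
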