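"""Class-specific heatmaps for the unsupervised route.

Codebook concepts have no class meaning of their own, so per-concept
importance for a class is measured by permutation importance of the
slide-level classifier, then propagated to each tile as the posterior-
weighted sum I_x(C) = sum_m p(c_m | f(x)) I_{c_m}(C).  The rendered
overlay highlights where the model believes the class-discriminative
tissue sits.
"""

import numpy as np
import imageio.v3 as iio
from pathlib import Path
from sklearn.metrics import roc_auc_score

from histocode import encoding
from histocode.codebook import fit_gmm_codebook, posterior
from histocode.interpretability import (
    permutation_importance,
    render_heatmap,
    tile_importance,
    tile_importance_map,
)
from histocode.slide_inference import train_fusion_classifier
from histocode.synthetic import CohortParams, generate_cohort
from histocode.tile_models import train_autoencoder
from histocode.tiling import extract_and_filter_tiles, lattice_shape

slides, truth, _ = generate_cohort(
    CohortParams(n_patients=12, slides_per_patient=(2, 2), seed=0)
)
tiles_by = {
    s.slide_id: extract_and_filter_tiles(s.image, 64, slide_id=s.slide_id)
    for s in slides
}
all_tiles = [t for s in slides for t in tiles_by[s.slide_id]]
cae = train_autoencoder(all_tiles, embed_dim=32)
codebook = fit_gmm_codebook(cae.embed_batch(all_tiles), K=16, seed=0)
mapper = encoding.codebook_mapper(cae, codebook)
H = np.stack(
    [encoding.encode_soft(tiles_by[s.slide_id], mapper, s.slide_id).values
     for s in slides]
)
labels = np.array([s.label for s in slides])
model = train_fusion_classifier(H, labels, "svm", seed=0)
importances = permutation_importance(
    model, H, labels, "dysplastic", repeats=10, seed=0
)
print("top-3 codeblocks for 'dysplastic':", np.argsort(importances)[::-1][:3])

rec = next(s for s in slides if s.label == "dysplastic")
tl = tiles_by[rec.slide_id]
post = posterior(codebook, cae.embed_batch(tl))
m = tile_importance_map(
    post, tl, lattice_shape(rec.image.shape, 64), importances,
    slide_id=rec.slide_id, class_label="dysplastic",
)
overlay = render_heatmap(m, tile_size=64)
out = Path("scratch/heatmap_dysplastic.png")
out.parent.mkdir(exist_ok=True)
iio.imwrite(out, overlay)
print("overlay written to", out)

tru = truth.set_index(["slide_id", "row", "col"]).truth_class
y = [tru[(rec.slide_id, t.row, t.col)] == "dysplastic" for t in tl]
auc = roc_auc_score(y, tile_importance(post, importances))
print(f"lesion localization AUC on this slide: {auc:.3f}")
# AUC 1.0 = the heatmap ranks every planted lesion tile above every
# benign tile, i.e. the model's attention sits exactly on the lesions.
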