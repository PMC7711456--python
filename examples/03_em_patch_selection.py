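"""EM discriminative-patch selection under weak (slide-level) labels.

Starting from "every tile is discriminative", the loop alternates
retraining the tile classifier on selected tiles with re-estimating the
per-tile indicators from smoothed slide-class probability maps.  The
printout compares the final selection against the planted lesion tiles.
"""

import numpy as np

from histocode.concept_mappers import EMConfig, em_train
from histocode.synthetic import CohortParams, generate_cohort
from histocode.tile_models import TrainConfig
from histocode.tiling import TilingParams

params = CohortParams(n_patients=8, slides_per_patient=(2, 2),
                      grid_side=6, tile_size=32, seed=0)
slides, truth, _ = generate_cohort(params)
clf, masks, log = em_train(
    slides,
    EMConfig(tiling=TilingParams(tile_size=32),
             train=TrainConfig(epochs=30, seed=0)),
)

print("EM iteration log (fraction of indicators that flipped):")
print(log.to_string(index=False))

tru = truth.set_index(["slide_id", "row", "col"]).truth_class
inter = union = 0
for rec in slides:
    if rec.label == "squamous":
        continue
    m = masks[rec.slide_id]
    for r, c in zip(*np.where(m.present)):
        lesion = tru[(rec.slide_id, int(r), int(c))] == rec.label
        z = bool(m.z[r, c])
        inter += int(z and lesion)
        union += int(z or lesion)
print(f"\nlesion-tile Jaccard on diseased slides: {inter / union:.3f}")
# A Jaccard near 1 means the loop pruned the mislabeled benign tiles out
# of the diseased bags and kept exactly the planted minority lesions.
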