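"""Generate a small synthetic slide cohort and inspect its structure.

Each slide is a lattice of 64-px tiles: near-white background, shared
benign (squamous-textured) tissue, and — on diseased slides only — a 30%
minority of class-specific lesion tiles.  Slides come in patient groups.
"""

from histocode.synthetic import CohortParams, generate_cohort, write_cohort

params = CohortParams(n_patients=6, slides_per_patient=(2, 2), seed=0)
slides, truth, manifest = generate_cohort(params)

print(f"{len(slides)} slides from {manifest.patient_id.nunique()} patients")
print("slides per class:", manifest.label.value_counts().to_dict())
per_slide = truth[truth.slide_id == "S0002"].truth_class.value_counts()
print("tile composition of one dysplastic slide:", per_slide.to_dict())

path = write_cohort(slides, truth, manifest, "scratch/example_cohort", params)
print("cohort written to", path.parent)
# The dysplastic slide holds 64 tiles: ~13 background, ~15 lesion-texture
# tiles (round(0.3 * 51 tissue tiles)) and the rest benign texture —
# the minority-discriminative bag structure the weak-supervision models
# must cope with.
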