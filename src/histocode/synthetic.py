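"""Synthetic slide cohorts with the bag-of-tiles structure the analysis
assumes.

Real esophageal cohorts cannot be redistributed, so every downstream stage
is exercised on generated slides that reproduce the *statistical* shape of
the problem rather than its biology: each slide is a lattice of fixed-size
tiles; the first class plays the role of shared benign tissue; slides of
every other ("diseased") class contain only a minority of tiles carrying
their class-specific texture, the remainder being benign tissue and
near-white background; slides come in patient groups; and an optional RGB
mode adds per-slide color casts that grayscale conversion largely cancels.

Class textures are oriented sinusoidal gratings with class-specific
spatial frequency and orientation plus additive Gaussian noise — cheap,
seedable, and with a single knob (``texture_noise``) controlling class
overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .tiling import DEFAULT_BACKGROUND_THRESHOLD, TilePatch, tissue_fraction

#: Mask / truth value for background (non-tissue) tiles.
BACKGROUND = 255
BACKGROUND_NAME = "background"

_GRATING_AMPLITUDE = 0.28
_GRATING_MEAN = 0.5


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; the defaults define the reference study cohort.

    ``lesion_fraction`` is the fraction of tissue tiles in a diseased slide
    (any class after the first) that carry the class-discriminative
    texture; all other tissue tiles carry the benign (first-class)
    texture.
    """

    n_patients: int = 30
    slides_per_patient: tuple[int, int] = (2, 4)
    grid_side: int = 8
    tile_size: int = 64
    class_names: tuple[str, ...] = ("squamous", "ndbe", "dysplastic")
    lesion_fraction: float = 0.3
    background_fraction: float = 0.2
    texture_noise: float = 0.1
    color_mode: str = "grayscale"  # or "rgb"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.lesion_fraction <= 1.0):
            raise ValueError("lesion_fraction must be in (0, 1]")
        if self.background_fraction + self.lesion_fraction > 1.0:
            raise ValueError("background_fraction + lesion_fraction must be <= 1")
        if self.grid_side < 2:
            raise ValueError("grid_side must be >= 2")
        if len(self.class_names) < 2:
            raise ValueError("need at least 2 classes")
        if self.color_mode not in ("grayscale", "rgb"):
            raise ValueError("color_mode must be 'grayscale' or 'rgb'")
        lo, hi = self.slides_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("slides_per_patient must be an increasing range")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class SlideRecord:
    """One slide: raster image, label, patient group and annotation mask.

    ``mask`` holds the per-pixel class index (``BACKGROUND`` = 255 for
    glass); ``image`` is float in [0, 1], grayscale or RGB.
    """

    slide_id: str
    patient_id: str
    label: str
    image: np.ndarray
    mask: np.ndarray | None = None


def texture_params(class_id: int, n_classes: int) -> tuple[float, float]:
    """(cycles per tile, orientation in radians) for a texture class.

    Frequencies 3, 5, 7, ... and evenly spread orientations keep the class
    spectra distinct and safely below the Nyquist limit of the model input
    resolution.
    """
    return 3.0 + 2.0 * class_id, np.pi * class_id / n_classes


def render_tile_texture(class_id, params: CohortParams, seed: int) -> TilePatch:
    """Render one grayscale tile of a texture class (or ``"background"``).

    Same ``(class_id, seed)`` always yields a bit-identical tile.  Tissue
    textures are gratings around mid-gray; background tiles are near-white
    so they fail the default tissue filter.
    """
    rng = np.random.default_rng(seed)
    s = params.tile_size
    if class_id == BACKGROUND_NAME or class_id == BACKGROUND:
        px = 0.97 + 0.01 * rng.standard_normal((s, s))
    else:
        class_id = int(class_id)
        if not 0 <= class_id < params.n_classes:
            raise ValueError(f"unknown class_id {class_id!r}")
        freq, theta = texture_params(class_id, params.n_classes)
        yy, xx = np.mgrid[0:s, 0:s] / s
        phase = 2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta))
        px = _GRATING_MEAN + _GRATING_AMPLITUDE * np.sin(phase)
        px = px + params.texture_noise * rng.standard_normal((s, s))
    px = np.clip(px, 0.0, 1.0)
    return TilePatch(pixels=px, tissue_fraction=tissue_fraction(px))


def _slide_seed(base_seed: int, index: int) -> int:
    # stable per-slide substream, kept below 2**31
    return int((base_seed * 1_000_003 + 7_919 * index) % (2**31 - 1))


def generate_slide(
    label: str, params: CohortParams, seed: int, slide_id: str = "S0000",
    patient_id: str = "P000",
) -> tuple[SlideRecord, pd.DataFrame]:
    """Generate one slide and its per-tile ground truth.

    Tile budget: ``round(background_fraction * n_total)`` background tiles;
    for a diseased slide, ``round(lesion_fraction * n_tissue)`` lesion
    tiles; all remaining tissue tiles carry the benign (first-class)
    texture.  Truth rows give each lattice cell's texture class name or
    ``"background"``.
    """
    if label not in params.class_names:
        raise ValueError(f"label {label!r} not in class_names")
    rng = np.random.default_rng(seed)
    li = params.class_names.index(label)
    g = params.grid_side
    n_total = g * g
    n_bg = int(round(params.background_fraction * n_total))
    n_tissue = n_total - n_bg
    n_lesion = 0 if li == 0 else int(round(params.lesion_fraction * n_tissue))

    order = rng.permutation(n_total)
    cell_class = np.zeros(n_total, dtype=int)  # benign texture by default
    cell_class[order[:n_bg]] = BACKGROUND
    cell_class[order[n_bg : n_bg + n_lesion]] = li

    s = params.tile_size
    image = np.empty((g * s, g * s), dtype=float)
    mask = np.empty((g * s, g * s), dtype=np.uint8)
    rows = []
    for cell in range(n_total):
        r, c = divmod(cell, g)
        cid = cell_class[cell]
        tile_cid = BACKGROUND_NAME if cid == BACKGROUND else int(cid)
        tile = render_tile_texture(
            tile_cid, params, _slide_seed(seed, cell + 1)
        )
        image[r * s : (r + 1) * s, c * s : (c + 1) * s] = tile.pixels
        mask[r * s : (r + 1) * s, c * s : (c + 1) * s] = cid
        rows.append(
            {
                "slide_id": slide_id,
                "row": r,
                "col": c,
                "truth_class": BACKGROUND_NAME
                if cid == BACKGROUND
                else params.class_names[cid],
            }
        )

    if params.color_mode == "rgb":
        gains = rng.uniform(0.7, 1.3, size=3)
        # normalize so the luminance-weighted gain is 1: grayscale
        # conversion then cancels the cast (up to clipping)
        gains = gains / (gains @ np.array([0.299, 0.587, 0.114]))
        image = np.clip(image[:, :, None] * gains[None, None, :], 0.0, 1.0)

    record = SlideRecord(
        slide_id=slide_id, patient_id=patient_id, label=label, image=image, mask=mask
    )
    return record, pd.DataFrame(rows)


def generate_cohort(
    params: CohortParams,
) -> tuple[list[SlideRecord], pd.DataFrame, pd.DataFrame]:
    """Generate the full cohort: slides, truth table and manifest.

    Slides-per-patient cycles deterministically through the configured
    range and labels are assigned round-robin over slides, so per-class
    slide counts depend only on the parameters, not the seed.  Pixel
    content is a pure function of ``params`` (including ``params.seed``).
    """
    lo, hi = params.slides_per_patient
    span = hi - lo + 1
    slides: list[SlideRecord] = []
    truths = []
    manifest_rows = []
    j = 0
    for i in range(params.n_patients):
        patient_id = f"P{i:03d}"
        for _ in range(lo + (i % span)):
            label = params.class_names[j % params.n_classes]
            slide_id = f"S{j:04d}"
            record, truth = generate_slide(
                label,
                params,
                seed=_slide_seed(params.seed, j),
                slide_id=slide_id,
                patient_id=patient_id,
            )
            slides.append(record)
            truths.append(truth)
            manifest_rows.append(
                {
                    "slide_id": slide_id,
                    "patient_id": patient_id,
                    "label": label,
                    "image": f"{slide_id}.png",
                    "mask": f"{slide_id}_mask.png",
                }
            )
            j += 1
    return slides, pd.concat(truths, ignore_index=True), pd.DataFrame(manifest_rows)


# --------------------------------------------------------------------- #
# disk round-trip

def write_cohort(
    slides: list[SlideRecord],
    truth: pd.DataFrame,
    manifest: pd.DataFrame,
    outdir,
    params: CohortParams | None = None,
) -> Path:
    """Write slide/mask PNGs, manifest CSV and truth CSV; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in slides:
        img8 = np.clip(np.round(rec.image * 255), 0, 255).astype(np.uint8)
        iio.imwrite(outdir / f"{rec.slide_id}.png", img8)
        if rec.mask is not None:
            iio.imwrite(outdir / f"{rec.slide_id}_mask.png", rec.mask)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    truth.to_csv(outdir / "truth.csv", index=False)
    if params is not None:
        (outdir / "cohort.json").write_text(
            json.dumps(
                {
                    "class_names": list(params.class_names),
                    "tile_size": params.tile_size,
                    "grid_side": params.grid_side,
                    "seed": params.seed,
                },
                indent=2,
            )
        )
    return manifest_path


def load_cohort(manifest_path) -> tuple[list[SlideRecord], pd.DataFrame]:
    """Read a written cohort back into memory."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    slides = []
    for row in manifest.itertuples():
        image = iio.imread(root / row.image).astype(float) / 255.0
        mask = None
        mask_path = root / row.mask if isinstance(row.mask, str) else None
        if mask_path is not None and mask_path.exists():
            mask = iio.imread(mask_path).astype(np.uint8)
        slides.append(
            SlideRecord(
                slide_id=row.slide_id,
                patient_id=row.patient_id,
                label=row.label,
                image=image,
                mask=mask,
            )
        )
    return slides, manifest
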