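"""Tile training sets for the supervised routes and the EM loop that
selects discriminative tiles under weak (slide-level) supervision.

Fully supervised (FS): tiles are labeled from per-pixel annotation masks.
MIL: every tile inherits its slide's label; bags are labeled, instances
are not, so a diseased slide's benign tiles carry wrong labels.
EM: hidden per-tile indicators z mark discriminative tiles. All tiles
start with z=1; each M-step retrains the tile classifier on the z=1
tiles (with bag labels) and each E-step re-estimates z by Gaussian
smoothing of the slide-class probability over the tile lattice and
thresholding. Iteration stops when the fraction of flipped indicators
drops below ``epsilon``.

A tile whose posterior for its slide's class is not above threshold is
judged non-discriminative.  The threshold default is 0.5 ("more likely
than not"): under bag labels, a benign tile shared by all classes
receives roughly the class-prior posterior (~1/K), so any threshold at
or below chance would select essentially every tile and the loop would
never prune.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import BACKGROUND, SlideRecord
from .tile_models import TileClassifier, TrainConfig, train_tile_classifier
from .tiling import TilePatch, TilingParams, extract_and_filter_tiles, lattice_shape


@dataclass
class DiscriminativeMask:
    """Per-tile smoothed slide-class probability and binary indicator z
    for one slide. Grids cover the full lattice; cells whose tile was
    filtered out are NaN / False."""

    slide_id: str
    smoothed: np.ndarray  # (rows, cols), NaN where no retained tile
    z: np.ndarray  # (rows, cols) bool, False where no retained tile
    present: np.ndarray  # (rows, cols) bool


# --------------------------------------------------------------------- #
# tile-set construction

def build_fs_tileset(
    slides: Sequence[SlideRecord],
    tiling: TilingParams = TilingParams(),
    min_coverage: float = 0.5,
) -> tuple[list[TilePatch], list[int]]:
    """Label retained tiles from annotation masks.

    A tile is labeled with class c iff at least ``min_coverage`` of its
    pixels carry mask value c; tiles meeting no class at that coverage are
    excluded.  Background mask pixels (255) never label a tile.
    """
    tiles: list[TilePatch] = []
    labels: list[int] = []
    stride = tiling.stride or tiling.tile_size
    for rec in slides:
        if rec.mask is None:
            raise ValueError(f"slide {rec.slide_id} has no annotation mask")
        for t in extract_and_filter_tiles(
            rec.image, tiling.tile_size, stride, tiling.min_tissue,
            tiling.background_threshold, slide_id=rec.slide_id,
        ):
            y, x = t.row * stride, t.col * stride
            mwin = rec.mask[y : y + tiling.tile_size, x : x + tiling.tile_size]
            vals, counts = np.unique(mwin, return_counts=True)
            keep = vals != BACKGROUND
            vals, counts = vals[keep], counts[keep]
            if len(vals) == 0:
                continue
            best = counts.argmax()
            if counts[best] / mwin.size >= min_coverage:
                tiles.append(t)
                labels.append(int(vals[best]))
    return tiles, labels


def build_mil_tileset(
    slides: Sequence[SlideRecord],
    tiling: TilingParams = TilingParams(),
) -> tuple[list[TilePatch], list]:
    """Label every retained tile with its slide's label (bag labels)."""
    tiles: list[TilePatch] = []
    labels: list = []
    stride = tiling.stride or tiling.tile_size
    for rec in slides:
        if rec.label is None:
            raise ValueError(f"slide {rec.slide_id} has no label")
        slide_tiles = extract_and_filter_tiles(
            rec.image, tiling.tile_size, stride, tiling.min_tissue,
            tiling.background_threshold, slide_id=rec.slide_id,
        )
        tiles.extend(slide_tiles)
        labels.extend([rec.label] * len(slide_tiles))
    return tiles, labels


# --------------------------------------------------------------------- #
# smoothing and selection

def smooth_probability_map(prob_map: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth a lattice value grid, ignoring missing (NaN) cells.

    The kernel (sd ``sigma`` lattice units, truncated at 3 sigma) is
    renormalized over the present cells, so a constant map is unchanged
    and ``sigma=0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    grid = np.asarray(prob_map, dtype=float)
    present = np.isfinite(grid)
    if sigma == 0:
        return grid.copy()
    radius = max(1, math.ceil(3 * sigma))
    ax = np.arange(-radius, radius + 1)
    k1 = np.exp(-0.5 * (ax / sigma) ** 2)
    kernel = np.outer(k1, k1)
    num = ndimage.convolve(
        np.where(present, grid, 0.0), kernel, mode="constant", cval=0.0
    )
    den = ndimage.convolve(present.astype(float), kernel, mode="constant", cval=0.0)
    out = np.full_like(grid, np.nan)
    out[present] = num[present] / den[present]
    return out


def select_discriminative(
    smoothed: np.ndarray, threshold: float, slide_id: str = ""
) -> DiscriminativeMask:
    """Threshold a smoothed slide-class probability grid into indicators.

    z=1 iff the smoothed value exceeds ``threshold``; if no cell does, the
    single maximum-value cell is kept (first in row-major order on ties)
    so a slide never contributes an empty bag.
    """
    grid = np.asarray(smoothed, dtype=float)
    present = np.isfinite(grid)
    z = np.where(present, grid > threshold, False)
    if present.any() and not z.any():
        z.flat[np.nanargmax(grid)] = True
    return DiscriminativeMask(slide_id=slide_id, smoothed=grid, z=z, present=present)


# --------------------------------------------------------------------- #
# EM loop

@dataclass(frozen=True)
class EMConfig:
    """EM discriminative-selection settings.

    ``threshold=None`` resolves to 0.5 (see module docstring); ``sigma``
    is the smoothing sd in lattice units; iteration stops when the
    fraction of flipped z falls below ``epsilon`` or ``max_iters`` is
    reached.
    """

    threshold: float | None = None
    sigma: float = 0.5
    epsilon: float = 0.01
    max_iters: int = 10
    train: TrainConfig = TrainConfig()
    tiling: TilingParams = TilingParams()


def em_train(
    slides: Sequence[SlideRecord],
    config: EMConfig = EMConfig(),
) -> tuple[TileClassifier, dict[str, DiscriminativeMask], pd.DataFrame]:
    """Run the EM discriminative-patch loop over a labeled cohort.

    Returns the final tile classifier, the final per-slide masks, and an
    iteration log (iteration, changed_fraction, n_selected).  With
    ``max_iters=1`` and ``threshold=0`` this is exactly one MIL training
    run: all z start at 1, and every positive probability re-selects.
    """
    if config.max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    labels_present = {rec.label for rec in slides}
    if len(labels_present) < 2:
        raise ValueError("need slides from at least 2 classes")
    threshold = 0.5 if config.threshold is None else config.threshold
    tp = config.tiling
    stride = tp.stride or tp.tile_size

    per_slide: list[tuple[SlideRecord, list[TilePatch], tuple[int, int]]] = []
    for rec in slides:
        tiles = extract_and_filter_tiles(
            rec.image, tp.tile_size, stride, tp.min_tissue,
            tp.background_threshold, slide_id=rec.slide_id,
        )
        per_slide.append((rec, tiles, lattice_shape(rec.image.shape, tp.tile_size, stride)))

    # initial E-step: every tile is discriminative
    z_state = {rec.slide_id: np.ones(len(tiles), dtype=bool) for rec, tiles, _ in per_slide}
    n_total = sum(len(tiles) for _, tiles, _ in per_slide)
    masks: dict[str, DiscriminativeMask] = {}
    log_rows = []
    clf: TileClassifier | None = None

    for iteration in range(1, config.max_iters + 1):
        # M-step: retrain (fresh, same seed) on the selected tiles
        train_tiles: list[TilePatch] = []
        train_labels: list = []
        for rec, tiles, _ in per_slide:
            sel = z_state[rec.slide_id]
            train_tiles.extend(t for t, keep in zip(tiles, sel) if keep)
            train_labels.extend([rec.label] * int(sel.sum()))
        clf = train_tile_classifier(train_tiles, train_labels, config.train)

        # E-step: smoothed slide-class probability -> new indicators
        changed = 0
        for rec, tiles, (n_rows, n_cols) in per_slide:
            if not tiles:
                masks[rec.slide_id] = DiscriminativeMask(
                    slide_id=rec.slide_id,
                    smoothed=np.full((n_rows, n_cols), np.nan),
                    z=np.zeros((n_rows, n_cols), dtype=bool),
                    present=np.zeros((n_rows, n_cols), dtype=bool),
                )
                continue
            probs = clf.predict_proba(tiles)[:, clf.classes.index(rec.label)]
            grid = np.full((n_rows, n_cols), np.nan)
            for t, p in zip(tiles, probs):
                grid[t.row, t.col] = p
            mask = select_discriminative(
                smooth_probability_map(grid, config.sigma), threshold, rec.slide_id
            )
            masks[rec.slide_id] = mask
            new_z = np.array([mask.z[t.row, t.col] for t in tiles], dtype=bool)
            changed += int((new_z != z_state[rec.slide_id]).sum())
            z_state[rec.slide_id] = new_z
        changed_fraction = changed / max(n_total, 1)
        n_selected = int(sum(z.sum() for z in z_state.values()))
        log_rows.append(
            {"iteration": iteration, "changed_fraction": changed_fraction,
             "n_selected": n_selected}
        )
        if changed_fraction < config.epsilon:
            break

    return clf, masks, pd.DataFrame(log_rows)


def masks_frame(masks: dict[str, DiscriminativeMask], iteration: int = -1) -> pd.DataFrame:
    """Flatten masks to rows (slide_id, row, col, z, smoothed_value,
    iteration) for CSV export."""
    rows = []
    for slide_id, m in masks.items():
        for r, c in zip(*np.where(m.present)):
            rows.append(
                {"slide_id": slide_id, "row": int(r), "col": int(c),
                 "z": int(m.z[r, c]), "smoothed_value": float(m.smoothed[r, c]),
                 "iteration": iteration}
            )
    return pd.DataFrame(rows)
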