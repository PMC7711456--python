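"""Sliding-window tile extraction, tissue filtering, grayscale conversion
and training-time augmentation.

A whole-slide image is processed as a bag of fixed-size tiles laid out on
a regular lattice.  A pixel counts as tissue when its grayscale intensity
falls below a near-white background threshold; tiles with too little
tissue are discarded before any modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Rec. 601 luminance weights used for RGB -> grayscale conversion.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Grayscale intensity at or above which a pixel is treated as background.
DEFAULT_BACKGROUND_THRESHOLD = 0.9

#: Minimum tissue fraction for a tile to be retained.
DEFAULT_MIN_TISSUE = 0.5


@dataclass
class TilePatch:
    """A fixed-size tile cut from a slide.

    ``pixels`` is ``(s, s)`` grayscale or ``(s, s, 3)`` RGB with values in
    ``[0, 1]``; ``row``/``col`` are 0-based lattice coordinates (row-major,
    top-left origin); ``tissue_fraction`` is the fraction of non-background
    pixels.
    """

    pixels: np.ndarray
    row: int = 0
    col: int = 0
    tissue_fraction: float = 1.0
    slide_id: str | None = None

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3


@dataclass(frozen=True)
class TilingParams:
    """Extraction settings shared across a cohort run."""

    tile_size: int = 64
    stride: int | None = None  # None -> tile_size (non-overlapping)
    min_tissue: float = DEFAULT_MIN_TISSUE
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD


def gray_view(pixels: np.ndarray) -> np.ndarray:
    """Grayscale view of an image array (identity for 2-D input)."""
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim == 3 and pixels.shape[-1] == 3:
        return pixels @ GRAY_WEIGHTS
    raise ValueError(f"expected (H,W) or (H,W,3) image, got shape {pixels.shape}")


def tissue_fraction(
    pixels: np.ndarray, background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD
) -> float:
    """Fraction of pixels whose grayscale intensity is below the background
    threshold (i.e. that look like tissue rather than glass)."""
    return float(np.mean(gray_view(pixels) < background_threshold))


def to_grayscale(tile: TilePatch) -> TilePatch:
    """Luminance-weighted grayscale conversion; grayscale input passes
    through unchanged."""
    if not tile.is_rgb:
        return tile
    return replace(tile, pixels=np.clip(gray_view(tile.pixels), 0.0, 1.0))


def extract_and_filter_tiles(
    image: np.ndarray,
    tile_size: int,
    stride: int | None = None,
    min_tissue: float = DEFAULT_MIN_TISSUE,
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
    slide_id: str | None = None,
) -> list[TilePatch]:
    """Enumerate tiles row-major over the lattice and keep the ones with at
    least ``min_tissue`` tissue fraction.

    Partial windows at the right/bottom edges are dropped.  Raises
    ``ValueError`` when the image is smaller than one tile.
    """
    if stride is None:
        stride = tile_size
    if not (0.0 < min_tissue <= 1.0):
        raise ValueError("min_tissue must be in (0, 1]")
    h, w = image.shape[:2]
    if h < tile_size or w < tile_size:
        raise ValueError(
            f"image {h}x{w} smaller than one {tile_size}x{tile_size} tile"
        )
    tiles: list[TilePatch] = []
    n_rows = (h - tile_size) // stride + 1
    n_cols = (w - tile_size) // stride + 1
    for r in range(n_rows):
        for c in range(n_cols):
            y, x = r * stride, c * stride
            window = image[y : y + tile_size, x : x + tile_size]
            tf = tissue_fraction(window, background_threshold)
            if tf >= min_tissue:
                tiles.append(
                    TilePatch(
                        pixels=window,
                        row=r,
                        col=c,
                        tissue_fraction=tf,
                        slide_id=slide_id,
                    )
                )
    return tiles


def lattice_shape(image_shape: Sequence[int], tile_size: int, stride: int | None = None):
    """(n_rows, n_cols) of the full tile lattice for an image."""
    if stride is None:
        stride = tile_size
    h, w = image_shape[:2]
    return ((h - tile_size) // stride + 1, (w - tile_size) // stride + 1)


# --------------------------------------------------------------------- #
# augmentation: the 8-element dihedral subset {optional h-flip} x {k*90 deg}

def dihedral(pixels: np.ndarray, transform_id: int) -> np.ndarray:
    """Apply one of the 8 flip/rotation symmetries of the square.

    ``transform_id`` in 0..7: low two bits choose the 90-degree rotation
    count, bit 2 toggles a horizontal flip applied first.
    """
    if not 0 <= transform_id < 8:
        raise ValueError("transform_id must be in 0..7")
    out = pixels
    if transform_id >= 4:
        out = out[:, ::-1]
    k = transform_id % 4
    if k:
        out = np.rot90(out, k)
    return np.ascontiguousarray(out)


def augment(tile: TilePatch, seed: int) -> TilePatch:
    """Random flip/rotation augmentation (training-time only).

    Draws one of the 8 square symmetries from ``seed``; the intensity
    multiset of the tile is preserved exactly.
    """
    if tile.pixels.shape[0] != tile.pixels.shape[1]:
        raise ValueError("augmentation requires square tiles")
    rng = np.random.default_rng(seed)
    return replace(tile, pixels=dihedral(tile.pixels, int(rng.integers(8))))


def standardize_intensity(tile: TilePatch) -> TilePatch:
    """Optional per-tile intensity standardization: subtract the mean,
    divide by the standard deviation, rescale into and re-clip to [0, 1].
    Off by default everywhere; provided as a mild stain-robustness aid."""
    px = tile.pixels.astype(float)
    sd = px.std()
    if sd == 0:
        return tile
    z = (px - px.mean()) / sd
    return replace(tile, pixels=np.clip(z * 0.2 + 0.5, 0.0, 1.0))


def tile_index(tiles: Sequence[TilePatch]) -> pd.DataFrame:
    """Sidecar index of a tile collection."""
    return pd.DataFrame(
        {
            "slide_id": [t.slide_id for t in tiles],
            "row": [t.row for t in tiles],
            "col": [t.col for t in tiles],
            "tissue_fraction": [t.tissue_fraction for t in tiles],
        }
    )
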