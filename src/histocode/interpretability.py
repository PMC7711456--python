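"""Class-specific tile importance and heatmaps.

For class-based mappers (FS/MIL/EM) the heatmap is simply the tile-level
class probability on the slide lattice.  For codebook routes there is no
class-codeblock correspondence, so per-codeblock importance for a class
is measured by permutation importance of the fusion classifier (increase
in one-vs-rest 0/1 error when a histogram column is shuffled across
slides) and propagated to a tile as the posterior-weighted sum

    I_x(C) = sum_m p(c_m | f(x)) * I_{c_m}(C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib import colormaps

from .slide_inference import FusionClassifier, slide_scores
from .tiling import TilePatch


@dataclass
class ImportanceTable:
    """Per-class, per-concept permutation importances (n_classes, K)."""

    values: np.ndarray
    classes: tuple
    repeats: int
    seed: int

    def row(self, class_label) -> np.ndarray:
        return self.values[self.classes.index(class_label)]


@dataclass
class TileImportanceMap:
    """Per-lattice-cell importance for one class on one slide; cells
    without a retained tile are NaN."""

    values: np.ndarray
    slide_id: str | None = None
    class_label: object | None = None


def _predict_labels(model: FusionClassifier, H: np.ndarray) -> np.ndarray:
    S = slide_scores(model, H)
    return model.classes_[S.argmax(axis=1)]


def permutation_importance(
    model: FusionClassifier,
    histograms: np.ndarray,
    labels: Sequence,
    class_label,
    repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Per-concept importance row for one class.

    importance[m] = mean over ``repeats`` shuffles of column m of
    (one-vs-rest 0/1 error for the class after shuffling) minus the
    baseline error.  A constant column yields exactly 0.  Deterministic
    given ``seed``.
    """
    H = np.asarray(histograms, dtype=float)
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if class_label not in set(y):
        raise ValueError(f"class {class_label!r} not present in labels")
    b_true = y == class_label

    def _error(mat):
        return float(np.mean((_predict_labels(model, mat) == class_label) != b_true))

    baseline = _error(H)
    rng = np.random.default_rng(seed)
    K = H.shape[1]
    imp = np.zeros(K)
    for m in range(K):
        errs = []
        for _ in range(repeats):
            perm = rng.permutation(len(y))
            Hs = H.copy()
            Hs[:, m] = H[perm, m]
            errs.append(_error(Hs))
        imp[m] = float(np.mean(errs)) - baseline
    return imp


def importance_table(
    model: FusionClassifier,
    histograms: np.ndarray,
    labels: Sequence,
    repeats: int = 10,
    seed: int = 0,
) -> ImportanceTable:
    """Permutation-importance rows for every class present in the model."""
    classes = tuple(model.classes_)
    rows = [
        permutation_importance(model, histograms, labels, c, repeats, seed)
        for c in classes
    ]
    return ImportanceTable(
        values=np.stack(rows), classes=classes, repeats=repeats, seed=seed
    )


def tile_importance(posteriors: np.ndarray, importance_row: np.ndarray) -> np.ndarray:
    """Propagate codeblock importances to tiles: posterior-weighted sums."""
    P = np.atleast_2d(np.asarray(posteriors, dtype=float))
    w = np.asarray(importance_row, dtype=float)
    if P.shape[1] != w.shape[0]:
        raise ValueError(
            f"posterior length {P.shape[1]} != importance length {w.shape[0]}"
        )
    out = P @ w
    return out[0] if np.ndim(posteriors) == 1 else out


def tile_importance_map(
    posteriors: np.ndarray,
    tiles: Sequence[TilePatch],
    grid_shape: tuple[int, int],
    importance_row: np.ndarray,
    slide_id: str | None = None,
    class_label=None,
) -> TileImportanceMap:
    """Lay per-tile importances out on the slide lattice."""
    vals = tile_importance(posteriors, importance_row)
    grid = np.full(grid_shape, np.nan)
    for t, v in zip(tiles, np.atleast_1d(vals)):
        grid[t.row, t.col] = v
    return TileImportanceMap(values=grid, slide_id=slide_id, class_label=class_label)


def class_probability_heatmap(
    mapper,
    tiles: Sequence[TilePatch],
    grid_shape: tuple[int, int],
    class_index: int,
    slide_id: str | None = None,
) -> TileImportanceMap:
    """Heatmap of p(C | tile) for a class-based mapper on one slide."""
    probs = mapper.predict_proba(tiles)
    if not 0 <= class_index < probs.shape[1]:
        raise ValueError(f"class index {class_index} out of range")
    grid = np.full(grid_shape, np.nan)
    for t, p in zip(tiles, probs[:, class_index]):
        grid[t.row, t.col] = p
    return TileImportanceMap(
        values=grid, slide_id=slide_id, class_label=class_index
    )


def render_heatmap(
    imp_map: TileImportanceMap,
    tile_size: int,
    stride: int | None = None,
    cmap: str = "jet",
) -> np.ndarray:
    """RGBA overlay at slide resolution.

    Values are min-max normalized per slide (an all-equal map renders at
    uniform mid-scale); cells without a tile are fully transparent; high
    importance maps to the top (red) end of the colormap.
    """
    grid = imp_map.values
    if grid.size == 0:
        raise ValueError("empty importance map")
    stride = stride or tile_size
    present = np.isfinite(grid)
    norm = np.full_like(grid, 0.5, dtype=float)
    if present.any():
        vmin, vmax = np.nanmin(grid), np.nanmax(grid)
        if vmax > vmin:
            norm[present] = (grid[present] - vmin) / (vmax - vmin)
    rgba_cells = colormaps[cmap](norm)
    rgba_cells[..., 3] = np.where(present, 0.6, 0.0)
    n_rows, n_cols = grid.shape
    h = (n_rows - 1) * stride + tile_size
    w = (n_cols - 1) * stride + tile_size
    out = np.zeros((h, w, 4))
    for r in range(n_rows):
        for c in range(n_cols):
            out[r * stride : r * stride + tile_size,
                c * stride : c * stride + tile_size] = rgba_cells[r, c]
    return (out * 255).astype(np.uint8)


def maps_frame(maps: Sequence[TileImportanceMap]) -> pd.DataFrame:
    """Flatten maps to rows (slide_id, row, col, value, class)."""
    rows = []
    for m in maps:
        for r, c in zip(*np.where(np.isfinite(m.values))):
            rows.append(
                {"slide_id": m.slide_id, "row": int(r), "col": int(c),
                 "value": float(m.values[r, c]), "class": m.class_label}
            )
    return pd.DataFrame(rows)
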