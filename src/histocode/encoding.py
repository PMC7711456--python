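"""Slide encoding: from a bag of tiles to a concept histogram.

Every representation route ends here.  A slide X = {x_1..x_n} of retained
tissue tiles is mapped to a length-K histogram H = (h_1..h_K):

soft route
    h_k = (1/n) * sum_x p(c_k | f(x))    (class probabilities or GMM
    posteriors)
hard route
    h_k = (1/n) * #{x : assign(x) = k}   (nearest-centroid counts)

The hard route is exactly the soft route applied to one-hot vectors.
Only tiles that survived the tissue filter count toward n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .codebook import CentroidCodebook, GaussianCodebook, hard_assign, posterior
from .tiling import TilePatch


@dataclass
class SlideHistogram:
    """Normalized concept-frequency vector of one slide."""

    values: np.ndarray  # (K,)
    slide_id: str | None = None
    n_tiles: int = 0
    vocabulary: str | None = None


def encode_soft(
    tiles: Sequence[TilePatch],
    mapper: Callable[[Sequence[TilePatch]], np.ndarray],
    slide_id: str | None = None,
    vocabulary: str | None = None,
) -> SlideHistogram:
    """Average the mapper's per-tile probability vectors.

    ``mapper`` maps a tile batch to an (n, K) array of nonnegative rows
    summing to 1.  Raises on an empty bag.
    """
    if len(tiles) == 0:
        raise ValueError("cannot encode a slide with zero retained tiles")
    P = np.asarray(mapper(tiles), dtype=float)
    if P.ndim != 2 or P.shape[0] != len(tiles):
        raise ValueError(f"mapper returned shape {P.shape} for {len(tiles)} tiles")
    return SlideHistogram(
        values=P.mean(axis=0), slide_id=slide_id, n_tiles=len(tiles),
        vocabulary=vocabulary,
    )


def encode_hard(
    tiles: Sequence[TilePatch],
    assigner: Callable[[Sequence[TilePatch]], np.ndarray],
    K: int,
    slide_id: str | None = None,
    vocabulary: str | None = None,
) -> SlideHistogram:
    """Count the assigner's per-tile concept indices and normalize."""
    if len(tiles) == 0:
        raise ValueError("cannot encode a slide with zero retained tiles")
    idx = np.asarray(assigner(tiles), dtype=int)
    counts = np.bincount(idx, minlength=K)
    if len(counts) > K:
        raise ValueError("assigner produced an index >= K")
    return SlideHistogram(
        values=counts / len(tiles), slide_id=slide_id, n_tiles=len(tiles),
        vocabulary=vocabulary,
    )


# --------------------------------------------------------------------- #
# mapper factories for the concrete routes

def classifier_mapper(model) -> Callable[[Sequence[TilePatch]], np.ndarray]:
    """Soft mapper from a trained tile classifier (class vocabulary)."""
    return model.predict_proba


def codebook_mapper(
    autoencoder, codebook: GaussianCodebook
) -> Callable[[Sequence[TilePatch]], np.ndarray]:
    """Soft mapper: autoencoder embedding followed by GMM posteriors."""

    def _map(tiles):
        return posterior(codebook, autoencoder.embed_batch(tiles))

    return _map


def codebook_assigner(
    autoencoder, codebook: CentroidCodebook
) -> Callable[[Sequence[TilePatch]], np.ndarray]:
    """Hard assigner: autoencoder embedding followed by nearest centroid."""

    def _assign(tiles):
        return hard_assign(codebook, autoencoder.embed_batch(tiles))

    return _assign


# --------------------------------------------------------------------- #
def histograms_frame(histograms: Sequence[SlideHistogram]) -> pd.DataFrame:
    K = len(histograms[0].values)
    rows = {f"h_{k}": [h.values[k] for h in histograms] for k in range(K)}
    return pd.DataFrame({"slide_id": [h.slide_id for h in histograms], **rows})


def write_histograms(histograms: Sequence[SlideHistogram], path) -> None:
    """CSV of histogram rows plus a JSON sidecar naming the vocabulary."""
    path = Path(path)
    histograms_frame(histograms).to_csv(path, index=False)
    sidecar = {
        "vocabulary": histograms[0].vocabulary,
        "K": int(len(histograms[0].values)),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
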