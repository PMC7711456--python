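"""Tile-level feature extractors: a softmax tile classifier and an
autoencoder whose encoder provides the low-dimensional embedding f(x).

Both are seeded feed-forward networks over block-mean-downsampled
grayscale tiles (see ``_nn``).  Architecture presets:

``desk``
    Downsample factor 2, one 128-unit ReLU hidden layer, dropout 0.5 on
    the classifier head.  Small enough to train in seconds on a CPU while
    separating the reference synthetic textures essentially perfectly.
``paper-head``
    As ``desk`` but with a 1024-unit dense head (dropout 0.5), mirroring
    the wide dense head of the full-scale reference architecture.

The slide-level pipeline never looks inside these models: any mapping
from tiles to class probabilities / embeddings with the same contracts
can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._nn import DenseNet
from .tiling import TilePatch, dihedral, gray_view

PRESETS = {
    "desk": {"hidden": (128,), "downsample": 2, "dropout": 0.5},
    "paper-head": {"hidden": (1024,), "downsample": 2, "dropout": 0.5},
}


@dataclass(frozen=True)
class TrainConfig:
    """Training settings for both tile models.

    ``hidden``/``downsample``/``dropout`` default to the preset's values
    when ``None``.  Augmentation (random square symmetries) is applied
    during classifier training only.
    """

    preset: str = "desk"
    epochs: int = 12
    batch_size: int = 128
    lr: float = 1e-3
    seed: int = 0
    augment: bool = True
    class_weight: str | None = "balanced"
    hidden: tuple[int, ...] | None = None
    downsample: int | None = None
    dropout: float | None = None

    def resolved(self) -> dict:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        p = dict(PRESETS[self.preset])
        if self.hidden is not None:
            p["hidden"] = tuple(self.hidden)
        if self.downsample is not None:
            p["downsample"] = self.downsample
        if self.dropout is not None:
            p["dropout"] = self.dropout
        return p


def _tile_stack(tiles: Sequence[TilePatch]) -> np.ndarray:
    """Stack tiles as (n, s, s) grayscale float arrays."""
    if len(tiles) == 0:
        raise ValueError("empty tile collection")
    shapes = {t.pixels.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError(f"tiles have mixed shapes: {sorted(shapes)}")
    return np.stack([gray_view(t.pixels) for t in tiles])


def _downsample(stack: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling of a (n, s, s) stack."""
    if factor == 1:
        return stack
    n, s, _ = stack.shape
    if s % factor:
        raise ValueError(f"tile size {s} not divisible by downsample {factor}")
    d = s // factor
    return stack.reshape(n, d, factor, d, factor).mean(axis=(2, 4))


def _augment_stack(stack: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-tile random square symmetry, vectorized per transform group."""
    tids = rng.integers(0, 8, size=stack.shape[0])
    out = np.empty_like(stack)
    for t in range(8):
        sel = tids == t
        if sel.any():
            sub = stack[sel]
            if t >= 4:
                sub = sub[:, :, ::-1]
            k = t % 4
            if k:
                sub = np.rot90(sub, k, axes=(1, 2))
            out[sel] = sub
    return out


@dataclass
class TileClassifier:
    """Softmax classifier over the slide-class vocabulary."""

    net: DenseNet
    classes: tuple
    tile_shape: tuple
    downsample: int
    config: TrainConfig

    def _features(self, tiles: Sequence[TilePatch]) -> np.ndarray:
        stack = _tile_stack(tiles)
        if stack.shape[1:] != self.tile_shape:
            raise ValueError(
                f"tile shape {stack.shape[1:]} != training shape {self.tile_shape}"
            )
        x = _downsample(stack, self.downsample)
        return x.reshape(x.shape[0], -1)

    def predict_proba(self, tiles: Sequence[TilePatch]) -> np.ndarray:
        """(n, K) class probabilities; evaluation mode, deterministic."""
        return self.net.predict(self._features(tiles))

    def predict(self, tiles: Sequence[TilePatch]) -> list:
        return [self.classes[i] for i in self.predict_proba(tiles).argmax(axis=1)]


@dataclass
class Autoencoder:
    """Dense autoencoder; ``embed`` exposes the bottleneck code."""

    net: DenseNet
    embed_dim: int
    tile_shape: tuple
    downsample: int
    config: TrainConfig
    encoder_depth: int = 2

    def _features(self, tiles: Sequence[TilePatch]) -> np.ndarray:
        stack = _tile_stack(tiles)
        if stack.shape[1:] != self.tile_shape:
            raise ValueError(
                f"tile shape {stack.shape[1:]} != training shape {self.tile_shape}"
            )
        x = _downsample(stack, self.downsample)
        return x.reshape(x.shape[0], -1)

    def embed_batch(self, tiles: Sequence[TilePatch]) -> np.ndarray:
        return self.net.encode(self._features(tiles), self.encoder_depth)

    def reconstruct(self, tiles: Sequence[TilePatch]) -> np.ndarray:
        return self.net.predict(self._features(tiles))


def train_tile_classifier(
    tiles: Sequence[TilePatch],
    labels: Sequence,
    config: TrainConfig = TrainConfig(),
) -> TileClassifier:
    """Train the softmax tile classifier.

    Deterministic given ``config.seed`` and the tile order; raises on
    single-class input.  Flip/rotation augmentation is redrawn every epoch
    and applied to the training copies only.
    """
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("need tiles from at least 2 classes")
    p = config.resolved()
    stack = _downsample(_tile_stack(tiles), p["downsample"])
    tile_shape = _tile_stack(tiles[:1]).shape[1:]
    d = stack.shape[1] * stack.shape[2]
    index = {c: i for i, c in enumerate(classes)}
    yi = np.array([index[l] for l in labels])
    Y = np.zeros((len(tiles), len(classes)))
    Y[np.arange(len(tiles)), yi] = 1.0
    sw = None
    if config.class_weight == "balanced":
        # per-class weights averaging to 1, compensating uneven tile counts
        counts = np.bincount(yi, minlength=len(classes)).astype(float)
        sw = (len(tiles) / (len(classes) * counts))[yi]

    sizes = [d, *p["hidden"], len(classes)]
    acts = ["relu"] * len(p["hidden"]) + ["softmax"]
    net = DenseNet(sizes, acts, dropout=p["dropout"], seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    for _ in range(config.epochs):
        x = _augment_stack(stack, rng) if config.augment else stack
        net.train_epoch(
            x.reshape(x.shape[0], -1), Y, rng,
            lr=config.lr, batch_size=config.batch_size, loss="ce",
            sample_weight=sw,
        )
    return TileClassifier(
        net=net,
        classes=classes,
        tile_shape=tile_shape,
        downsample=p["downsample"],
        config=config,
    )


def predict_concept_probabilities(model: TileClassifier, tile: TilePatch) -> np.ndarray:
    """Class-probability vector for a single tile (length K, sums to 1)."""
    return model.predict_proba([tile])[0]


def train_autoencoder(
    tiles: Sequence[TilePatch],
    embed_dim: int = 32,
    config: TrainConfig = TrainConfig(epochs=15, augment=False, dropout=0.0),
) -> Autoencoder:
    """Train the unsupervised embedding model (MSE reconstruction loss).

    ``embed_dim`` must be smaller than the raw tile pixel count.
    """
    stack = _tile_stack(tiles)
    tile_shape = stack.shape[1:]
    raw_dim = int(np.prod(tile_shape))
    if embed_dim >= raw_dim:
        raise ValueError(f"embed_dim {embed_dim} must be < tile dimension {raw_dim}")
    p = config.resolved()
    x = _downsample(stack, p["downsample"])
    X = x.reshape(x.shape[0], -1)
    d = X.shape[1]
    hidden = p["hidden"][0] if p["hidden"] else 128
    sizes = [d, hidden, embed_dim, hidden, d]
    acts = ["relu", "linear", "relu", "sigmoid"]
    net = DenseNet(sizes, acts, dropout=0.0, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    for _ in range(config.epochs):
        net.train_epoch(
            X, X, rng, lr=config.lr, batch_size=config.batch_size, loss="mse"
        )
    return Autoencoder(
        net=net,
        embed_dim=embed_dim,
        tile_shape=tile_shape,
        downsample=p["downsample"],
        config=config,
    )


def embed(model: Autoencoder, tile: TilePatch) -> np.ndarray:
    """Embedding vector of a single tile (length E, deterministic)."""
    return model.embed_batch([tile])[0]
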