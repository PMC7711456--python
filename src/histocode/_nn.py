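"""Seeded dense-network backend for the tile models.

A deliberately small feed-forward implementation (ReLU hidden units,
inverted dropout, Adam) written directly on numpy so that training is
bit-reproducible from a seed on any machine.  The slide-classification
pipeline only requires *some* deterministic tile-level feature extractor;
everything slide-level is agnostic to the backbone.
"""

from __future__ import annotations

import numpy as np

_ACTIVATIONS = ("linear", "relu", "softmax", "sigmoid")


def _apply(z: np.ndarray, act: str) -> np.ndarray:
    if act == "linear":
        return z
    if act == "relu":
        return np.maximum(z, 0.0)
    if act == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if act == "softmax":
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown activation {act!r}")


class DenseNet:
    """Fully connected network with per-layer activations.

    Parameters
    ----------
    sizes
        Layer widths, input first: ``[d_in, h1, ..., d_out]``.
    activations
        One activation name per weight layer (``len(sizes) - 1``).
    dropout
        Inverted-dropout probability applied to every hidden layer's
        activations during training only.
    seed
        Seeds He-style weight initialization.
    """

    def __init__(self, sizes, activations, dropout: float = 0.0, seed: int = 0):
        if len(activations) != len(sizes) - 1:
            raise ValueError("need one activation per weight layer")
        for a in activations:
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")
        rng = np.random.default_rng(seed)
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(fan_out) for fan_out in sizes[1:]]
        self.sizes = list(sizes)
        self.activations = list(activations)
        self.dropout = float(dropout)
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0

    # ------------------------------------------------------------------ #
    def forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Run the network; with ``rng`` given, dropout is active and the
        per-layer cache needed for backprop is returned."""
        a = X
        cache = []
        last = len(self.W) - 1
        for i, (W, b, act) in enumerate(zip(self.W, self.b, self.activations)):
            z = a @ W + b
            h = _apply(z, act)
            mask = None
            if rng is not None and self.dropout > 0.0 and i < last:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
            cache.append((a, z, mask))
            a = h
        return a, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.forward(X)
        return out

    def encode(self, X: np.ndarray, depth: int) -> np.ndarray:
        """Activations after the first ``depth`` weight layers (no dropout)."""
        a = X
        for W, b, act in list(zip(self.W, self.b, self.activations))[:depth]:
            a = _apply(a @ W + b, act)
        return a

    # ------------------------------------------------------------------ #
    def _backward(self, cache, delta):
        """``delta`` is dL/dz at the output layer; returns per-layer grads."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.W)
        for i in range(len(self.W) - 1, -1, -1):
            a_in, _, _ = cache[i]
            gW[i] = a_in.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                dh = delta @ self.W[i].T
                _, z_prev, mask_prev = cache[i - 1]
                if mask_prev is not None:
                    dh = dh * mask_prev
                act_prev = self.activations[i - 1]
                if act_prev == "relu":
                    dh = dh * (z_prev > 0)
                elif act_prev == "sigmoid":
                    s = _apply(z_prev, "sigmoid")
                    dh = dh * s * (1.0 - s)
                # linear: pass through
                delta = dh
        return gW, gb

    def _adam_step(self, gW, gb, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_m is None:
            self._adam_m = [np.zeros_like(p) for p in self.W + self.b]
            self._adam_v = [np.zeros_like(p) for p in self.W + self.b]
        self._adam_t += 1
        t = self._adam_t
        params = self.W + self.b
        grads = gW + gb
        for k, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_epoch(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        rng: np.random.Generator,
        lr: float = 1e-3,
        batch_size: int = 128,
        loss: str = "ce",
        sample_weight: np.ndarray | None = None,
    ) -> float:
        """One pass of minibatch Adam; returns the mean loss over batches.

        ``loss="ce"`` pairs with a softmax output, ``loss="mse"`` with a
        sigmoid or linear output.  ``sample_weight`` rescales each
        sample's loss contribution.
        """
        n = X.shape[0]
        order = rng.permutation(n)
        total = 0.0
        nb = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], Y[idx]
            out, cache = self.forward(xb, rng=rng)
            m = xb.shape[0]
            if loss == "ce":
                losses = -np.sum(yb * np.log(out + 1e-12), axis=1)
                delta = (out - yb) / m
                if sample_weight is not None:
                    w = sample_weight[idx]
                    losses = losses * w
                    delta = delta * w[:, None]
                total += float(np.mean(losses))
            elif loss == "mse":
                total += float(np.mean((out - yb) ** 2))
                delta = 2.0 * (out - yb) / (m * out.shape[1])
                if self.activations[-1] == "sigmoid":
                    delta = delta * out * (1.0 - out)
            else:
                raise ValueError(f"unknown loss {loss!r}")
            gW, gb = self._backward(cache, delta)
            self._adam_step(gW, gb, lr)
            nb += 1
        return total / max(nb, 1)
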