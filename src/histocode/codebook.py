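"""Visual-vocabulary learning over tile embeddings.

A codebook is a set of K "codeblocks" obtained by clustering autoencoder
embeddings: k-means centroids give hard assignments; a Gaussian mixture
(diagonal covariances) gives soft assignments through the component
posterior

    p(c_m | v) = pi_m N(v | mu_m, Sigma_m) / sum_k pi_k N(v | mu_k, Sigma_k),

evaluated in log-space for stability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

#: Variance floor applied to all diagonal covariance entries.
VARIANCE_FLOOR = 1e-6


@dataclass
class CentroidCodebook:
    """K-means codebook: hard visual vocabulary."""

    centroids: np.ndarray  # (K, E)
    seed: int = 0

    @property
    def n_concepts(self) -> int:
        return self.centroids.shape[0]


@dataclass
class GaussianCodebook:
    """Diagonal-covariance Gaussian-mixture codebook: soft vocabulary."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, E)
    covariances: np.ndarray  # (K, E) diagonal entries
    seed: int = 0

    @property
    def n_concepts(self) -> int:
        return self.means.shape[0]


def fit_kmeans_codebook(embeddings: np.ndarray, K: int, seed: int = 0) -> CentroidCodebook:
    """Fit a K-centroid codebook (Lloyd's algorithm, seeded)."""
    X = np.asarray(embeddings, dtype=float)
    if X.shape[0] < K:
        raise ValueError(f"need at least K={K} embeddings, got {X.shape[0]}")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(X)
    return CentroidCodebook(centroids=km.cluster_centers_, seed=seed)


def fit_gmm_codebook(embeddings: np.ndarray, K: int, seed: int = 0) -> GaussianCodebook:
    """Fit a K-component diagonal GMM codebook.

    Initialized from a k-means fit with the same seed (one restart);
    covariances are floored at ``VARIANCE_FLOOR``.
    """
    X = np.asarray(embeddings, dtype=float)
    if X.shape[0] < K:
        raise ValueError(f"need at least K={K} embeddings, got {X.shape[0]}")
    km = fit_kmeans_codebook(X, K, seed=seed)
    gm = GaussianMixture(
        n_components=K,
        covariance_type="diag",
        reg_covar=VARIANCE_FLOOR,
        means_init=km.centroids,
        random_state=seed,
        n_init=1,
        max_iter=200,
    ).fit(X)
    return GaussianCodebook(
        weights=gm.weights_,
        means=gm.means_,
        covariances=np.maximum(gm.covariances_, VARIANCE_FLOOR),
        seed=seed,
    )


def log_posterior(codebook: GaussianCodebook, v: np.ndarray) -> np.ndarray:
    """Log component posteriors; ``v`` is (E,) or (n, E)."""
    V = np.atleast_2d(np.asarray(v, dtype=float))
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite embedding vector")
    mu = codebook.means
    var = codebook.covariances
    # (n, K) log N(v | mu_k, diag(var_k))
    log_det = np.sum(np.log(2.0 * np.pi * var), axis=1)
    sq = ((V[:, None, :] - mu[None, :, :]) ** 2 / var[None, :, :]).sum(axis=2)
    log_joint = np.log(codebook.weights)[None, :] - 0.5 * (log_det[None, :] + sq)
    out = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
    return out[0] if np.ndim(v) == 1 else out


def posterior(codebook: GaussianCodebook, v: np.ndarray) -> np.ndarray:
    """Component posterior probabilities (sum to 1 along the last axis)."""
    return np.exp(log_posterior(codebook, v))


def hard_assign(codebook: CentroidCodebook, v: np.ndarray):
    """Index of the nearest centroid (Euclidean); ties break to the lowest
    index. ``v`` is (E,) for one index or (n, E) for an index array."""
    V = np.atleast_2d(np.asarray(v, dtype=float))
    d2 = ((V[:, None, :] - codebook.centroids[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)  # argmin returns the first (lowest) minimizer
    return int(idx[0]) if np.ndim(v) == 1 else idx


def sweep_codebook_sizes(
    embeddings: np.ndarray,
    K_list,
    eval_fn,
    kind: str = "gmm",
    seed: int = 0,
) -> pd.DataFrame:
    """Fit a codebook per K and score it with a downstream evaluation.

    ``eval_fn(codebook) -> (weighted_auc, ci_low, ci_high)`` runs the
    caller's encoding + cross-validation.  A K larger than the sample is
    recorded as an error row rather than raising.  The default grid in the
    reference study was [3, 5, 10, 20, 50, 100, 150, 200, 300].
    """
    if len(K_list) == 0:
        raise ValueError("K_list must be nonempty")
    fit = {"gmm": fit_gmm_codebook, "kmeans": fit_kmeans_codebook}[kind]
    X = np.asarray(embeddings, dtype=float)
    rows = []
    for K in sorted(K_list):
        if K > X.shape[0]:
            rows.append(
                {"K": K, "weighted_auc": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "error": f"K={K} > n={X.shape[0]}"}
            )
            continue
        cb = fit(X, K, seed=seed)
        auc, lo, hi = eval_fn(cb)
        rows.append(
            {"K": K, "weighted_auc": auc, "ci_low": lo, "ci_high": hi, "error": ""}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# serialization: portable array container with a JSON header

def save_codebook(codebook, path) -> None:
    path = Path(path)
    if isinstance(codebook, GaussianCodebook):
        header = {"kind": "gaussian-codebook", "K": codebook.n_concepts,
                  "E": codebook.means.shape[1], "seed": codebook.seed}
        np.savez(path, header=json.dumps(header), weights=codebook.weights,
                 means=codebook.means, covariances=codebook.covariances)
    elif isinstance(codebook, CentroidCodebook):
        header = {"kind": "centroid-codebook", "K": codebook.n_concepts,
                  "E": codebook.centroids.shape[1], "seed": codebook.seed}
        np.savez(path, header=json.dumps(header), centroids=codebook.centroids)
    else:
        raise TypeError(f"not a codebook: {type(codebook)!r}")


def load_codebook(path):
    with np.load(Path(path), allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        if header["kind"] == "gaussian-codebook":
            return GaussianCodebook(
                weights=data["weights"], means=data["means"],
                covariances=data["covariances"], seed=header["seed"],
            )
        return CentroidCodebook(centroids=data["centroids"], seed=header["seed"])
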