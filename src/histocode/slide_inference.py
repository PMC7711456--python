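"""Decision-fusion slide classification and its evaluation harness.

Slide histograms are classified with an SVM (RBF) or a random forest;
evaluation is patient-grouped k-fold cross-validation with per-class
one-vs-rest metrics (accuracy, AUC, precision, recall, F1), their
support-weighted averages, plain multiclass accuracy ("overall"), and
t-distribution 95% confidence intervals over folds clipped to [0, 1].

``run_model_grid`` reproduces the 10-model comparison: tile features from
the fully supervised (FS), MIL, EM, k-means-codebook (KM) and
GMM-codebook routes, each fused with SVM and RF, all sharing one fold
assignment.  Tile-level models are trained on a patient-grouped held-out
fraction of the cohort; cross-validation runs on the remaining slides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from . import encoding
from .codebook import fit_gmm_codebook, fit_kmeans_codebook
from .concept_mappers import EMConfig, build_fs_tileset, build_mil_tileset, em_train
from .synthetic import SlideRecord
from .tile_models import TrainConfig, train_autoencoder, train_tile_classifier
from .tiling import TilingParams, extract_and_filter_tiles

MODEL_IDS = (
    "FS-RF", "FS-SVM", "MIL-RF", "MIL-SVM", "EM-RF",
    "EM-SVM", "KM-RF", "KM-SVM", "GMM-RF", "GMM-SVM",
)

METRICS = ("accuracy", "auc", "precision", "recall", "f1")


@dataclass
class FusionClassifier:
    """Slide-level classifier over concept histograms."""

    kind: str  # "svm" | "rf"
    estimator: object
    classes_: np.ndarray


@dataclass
class CVReport:
    """Cross-validation summary for one model.

    ``per_class``: tidy frame (class, metric, mean, ci_low, ci_high);
    ``weighted``: support-weighted averages plus an ``overall`` multiclass
    accuracy row; ``folds``: fold id per slide.
    """

    model_id: str
    per_class: pd.DataFrame
    weighted: pd.DataFrame
    folds: pd.Series

    def weighted_value(self, metric: str) -> float:
        row = self.weighted[self.weighted["metric"] == metric]
        return float(row["mean"].iloc[0])


def patient_grouped_folds(
    manifest: pd.DataFrame, k: int = 10, seed: int = 0
) -> pd.Series:
    """Assign every slide to the fold of its patient.

    Patients are shuffled with ``seed`` and dealt round-robin into k
    groups whose sizes differ by at most 1; all of a patient's slides land
    in the same fold.
    """
    patients = pd.unique(manifest["patient_id"])
    if len(patients) < k:
        raise ValueError(f"need >= {k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    shuffled = patients[rng.permutation(len(patients))]
    fold_of = {p: i % k for i, p in enumerate(shuffled)}
    return pd.Series(
        [fold_of[p] for p in manifest["patient_id"]],
        index=manifest["slide_id"].to_numpy(),
        name="fold",
    )


def train_fusion_classifier(
    histograms: np.ndarray, labels: Sequence, kind: str, seed: int = 0
) -> FusionClassifier:
    """Fit the decision-fusion classifier (``kind`` = "svm" or "rf")."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    H = np.asarray(histograms, dtype=float)
    if kind == "svm":
        est = SVC(kernel="rbf", decision_function_shape="ovr", random_state=seed)
    elif kind == "rf":
        est = RandomForestClassifier(n_estimators=500, random_state=seed)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    est.fit(H, y)
    return FusionClassifier(kind=kind, estimator=est, classes_=est.classes_)


def slide_scores(model: FusionClassifier, histograms: np.ndarray) -> np.ndarray:
    """(n, K) per-class scores usable for one-vs-rest ROC analysis."""
    H = np.atleast_2d(np.asarray(histograms, dtype=float))
    if H.shape[1] != model.estimator.n_features_in_:
        raise ValueError(
            f"histogram length {H.shape[1]} != trained length "
            f"{model.estimator.n_features_in_}"
        )
    if model.kind == "svm":
        s = model.estimator.decision_function(H)
        if s.ndim == 1:  # binary: decision value for classes_[1]
            s = np.column_stack([-s, s])
        return s
    return model.estimator.predict_proba(H)


def predict_slide(model: FusionClassifier, histogram: np.ndarray):
    """(label, per-class scores) for one histogram; label = argmax score."""
    s = slide_scores(model, histogram)[0]
    return model.classes_[int(s.argmax())], s


def _t_ci(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, lo, hi): t-interval over folds, clipped to [0, 1]."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan, np.nan, np.nan
    m = float(v.mean())
    if len(v) == 1:
        half = 0.0
    else:
        half = float(stats.t.ppf(0.975, len(v) - 1) * v.std(ddof=1) / np.sqrt(len(v)))
    return m, max(m - half, 0.0), min(m + half, 1.0)


def evaluate_cv(
    histograms: np.ndarray,
    labels: Sequence,
    patients: Sequence,
    kind: str,
    k: int = 10,
    seed: int = 0,
    model_id: str | None = None,
    folds: pd.Series | None = None,
) -> CVReport:
    """Patient-grouped k-fold cross-validation of a fusion classifier.

    Per-class metrics are one-vs-rest within each held-out fold; weighted
    averages use the true-class supports in the fold; fold means get 95%
    t-intervals clipped to [0, 1].  A fold in which a class's AUC is
    undefined (class absent, or alone) is excluded from that class's AUC
    mean with a warning.
    """
    H = np.asarray(histograms, dtype=float)
    y = np.asarray(labels)
    manifest = pd.DataFrame(
        {"slide_id": np.arange(len(y)).astype(str), "patient_id": np.asarray(patients)}
    )
    if folds is None:
        folds = patient_grouped_folds(manifest, k=k, seed=seed)
    fold_arr = folds.to_numpy()
    classes = np.unique(y)

    per_class_vals = {(c, m): [] for c in classes for m in METRICS}
    weighted_vals = {m: [] for m in METRICS}
    overall_vals = []

    for f in sorted(np.unique(fold_arr)):
        test = fold_arr == f
        model = train_fusion_classifier(H[~test], y[~test], kind, seed=seed)
        S = slide_scores(model, H[test])
        # align score columns to the global class order
        col = {c: i for i, c in enumerate(model.classes_)}
        y_test = y[test]
        pred = model.classes_[S.argmax(axis=1)]
        overall_vals.append(float(np.mean(pred == y_test)))

        supports, fold_metrics = [], {m: [] for m in METRICS}
        for c in classes:
            b_true = y_test == c
            b_pred = pred == c
            support = int(b_true.sum())
            tp = int(np.sum(b_true & b_pred))
            acc = float(np.mean(b_true == b_pred))
            prec = tp / b_pred.sum() if b_pred.sum() else 0.0
            rec = tp / support if support else 0.0
            f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
            if c in col and 0 < support < len(y_test):
                auc = float(roc_auc_score(b_true, S[:, col[c]]))
            else:
                auc = np.nan
                warnings.warn(
                    f"fold {f}: AUC undefined for class {c!r} "
                    f"(support {support}/{len(y_test)})"
                )
            vals = {"accuracy": acc, "auc": auc, "precision": prec,
                    "recall": rec, "f1": f1}
            for m in METRICS:
                per_class_vals[(c, m)].append(vals[m])
                fold_metrics[m].append(vals[m])
            supports.append(support)
        supports = np.asarray(supports, dtype=float)
        for m in METRICS:
            vals = np.asarray(fold_metrics[m], dtype=float)
            ok = np.isfinite(vals) & (supports > 0)
            weighted_vals[m].append(
                float(np.sum(vals[ok] * supports[ok]) / supports[ok].sum())
                if ok.any()
                else np.nan
            )

    pc_rows = []
    for c in classes:
        for m in METRICS:
            mean, lo, hi = _t_ci(per_class_vals[(c, m)])
            pc_rows.append(
                {"class": c, "metric": m, "mean": mean, "ci_low": lo, "ci_high": hi}
            )
    w_rows = []
    for m in METRICS:
        mean, lo, hi = _t_ci(weighted_vals[m])
        w_rows.append({"metric": m, "mean": mean, "ci_low": lo, "ci_high": hi})
    mean, lo, hi = _t_ci(overall_vals)
    w_rows.append({"metric": "overall_accuracy", "mean": mean, "ci_low": lo,
                   "ci_high": hi})
    return CVReport(
        model_id=model_id or kind,
        per_class=pd.DataFrame(pc_rows),
        weighted=pd.DataFrame(w_rows),
        folds=folds,
    )


def project_histograms_pca(histograms: np.ndarray) -> np.ndarray:
    """Mean-centered scores on the top-2 principal axes (separability
    plots)."""
    H = np.asarray(histograms, dtype=float)
    if H.shape[0] < 3:
        raise ValueError("need at least 3 slides for a PCA projection")
    return PCA(n_components=2).fit_transform(H)


# --------------------------------------------------------------------- #
# the 10-model comparison grid

@dataclass(frozen=True)
class GridConfig:
    """Configuration of a full comparison run."""

    tiling: TilingParams = TilingParams()
    train: TrainConfig = TrainConfig()
    cae_train: TrainConfig = TrainConfig(epochs=15, augment=False, dropout=0.0)
    em: EMConfig | None = None  # None -> EMConfig(train=..., tiling=...)
    embed_dim: int = 32
    codebook_sizes: dict = field(
        default_factory=lambda: {"KM-RF": 100, "KM-SVM": 200, "GMM-RF": 150,
                                 "GMM-SVM": 150}
    )
    n_folds: int = 10
    min_coverage: float = 0.5
    feature_split_fraction: float = 0.2


def _route_and_kind(model_id: str) -> tuple[str, str]:
    route, clf = model_id.rsplit("-", 1)
    return route, {"RF": "rf", "SVM": "svm"}[clf]


def run_model_grid(
    slides: Sequence[SlideRecord],
    model_ids: Sequence[str] = MODEL_IDS,
    config: GridConfig = GridConfig(),
    seed: int = 0,
) -> dict[str, CVReport]:
    """Evaluate a subset of the 10 models on one cohort.

    A patient-grouped ``feature_split_fraction`` of the cohort trains the
    tile-level models (FS/MIL/EM classifiers, autoencoder, codebooks); the
    remaining slides are encoded per route and cross-validated.  All
    models share a single fold assignment.
    """
    for mid in model_ids:
        if mid not in MODEL_IDS:
            raise ValueError(f"unknown model id {mid!r}")
    routes = {_route_and_kind(mid)[0] for mid in model_ids}
    tp = config.tiling
    stride = tp.stride or tp.tile_size
    train_cfg = TrainConfig(**{**config.train.__dict__, "seed": seed})
    cae_cfg = TrainConfig(**{**config.cae_train.__dict__, "seed": seed})

    # patient-grouped feature/evaluation split
    patients = pd.unique(pd.Series([s.patient_id for s in slides]))
    rng = np.random.default_rng(seed)
    shuffled = patients[rng.permutation(len(patients))]
    n_feat = max(1, int(round(config.feature_split_fraction * len(patients))))
    feat_patients = set(shuffled[:n_feat])
    feat_slides = [s for s in slides if s.patient_id in feat_patients]
    eval_slides = [s for s in slides if s.patient_id not in feat_patients]

    eval_tiles = {
        s.slide_id: extract_and_filter_tiles(
            s.image, tp.tile_size, stride, tp.min_tissue,
            tp.background_threshold, slide_id=s.slide_id,
        )
        for s in eval_slides
    }
    eval_slides = [s for s in eval_slides if eval_tiles[s.slide_id]]
    labels = [s.label for s in eval_slides]
    eval_patients = [s.patient_id for s in eval_slides]
    manifest = pd.DataFrame(
        {"slide_id": [s.slide_id for s in eval_slides], "patient_id": eval_patients}
    )
    folds = patient_grouped_folds(manifest, k=config.n_folds, seed=seed)

    def _soft_encode(mapper, vocabulary):
        return np.stack(
            [
                encoding.encode_soft(
                    eval_tiles[s.slide_id], mapper, s.slide_id, vocabulary
                ).values
                for s in eval_slides
            ]
        )

    encodings: dict[str, np.ndarray] = {}
    cae = None
    embeddings = None
    if routes & {"KM", "GMM"}:
        all_feat_tiles, _ = build_mil_tileset(feat_slides, tp)
        cae = train_autoencoder(all_feat_tiles, config.embed_dim, cae_cfg)
        embeddings = cae.embed_batch(all_feat_tiles)

    for route in sorted(routes):
        if route == "FS":
            tiles, tl = build_fs_tileset(feat_slides, tp, config.min_coverage)
            clf = train_tile_classifier(tiles, tl, train_cfg)
            encodings["FS"] = _soft_encode(encoding.classifier_mapper(clf), "fs")
        elif route == "MIL":
            tiles, tl = build_mil_tileset(feat_slides, tp)
            clf = train_tile_classifier(tiles, tl, train_cfg)
            encodings["MIL"] = _soft_encode(encoding.classifier_mapper(clf), "mil")
        elif route == "EM":
            em_cfg = config.em or EMConfig(train=train_cfg, tiling=tp)
            clf, _, _ = em_train(feat_slides, em_cfg)
            encodings["EM"] = _soft_encode(encoding.classifier_mapper(clf), "em")

    reports: dict[str, CVReport] = {}
    for mid in model_ids:
        route, kind = _route_and_kind(mid)
        if route in encodings:
            H = encodings[route]
        elif route == "KM":
            K = config.codebook_sizes[mid]
            cb = fit_kmeans_codebook(embeddings, K, seed=seed)
            assigner = encoding.codebook_assigner(cae, cb)
            H = np.stack(
                [
                    encoding.encode_hard(
                        eval_tiles[s.slide_id], assigner, K, s.slide_id, "km"
                    ).values
                    for s in eval_slides
                ]
            )
        elif route == "GMM":
            K = config.codebook_sizes[mid]
            cb = fit_gmm_codebook(embeddings, K, seed=seed)
            H = _soft_encode(encoding.codebook_mapper(cae, cb), "gmm")
        reports[mid] = evaluate_cv(
            H, labels, eval_patients, kind, k=config.n_folds, seed=seed,
            model_id=mid, folds=folds,
        )
    return reports
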