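"""Patient-grouped cross-validation, fusion classifiers, metrics/CI
reporting, the model grid, and PCA projection."""

import numpy as np
import pandas as pd
import pytest

from histocode.slide_inference import (
    MODEL_IDS,
    GridConfig,
    evaluate_cv,
    patient_grouped_folds,
    predict_slide,
    project_histograms_pca,
    run_model_grid,
    train_fusion_classifier,
)
from histocode.tile_models import TrainConfig
from histocode.concept_mappers import EMConfig


def _manifest(n_patients, slides_per_patient=2):
    rows = []
    for i in range(n_patients):
        for j in range(slides_per_patient):
            rows.append({"slide_id": f"S{i}_{j}", "patient_id": f"P{i}"})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# folds

def test_one_patient_per_fold():
    folds = patient_grouped_folds(_manifest(10), k=10)
    man = _manifest(10)
    by_patient = pd.Series(folds.to_numpy(), index=man.patient_id.to_numpy())
    assert by_patient.groupby(level=0).nunique().eq(1).all()
    assert sorted(by_patient.groupby(by_patient).size() // 2) == [1] * 10


def test_no_patient_straddles_folds():
    man = _manifest(23, slides_per_patient=3)
    folds = patient_grouped_folds(man, k=10, seed=3)
    per_patient = pd.DataFrame(
        {"patient": man.patient_id.to_numpy(), "fold": folds.to_numpy()}
    )
    assert per_patient.groupby("patient").fold.nunique().eq(1).all()


def test_fold_sizes_near_equal_23_patients():
    man = _manifest(23, slides_per_patient=1)
    folds = patient_grouped_folds(man, k=10, seed=0)
    sizes = sorted(folds.groupby(folds).size())
    assert sizes == [2] * 7 + [3] * 3


def test_too_few_patients_rejected():
    with pytest.raises(ValueError):
        patient_grouped_folds(_manifest(5), k=10)


def test_folds_deterministic():
    a = patient_grouped_folds(_manifest(12), k=4, seed=9)
    b = patient_grouped_folds(_manifest(12), k=4, seed=9)
    pd.testing.assert_series_equal(a, b)


# --------------------------------------------------------------------- #
# fusion classifiers

def _onehot_data(n_per_class=8, K=3, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    H, y, patients = [], [], []
    for c in range(K):
        for i in range(n_per_class):
            h = np.eye(K)[c] + jitter * rng.random(K)
            H.append(h / h.sum())
            y.append(f"class{c}")
            patients.append(f"P{c}_{i % (n_per_class // 2)}")
    return np.stack(H), np.array(y), patients


def test_separable_histograms_fit_perfectly():
    H, y, _ = _onehot_data()
    for kind in ("svm", "rf"):
        model = train_fusion_classifier(H, y, kind, seed=0)
        pred = [predict_slide(model, h)[0] for h in H]
        assert np.mean(np.array(pred) == y) == 1.0


def test_training_deterministic_given_seed():
    H, y, _ = _onehot_data(jitter=0.3)
    a = train_fusion_classifier(H[:-6], y[:-6], "rf", seed=1)
    b = train_fusion_classifier(H[:-6], y[:-6], "rf", seed=1)
    sa = np.stack([predict_slide(a, h)[1] for h in H[-6:]])
    sb = np.stack([predict_slide(b, h)[1] for h in H[-6:]])
    assert np.array_equal(sa, sb)


def test_unknown_kind_and_length_mismatch_rejected():
    H, y, _ = _onehot_data()
    with pytest.raises(ValueError):
        train_fusion_classifier(H, y, "mlp")
    model = train_fusion_classifier(H, y, "svm")
    with pytest.raises(ValueError):
        predict_slide(model, np.zeros(5))


def test_predict_slide_argmax_consistency():
    H, y, _ = _onehot_data(jitter=0.4, seed=3)
    model = train_fusion_classifier(H, y, "rf", seed=0)
    for h in H[:10]:
        label, scores = predict_slide(model, h)
        assert len(scores) == 3
        assert label == model.classes_[scores.argmax()]


# --------------------------------------------------------------------- #
# evaluate_cv

def test_perfect_predictor_metrics_one_with_degenerate_ci():
    H, y, patients = _onehot_data(n_per_class=10)
    report = evaluate_cv(H, y, patients, "rf", k=5, seed=0)
    for metric in ("accuracy", "auc", "precision", "recall", "f1"):
        row = report.weighted[report.weighted.metric == metric].iloc[0]
        assert row["mean"] == 1.0
        assert row.ci_low == 1.0 and row.ci_high == 1.0


def test_ci_bounds_clipped_to_unit_interval():
    H, y, patients = _onehot_data(n_per_class=10, jitter=0.8, seed=5)
    report = evaluate_cv(H, y, patients, "svm", k=5, seed=0)
    for frame in (report.per_class, report.weighted):
        assert (frame.ci_high <= 1.0).all()
        assert (frame.ci_low >= 0.0).all()
        ok = frame.dropna(subset=["mean"])
        assert (ok.ci_low <= ok["mean"] + 1e-12).all()
        assert (ok["mean"] <= ok.ci_high + 1e-12).all()


def test_constant_features_give_majority_class_recall():
    """With uninformative histograms the classifier collapses to the
    majority class: recall 1 for it, 0 elsewhere, weighted recall equal to
    its prevalence."""
    K = 3
    H = np.full((30, K), 1.0 / K)
    y = np.array(["maj"] * 18 + ["min1"] * 6 + ["min2"] * 6)
    patients = [f"P{i//2}" for i in range(30)]
    rng = np.random.default_rng(0)
    order = rng.permutation(30)
    report = evaluate_cv(H[order], y[order],
                         [patients[i] for i in order], "rf", k=5, seed=0)
    rec = report.per_class[report.per_class.metric == "recall"]
    assert rec[rec["class"] == "maj"]["mean"].iloc[0] == 1.0
    assert rec[rec["class"] != "maj"]["mean"].eq(0.0).all()
    w = report.weighted[report.weighted.metric == "recall"].iloc[0]["mean"]
    assert w == pytest.approx(0.6, abs=1e-9)


def test_cv_invariant_to_slide_order():
    H, y, patients = _onehot_data(n_per_class=10, jitter=0.5, seed=2)
    man = pd.DataFrame(
        {"slide_id": np.arange(len(y)).astype(str), "patient_id": patients}
    )
    folds = patient_grouped_folds(man, k=5, seed=0)
    rep1 = evaluate_cv(H, y, patients, "rf", k=5, folds=folds)
    perm = np.random.default_rng(1).permutation(len(y))
    folds_perm = pd.Series(folds.to_numpy()[perm],
                           index=np.asarray(folds.index)[perm])
    rep2 = evaluate_cv(H[perm], y[perm], [patients[i] for i in perm],
                       "rf", k=5, folds=folds_perm)
    pd.testing.assert_frame_equal(
        rep1.weighted.sort_values("metric").reset_index(drop=True),
        rep2.weighted.sort_values("metric").reset_index(drop=True),
    )


# --------------------------------------------------------------------- #
# model grid

def test_unknown_model_id_rejected(tiny_cohort):
    slides, _, _ = tiny_cohort
    with pytest.raises(ValueError):
        run_model_grid(slides, ["FS-XGB"])


def test_grid_runs_all_models_with_shared_folds(tiny_cohort, tiny_tiling):
    """All 10 models produce reports and share one fold assignment."""
    slides, _, _ = tiny_cohort
    cfg = GridConfig(
        tiling=tiny_tiling,
        train=TrainConfig(epochs=4),
        cae_train=TrainConfig(epochs=6, augment=False, dropout=0.0),
        em=EMConfig(max_iters=3, tiling=tiny_tiling,
                    train=TrainConfig(epochs=4)),
        embed_dim=16,
        codebook_sizes={"KM-RF": 8, "KM-SVM": 8, "GMM-RF": 8, "GMM-SVM": 8},
        n_folds=4,
        feature_split_fraction=0.34,
    )
    reports = run_model_grid(slides, MODEL_IDS, cfg, seed=0)
    assert set(reports) == set(MODEL_IDS)
    ref = reports["FS-RF"].folds
    for rep in reports.values():
        pd.testing.assert_series_equal(rep.folds, ref)
        assert np.isfinite(rep.weighted_value("accuracy"))


def test_singleton_grid(tiny_cohort, tiny_tiling):
    slides, _, _ = tiny_cohort
    cfg = GridConfig(
        tiling=tiny_tiling, train=TrainConfig(epochs=4), n_folds=4,
        feature_split_fraction=0.34,
    )
    reports = run_model_grid(slides, ["MIL-SVM"], cfg, seed=0)
    assert list(reports) == ["MIL-SVM"]


# --------------------------------------------------------------------- #
# PCA projection

def test_pca_projection_properties(rng):
    H = rng.dirichlet(np.ones(6), size=40)
    XY = project_histograms_pca(H)
    assert XY.shape == (40, 2)
    assert np.allclose(XY.mean(axis=0), 0.0, atol=1e-9)
    assert XY[:, 0].var() >= XY[:, 1].var()
    with pytest.raises(ValueError):
        project_histograms_pca(H[:2])
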