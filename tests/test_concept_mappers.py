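"""FS/MIL tile-set construction, lattice smoothing, discriminative
selection, and the EM loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histocode.concept_mappers import (
    EMConfig,
    build_fs_tileset,
    build_mil_tileset,
    em_train,
    masks_frame,
    select_discriminative,
    smooth_probability_map,
)
from histocode.synthetic import BACKGROUND, CohortParams, SlideRecord, generate_cohort
from histocode.tile_models import TrainConfig, train_tile_classifier
from histocode.tiling import TilingParams


# --------------------------------------------------------------------- #
# FS / MIL tile sets

def _slide_with_mask(label="ndbe", mask_value=1, size=64, tile=32):
    image = np.full((size, size), 0.4)
    mask = np.full((size, size), mask_value, dtype=np.uint8)
    return SlideRecord("S0", "P0", label, image, mask)


def test_fs_tile_fully_inside_region_labeled(tiny_tiling):
    rec = _slide_with_mask(mask_value=2)
    tiles, labels = build_fs_tileset([rec], TilingParams(tile_size=32))
    assert len(tiles) == 4
    assert labels == [2, 2, 2, 2]


def test_fs_low_coverage_tile_excluded():
    rec = _slide_with_mask(mask_value=1, size=32, tile=32)
    rec.mask[: int(32 * 0.7)] = BACKGROUND  # best class covers 30%
    tiles, labels = build_fs_tileset([rec], TilingParams(tile_size=32))
    assert tiles == []


def test_fs_empty_mask_contributes_nothing():
    rec = _slide_with_mask()
    rec.mask[:] = BACKGROUND
    tiles, _ = build_fs_tileset([rec], TilingParams(tile_size=32))
    assert tiles == []


def test_fs_missing_mask_rejected():
    rec = _slide_with_mask()
    rec.mask = None
    with pytest.raises(ValueError):
        build_fs_tileset([rec], TilingParams(tile_size=32))


def test_mil_tiles_inherit_bag_label(tiny_cohort, tiny_tiling):
    slides, _, _ = tiny_cohort
    tiles, labels = build_mil_tileset(slides[:4], tiny_tiling)
    offset = 0
    for rec in slides[:4]:
        n = sum(1 for t in tiles if t.slide_id == rec.slide_id)
        assert set(labels[offset : offset + n]) == {rec.label}
        offset += n
    assert offset == len(tiles)


def test_mil_unlabeled_slide_rejected():
    rec = _slide_with_mask()
    rec.label = None
    with pytest.raises(ValueError):
        build_mil_tileset([rec], TilingParams(tile_size=32))


def test_mil_empty_slide_contributes_nothing():
    rec = SlideRecord("S0", "P0", "ndbe", np.ones((64, 64)))
    tiles, labels = build_mil_tileset([rec], TilingParams(tile_size=32))
    assert tiles == [] and labels == []


# --------------------------------------------------------------------- #
# smoothing and selection

def test_smoothing_constant_map_unchanged():
    grid = np.full((5, 5), 0.4)
    assert np.allclose(smooth_probability_map(grid, sigma=1.0), grid)


def test_smoothing_sigma_zero_identity(rng):
    grid = rng.random((4, 6))
    assert np.array_equal(smooth_probability_map(grid, 0.0), grid)


def test_smoothing_peak_stays_but_shrinks():
    grid = np.zeros((5, 5))
    grid[2, 2] = 1.0
    out = smooth_probability_map(grid, sigma=1.0)
    assert np.unravel_index(np.argmax(out), out.shape) == (2, 2)
    assert 0 < out[2, 2] < 1.0


def test_smoothing_respects_missing_cells(rng):
    grid = np.full((4, 4), 0.7)
    grid[1, 2] = np.nan
    out = smooth_probability_map(grid, sigma=1.0)
    assert np.isnan(out[1, 2])
    # renormalized kernel over present cells keeps a constant map constant
    present = np.isfinite(grid)
    assert np.allclose(out[present], 0.7)


def test_negative_sigma_rejected():
    with pytest.raises(ValueError):
        smooth_probability_map(np.zeros((3, 3)), -1.0)


def test_selection_threshold_extremes():
    grid = np.array([[0.2, 0.8], [0.5, 0.1]])
    all_in = select_discriminative(grid, threshold=0.0)
    assert all_in.z.all()
    top1 = select_discriminative(grid, threshold=1.0)
    assert top1.z.sum() == 1
    assert top1.z[0, 1]  # the maximum cell


@settings(deadline=None, derandomize=True, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_selection_monotone_in_threshold(seed):
    rng = np.random.default_rng(seed)
    grid = rng.random((5, 5))
    grid[rng.random((5, 5)) < 0.2] = np.nan
    thresholds = sorted(rng.random(3))
    masks = [select_discriminative(grid, t).z for t in thresholds]
    for lo, hi in zip(masks, masks[1:]):
        extra = hi & ~lo
        # raising the threshold never adds tiles beyond the top-1 fallback
        assert extra.sum() == 0 or (hi.sum() == 1 and lo.sum() >= 1)


def test_selection_precision_after_one_mil_round(tiny_cohort, tiny_tiling):
    """One MIL training round plus smoothing/thresholding already
    concentrates selection on planted lesion tiles."""
    slides, truth, _ = tiny_cohort
    tiles, labels = build_mil_tileset(slides, tiny_tiling)
    clf = train_tile_classifier(tiles, labels, TrainConfig(seed=0))
    tru = truth.set_index(["slide_id", "row", "col"]).truth_class
    from histocode.tiling import extract_and_filter_tiles, lattice_shape

    hits, total = 0, 0
    for rec in slides:
        if rec.label == "squamous":
            continue
        tl = extract_and_filter_tiles(
            rec.image, tiny_tiling.tile_size, slide_id=rec.slide_id
        )
        probs = clf.predict_proba(tl)[:, clf.classes.index(rec.label)]
        grid = np.full(
            lattice_shape(rec.image.shape, tiny_tiling.tile_size), np.nan
        )
        for t, p in zip(tl, probs):
            grid[t.row, t.col] = p
        mask = select_discriminative(
            smooth_probability_map(grid, 0.5), 0.5, rec.slide_id
        )
        for r, c in zip(*np.where(mask.z)):
            total += 1
            hits += tru[(rec.slide_id, int(r), int(c))] == rec.label
    assert total > 0
    assert hits / total >= 0.7


# --------------------------------------------------------------------- #
# EM loop

def test_em_initial_mask_is_all_ones(tiny_cohort, tiny_tiling):
    """Iteration 0 treats every tissue tile as discriminative: a 1-round
    run trains on the full MIL tile set."""
    slides, _, _ = tiny_cohort
    cfg = EMConfig(
        threshold=0.0, max_iters=1, tiling=tiny_tiling,
        train=TrainConfig(epochs=2, seed=0),
    )
    _, masks, log = em_train(slides[:6], cfg)
    assert log.iloc[0].n_selected == sum(
        m.present.sum() for m in masks.values()
    )


def test_em_single_round_threshold_zero_equals_mil(tiny_cohort, tiny_tiling):
    """max_iters=1 with threshold 0 is bit-for-bit plain MIL training."""
    slides, _, _ = tiny_cohort
    train_cfg = TrainConfig(epochs=3, seed=0)
    clf_em, _, _ = em_train(
        slides[:6],
        EMConfig(threshold=0.0, max_iters=1, tiling=tiny_tiling, train=train_cfg),
    )
    tiles, labels = build_mil_tileset(slides[:6], tiny_tiling)
    clf_mil = train_tile_classifier(tiles, labels, train_cfg)
    assert all(
        np.array_equal(a, b)
        for a, b in zip(clf_em.net.W, clf_mil.net.W)
    )
    assert np.array_equal(
        clf_em.predict_proba(tiles[:20]), clf_mil.predict_proba(tiles[:20])
    )


def test_em_converges_and_recovers_lesions(tiny_cohort, tiny_tiling):
    # a small tile set needs proportionally more epochs per M-step
    slides, truth, _ = tiny_cohort
    clf, masks, log = em_train(
        slides, EMConfig(tiling=tiny_tiling, train=TrainConfig(epochs=30, seed=0))
    )
    assert len(log) <= 10
    assert log.iloc[-1].changed_fraction < 0.01
    tru = truth.set_index(["slide_id", "row", "col"]).truth_class
    inter = union = 0
    for rec in slides:
        if rec.label == "squamous":
            continue
        m = masks[rec.slide_id]
        for r, c in zip(*np.where(m.present)):
            lesion = tru[(rec.slide_id, int(r), int(c))] == rec.label
            z = bool(m.z[r, c])
            inter += z and lesion
            union += z or lesion
    assert inter / union >= 0.5


def test_em_rejects_degenerate_configs(tiny_cohort, tiny_tiling):
    slides, _, _ = tiny_cohort
    with pytest.raises(ValueError):
        em_train(slides[:4], EMConfig(max_iters=0, tiling=tiny_tiling))
    one_class = [s for s in slides if s.label == "ndbe"]
    with pytest.raises(ValueError):
        em_train(one_class, EMConfig(tiling=tiny_tiling))


def test_masks_frame_schema(tiny_cohort, tiny_tiling):
    slides, _, _ = tiny_cohort
    _, masks, _ = em_train(
        slides[:6],
        EMConfig(max_iters=1, threshold=0.0, tiling=tiny_tiling,
                 train=TrainConfig(epochs=2)),
    )
    frame = masks_frame(masks, iteration=1)
    assert set(frame.columns) == {
        "slide_id", "row", "col", "z", "smoothed_value", "iteration"
    }
    assert len(frame) == sum(m.present.sum() for m in masks.values())
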