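"""Losses, overlap metrics, boundary F1 against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import frozenseg as fs
from frozenseg.metrics import default_bf_tolerance, _boundary


# ---------------------------------------------------------------------------
# confusion counts and overlap metrics
# ---------------------------------------------------------------------------


def test_identical_masks_have_no_errors(rng):
    m = rng.integers(0, 3, (16, 16))
    c = fs.confusion_counts(m, m, 3)
    assert np.all(c.fp == 0) and np.all(c.fn == 0)
    assert np.all(c.tp + c.tn == m.size)


def test_toy_counts_by_construction():
    gt = np.zeros((4, 4), int)
    pred = np.zeros((4, 4), int)
    gt.flat[:10] = 1  # 8 shared + 2 gt-only
    pred.flat[:8] = 1
    pred.flat[10:12] = 1  # 2 pred-only
    c = fs.confusion_counts(pred, gt, 2)
    assert (c.tp[1], c.fp[1], c.fn[1]) == (8, 2, 2)
    m = fs.segmentation_metrics(c)
    assert m.iou[1] == pytest.approx(8 / 12)
    assert m.dice[1] == pytest.approx(0.8)


def test_disjoint_masks_give_zero_overlap():
    gt = np.ones((4, 4), int)
    pred = np.zeros((4, 4), int)
    c = fs.confusion_counts(pred, gt, 2)
    assert (c.tp[1], c.fn[1], c.fp[1]) == (0, 16, 0)
    m = fs.segmentation_metrics(c)
    assert m.dice[1] == 0 and m.iou[1] == 0


def test_counts_validate_inputs():
    with pytest.raises(ValueError):
        fs.confusion_counts(np.zeros((2, 2), int), np.zeros((3, 3), int), 2)
    with pytest.raises(ValueError):
        fs.confusion_counts(np.full((2, 2), 5), np.zeros((2, 2), int), 2)


@given(
    tp=st.integers(0, 1000), fp=st.integers(0, 1000), fn=st.integers(0, 1000)
)
@settings(deadline=None, max_examples=50)
def test_dice_iou_identity_from_shared_counts(tp, fp, fn):
    """D = 2I/(1+I) must hold exactly when both come from one count set."""
    c = fs.ConfusionCounts(*(np.array([v]) for v in (tp, fp, fn, 0)))
    m = fs.segmentation_metrics(c)
    assert m.dice[0] == pytest.approx(2 * m.iou[0] / (1 + m.iou[0]))
    assert 0 <= m.dice[0] <= 1 and 0 <= m.iou[0] <= 1


def test_absent_class_convention():
    pred = np.zeros((4, 4), int)
    gt = np.zeros((4, 4), int)
    m = fs.segmentation_metrics(fs.confusion_counts(pred, gt, 3))
    assert m.dice[1] == 1.0 and m.dice[2] == 1.0
    assert not m.valid[1] and not m.valid[2]
    assert m.mean("dice") == 1.0  # only the background class counts


# ---------------------------------------------------------------------------
# boundary F1
# ---------------------------------------------------------------------------


def brute_force_bf(pred, gt, tol):
    """All-pairs boundary-distance oracle."""

    def boundary(m):
        pts = []
        h, w = m.shape
        for y in range(h):
            for x in range(w):
                if not m[y, x]:
                    continue
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < h and 0 <= xx < w) or not m[yy, xx]:
                        pts.append((y, x))
                        break
        return pts

    bp, bg = boundary(pred), boundary(gt)
    if not bp and not bg:
        return 1.0
    if not bp or not bg:
        return 0.0

    def frac_matched(a, b):
        hits = 0
        for p in a:
            if min((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 for q in b) <= tol**2:
                hits += 1
        return hits / len(a)

    prec, rec = frac_matched(bp, bg), frac_matched(bg, bp)
    return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)


def test_bf_score_identical_masks_is_one(rng):
    m = rng.uniform(size=(12, 12)) > 0.6
    assert fs.bf_score(m, m, tolerance=1) == 1.0


def test_bf_score_shifted_square_within_tolerance():
    a = np.zeros((8, 8), bool)
    a[2:6, 2:6] = True
    b = np.zeros((8, 8), bool)
    b[2:6, 3:7] = True
    assert fs.bf_score(b, a, tolerance=2) == 1.0


def test_bf_score_empty_conventions():
    e = np.zeros((8, 8), bool)
    f = np.zeros((8, 8), bool)
    f[2:4, 2:4] = True
    assert fs.bf_score(e, e) == 1.0
    assert fs.bf_score(e, f) == 0.0
    assert fs.bf_score(f, e) == 0.0


def test_bf_score_matches_brute_force_on_random_masks(rng):
    for _ in range(20):
        pred = rng.uniform(size=(16, 16)) > 0.7
        gt = rng.uniform(size=(16, 16)) > 0.7
        tol = int(rng.integers(1, 4))
        assert fs.bf_score(pred, gt, tol) == pytest.approx(
            brute_force_bf(pred, gt, tol)
        )


def test_default_tolerance_scales_with_diagonal():
    assert default_bf_tolerance((256, 256)) == int(np.ceil(0.0075 * np.hypot(256, 256)))


def test_boundary_includes_frame_edges():
    m = np.ones((4, 4), bool)
    # every frame pixel is a boundary pixel; the 2x2 interior is not
    b = _boundary(m)
    assert len(b) == 12


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _one_hot_probs(gt, k):
    return np.eye(k)[gt]


def test_losses_vanish_at_exact_agreement(rng):
    gt = rng.integers(0, 2, (2, 8, 8))
    probs = _one_hot_probs(gt, 2)
    assert fs.weighted_cross_entropy(probs, gt) <= 1e-6
    assert fs.weighted_dice_loss(probs, gt) <= 1e-4


def test_cross_entropy_uniform_binary_is_ln2():
    gt = np.zeros((1, 4, 4), int)
    probs = np.full((1, 4, 4, 2), 0.5)
    assert fs.weighted_cross_entropy(probs, gt) == pytest.approx(np.log(2), rel=1e-6)


def test_cross_entropy_is_linear_in_weights(rng):
    gt = rng.integers(0, 2, (1, 8, 8))
    z = rng.standard_normal((1, 8, 8, 2))
    probs = np.exp(z) / np.exp(z).sum(-1, keepdims=True)
    base = fs.weighted_cross_entropy(probs, gt, np.array([1.0, 1.0]))
    doubled = fs.weighted_cross_entropy(probs, gt, np.array([1.0, 2.0]))
    # class-1 pixel contributions double, class-0 unchanged
    only1 = fs.weighted_cross_entropy(probs, gt, np.array([1e-12, 1.0]))
    assert doubled == pytest.approx(base + only1, rel=1e-5)


def test_unit_weights_equal_unweighted_cross_entropy(rng):
    gt = rng.integers(0, 3, (1, 6, 6))
    z = rng.standard_normal((1, 6, 6, 3))
    probs = np.exp(z) / np.exp(z).sum(-1, keepdims=True)
    ptrue = np.take_along_axis(probs, gt[..., None], -1)[..., 0]
    assert fs.weighted_cross_entropy(probs, gt) == pytest.approx(
        float(np.mean(-np.log(ptrue))), rel=1e-9
    )


def test_dice_loss_disjoint_is_near_one():
    gt = np.zeros((1, 4, 4), int)
    pred_labels = np.ones((1, 4, 4), int)
    probs = _one_hot_probs(pred_labels, 2)
    assert fs.weighted_dice_loss(probs, gt) == pytest.approx(1.0, abs=1e-3)


def test_dice_loss_matches_direct_summation_toy():
    # 2x2, two classes, probs 0.5 everywhere, gt = class 1 on 2 pixels
    gt = np.array([[[1, 1], [0, 0]]])
    probs = np.full((1, 2, 2, 2), 0.5)
    eps = 1e-5
    soft = []
    onehot = np.eye(2)[gt]
    for k in range(2):
        inter = (probs[..., k] * onehot[..., k]).sum()
        denom = probs[..., k].sum() + onehot[..., k].sum()
        soft.append((2 * inter + eps) / (denom + eps))
    expected = 1 - np.mean(soft)
    assert fs.weighted_dice_loss(probs, gt) == pytest.approx(expected, rel=1e-9)


def test_losses_bounded_on_random_probabilities(rng):
    for _ in range(100):
        gt = rng.integers(0, 2, (1, 6, 6))
        z = rng.standard_normal((1, 6, 6, 2))
        probs = np.exp(z) / np.exp(z).sum(-1, keepdims=True)
        d = fs.weighted_dice_loss(probs, gt)
        c = fs.weighted_cross_entropy(probs, gt)
        assert 0 <= d <= 1
        assert c >= 0


# ---------------------------------------------------------------------------
# class weights
# ---------------------------------------------------------------------------


def test_balanced_counts_give_unit_weights():
    assert np.allclose(fs.compute_class_weights([50, 50]), [1, 1])


def test_inverse_frequency_ratio():
    w = fs.compute_class_weights([90, 10])
    assert w[0] == pytest.approx(100 / 180)
    assert w[1] == pytest.approx(5.0)
    assert w[1] / w[0] == pytest.approx(9.0)


def test_absent_class_floored_to_one_pixel():
    w = fs.compute_class_weights([100, 0])
    assert np.all(np.isfinite(w)) and w[1] > 0


def test_all_zero_counts_rejected():
    with pytest.raises(ValueError):
        fs.compute_class_weights([0, 0])


# ---------------------------------------------------------------------------
# error overlay
# ---------------------------------------------------------------------------


def test_overlay_colors(rng):
    img = rng.uniform(size=(8, 8, 3))
    gt = np.zeros((8, 8), bool)
    gt[2:5, 2:5] = True
    # identical: only blue on foreground
    out = fs.error_overlay(gt, gt, img)
    assert np.all(out[gt] == [0, 0, 1])
    # pred all fg, gt empty: all green
    out = fs.error_overlay(np.ones_like(gt), np.zeros_like(gt), img)
    assert np.all(out.reshape(-1, 3) == [0, 1, 0])
    # disjoint: green + red only
    pred = np.zeros_like(gt)
    pred[6:8, 6:8] = True
    out = fs.error_overlay(pred, gt, img)
    assert np.all(out[pred] == [0, 1, 0])
    assert np.all(out[gt] == [1, 0, 0])
    assert not np.any(np.all(out == [0, 0, 1], axis=-1))


def test_overlay_shape_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        fs.error_overlay(np.zeros((4, 4), bool), np.zeros((5, 5), bool), rng.uniform(size=(4, 4, 3)))
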