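"""Segmentation losses, overlap metrics, boundary F1, and error overlays.

Overlap metrics follow the usual pixel-count definitions
I = tp / (tp + fp + fn) and D = 2 tp / (2 tp + fp + fn); precision and recall
are tp/(tp+fp) and tp/(tp+fn). Boundary F1 scores boundary alignment within a
Euclidean distance tolerance. The two training losses are a class-weighted
cross-entropy and a class-weighted soft Dice, both taking normalized
per-pixel probabilities (N x H x W x K) and integer label masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .autodiff import Tensor

CE_CLIP = 1e-7
DICE_EPS = 1e-5


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest pixel counts; arrays of length num_classes."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    def __add__(self, other):
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @property
    def num_classes(self):
        return len(self.tp)


@dataclass
class SegMetrics:
    """Per-class metrics in [0,1]; multiply by 100 for the reported scale."""

    dice: np.ndarray
    iou: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    bf1: np.ndarray | None = None
    # classes absent from both masks are excluded from mean reporting
    valid: np.ndarray | None = None

    def mean(self, name):
        v = getattr(self, name)
        mask = self.valid if self.valid is not None else np.ones(len(v), bool)
        return float(v[mask].mean()) if mask.any() else float("nan")


def confusion_counts(pred, gt, num_classes):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt shapes differ")
    if pred.min() < 0 or gt.min() < 0 or pred.max() >= num_classes or gt.max() >= num_classes:
        raise ValueError("labels out of range")
    total = pred.size
    k = num_classes
    joint = np.bincount((gt.ravel() * k + pred.ravel()).astype(np.int64), minlength=k * k)
    joint = joint.reshape(k, k)  # rows gt, cols pred
    tp = np.diag(joint).astype(np.int64)
    fn = joint.sum(axis=1) - tp
    fp = joint.sum(axis=0) - tp
    tn = total - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_div(num, den, fill):
    out = np.full(len(np.atleast_1d(num)), fill, dtype=float)
    den = np.atleast_1d(den).astype(float)
    num = np.atleast_1d(num).astype(float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def segmentation_metrics(counts: ConfusionCounts) -> SegMetrics:
    """Dice/IoU/precision/recall from counts.

    Convention for a class absent from both prediction and ground truth
    (tp = fp = fn = 0): its D and I are 1 but the class is flagged invalid and
    excluded from mean reporting.
    """
    tp, fp, fn = counts.tp.astype(float), counts.fp.astype(float), counts.fn.astype(float)
    iou = _safe_div(tp, tp + fp + fn, fill=1.0)
    dice = _safe_div(2 * tp, 2 * tp + fp + fn, fill=1.0)
    precision = _safe_div(tp, tp + fp, fill=1.0)
    recall = _safe_div(tp, tp + fn, fill=1.0)
    valid = (tp + fp + fn) > 0
    return SegMetrics(dice, iou, precision, recall, valid=valid)


def default_bf_tolerance(shape):
    """0.75% of the image diagonal, rounded up."""
    h, w = shape[:2]
    return math.ceil(0.0075 * math.hypot(h, w))


def _boundary(mask):
    """Foreground pixels 4-adjacent to a non-foreground pixel (or the frame edge)."""
    m = np.asarray(mask, bool)
    if not m.any():
        return np.zeros((0, 2), dtype=np.int64)
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return np.argwhere(m & ~interior)


def bf_score(pred, gt, tolerance=None):
    """Boundary F1 between two binary masks.

    A boundary pixel counts as matched if any boundary pixel of the other
    mask lies within Euclidean distance <= tolerance. Both masks empty -> 1;
    exactly one empty -> 0.
    """
    pred = np.asarray(pred, bool)
    gt = np.asarray(gt, bool)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt shapes differ")
    if tolerance is None:
        tolerance = default_bf_tolerance(pred.shape)
    if not pred.any() and not gt.any():
        return 1.0
    if not pred.any() or not gt.any():
        return 0.0
    bp, bg = _boundary(pred), _boundary(gt)
    dist_p = cKDTree(bg).query(bp, k=1)[0]
    dist_g = cKDTree(bp).query(bg, k=1)[0]
    prec = float(np.mean(dist_p <= tolerance))
    rec = float(np.mean(dist_g <= tolerance))
    if prec + rec == 0:
        return 0.0
    return 2 * prec * rec / (prec + rec)


# ---------------------------------------------------------------------------
# class weights and losses
# ---------------------------------------------------------------------------


def compute_class_weights(label_frequency):
    """Inverse-frequency weights w_k = T / (K * c_k) with counts floored at 1.

    Balanced classes get unit weights; rarer classes get proportionally larger
    ones. Raises on all-zero counts.
    """
    c = np.asarray(label_frequency, dtype=float)
    if c.sum() <= 0:
        raise ValueError("all class counts are zero")
    c = np.maximum(c, 1.0)
    return c.sum() / (len(c) * c)


def _as_probs_array(probs):
    if isinstance(probs, Tensor):
        return probs.data, probs
    return np.asarray(probs, dtype=np.float64), None


def _check_loss_inputs(p, gt, k):
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite probabilities")
    gt = np.asarray(gt)
    if gt.shape != p.shape[:-1]:
        raise ValueError("ground-truth shape does not match probabilities")
    if gt.min() < 0 or gt.max() >= k:
        raise ValueError("labels out of range")
    return gt


def weighted_cross_entropy(probs, gt, weights=None):
    """Mean over pixels of -w[gt(p)] * log(probs[p, gt(p)]), probabilities
    clipped to [1e-7, 1]. Accepts either an ndarray or an autodiff Tensor
    (N x H x W x K for arrays; the Tensor path is N x K x H x W)."""
    p, tensor = _as_probs_array(probs)
    if tensor is not None:
        # NCHW tensor path used during training
        gt = np.asarray(gt)
        k = p.shape[1]
        n = p.shape[0]
        w = np.ones(k, dtype=p.dtype) if weights is None else np.asarray(weights, dtype=p.dtype)
        onehot = np.eye(k, dtype=p.dtype)[gt].transpose(0, 3, 1, 2)
        pc = np.clip(p, CE_CLIP, 1.0)
        wpix = w[gt][:, None]  # N,1,H,W
        npix = gt.size
        value = float((-(onehot * np.log(pc)) * wpix[:, :, :, :]).sum() / npix)

        def backward(g):
            grad = -(onehot * wpix) / pc / np.asarray(npix, dtype=p.dtype)
            grad[p < CE_CLIP] = 0.0
            tensor._accumulate(g * grad)

        return Tensor(np.asarray(value, dtype=p.dtype), parents=(tensor,), backward=backward)

    k = p.shape[-1]
    gt = _check_loss_inputs(p, gt, k)
    w = np.ones(k) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("class weights must be positive and finite")
    ptrue = np.take_along_axis(p, gt[..., None], axis=-1)[..., 0]
    ptrue = np.clip(ptrue, CE_CLIP, 1.0)
    return float(np.mean(-w[gt] * np.log(ptrue)))


def weighted_dice_loss(probs, gt, weights=None):
    """1 - weighted mean over classes of the soft Dice overlap.

    Soft Dice per class: (2 * sum(p*g) + eps) / (sum(p) + sum(g) + eps) with
    one-hot ground truth g and eps = 1e-5; weights averaged to the mean-1
    scale. Value lies in [0, 1]."""
    p, tensor = _as_probs_array(probs)
    channel_first = tensor is not None
    if channel_first:
        k = p.shape[1]
        axis = (0, 2, 3)
        gt = np.asarray(gt)
        onehot = np.eye(k, dtype=p.dtype)[gt].transpose(0, 3, 1, 2)
    else:
        k = p.shape[-1]
        gt = _check_loss_inputs(p, gt, k)
        axis = tuple(range(p.ndim - 1))
        onehot = np.eye(k, dtype=p.dtype)[gt]
    w = np.ones(k, dtype=p.dtype) if weights is None else np.asarray(weights, dtype=p.dtype)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("class weights must be positive and finite")
    inter = (p * onehot).sum(axis=axis)
    denom = p.sum(axis=axis) + onehot.sum(axis=axis)
    soft = (2 * inter + DICE_EPS) / (denom + DICE_EPS)
    value = float(1.0 - (w * soft).sum() / w.sum())
    if tensor is None:
        return value

    def backward(g):
        # dS_k/dp = (2*g_onehot*(denom+eps) - (2*inter+eps)) / (denom+eps)^2
        de = denom + DICE_EPS
        shape = (1, k, 1, 1)
        dsoft = (2 * onehot * de.reshape(shape) - (2 * inter + DICE_EPS).reshape(shape)) / (
            de.reshape(shape) ** 2
        )
        tensor._accumulate((g * (-(w.reshape(shape) * dsoft) / w.sum())).astype(p.dtype))

    return Tensor(np.asarray(value, dtype=p.dtype), parents=(tensor,), backward=backward)


# ---------------------------------------------------------------------------
# visual error overlay
# ---------------------------------------------------------------------------

OVERLAY_TP = np.array([0.0, 0.0, 1.0])  # blue
OVERLAY_FP = np.array([0.0, 1.0, 0.0])  # green
OVERLAY_FN = np.array([1.0, 0.0, 0.0])  # red


def error_overlay(pred, gt, image):
    """Paint tp pixels blue, fp green, fn red over the grayscale-dimmed image."""
    pred = np.asarray(pred, bool)
    gt = np.asarray(gt, bool)
    image = np.asarray(image, dtype=np.float64)
    if pred.shape != gt.shape or image.shape[:2] != pred.shape:
        raise ValueError("shape mismatch between masks and image")
    luma = image @ np.array([0.299, 0.587, 0.114]) if image.ndim == 3 else image
    out = np.repeat((0.5 * luma)[:, :, None], 3, axis=2)
    out[pred & gt] = OVERLAY_TP
    out[pred & ~gt] = OVERLAY_FP
    out[~pred & gt] = OVERLAY_FN
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def metrics_from_masks(pred, gt, num_classes, tolerance=None, with_bf1=True):
    """Full per-class metric set from a pair (or batch) of label masks."""
    counts = confusion_counts(pred, gt, num_classes)
    m = segmentation_metrics(counts)
    if with_bf1:
        pred = np.asarray(pred)
        gt = np.asarray(gt)
        if pred.ndim == 2:
            pred, gt = pred[None], gt[None]
        bf1 = np.zeros(num_classes)
        for k in range(num_classes):
            scores = [bf_score(p == k, g == k, tolerance) for p, g in zip(pred, gt)]
            bf1[k] = float(np.mean(scores))
        m.bf1 = bf1
    return m


def metrics_table(metrics_list, row_names, scale=100.0):
    """Tabulate mean metrics (rows = folds/classes, columns x100) as a DataFrame."""
    import pandas as pd

    rows = []
    for m in metrics_list:
        row = {
            "D": m.mean("dice") * scale,
            "I": m.mean("iou") * scale,
            "PRE": m.mean("precision") * scale,
            "REC": m.mean("recall") * scale,
        }
        if m.bf1 is not None:
            mask = m.valid if m.valid is not None else np.ones(len(m.bf1), bool)
            row["BF1"] = float(np.mean(m.bf1[mask])) * scale
        rows.append(row)
    return pd.DataFrame(rows, index=row_names)
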