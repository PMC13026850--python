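"""Optimization protocol: Adam with step-decayed learning rate, L2 weight
decay on convolution weights, per-epoch shuffling, and k-fold cross-validation.

Defaults: initial learning rate 5e-4 decayed by a factor 0.1 every 10
epochs, L2 coefficient 5e-4, Adam moments (0.9, 0.999).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .metrics import (
    compute_class_weights,
    confusion_counts,
    metrics_table,
    segmentation_metrics,
    weighted_cross_entropy,
    weighted_dice_loss,
)
from .network import NetworkConfig, SegModel, build_network, predict_mask


@dataclass
class TrainConfig:
    initial_lr: float = 5e-4
    lr_drop_period: int = 10
    lr_drop_factor: float = 0.1
    l2: float = 5e-4
    batch_size: int = 8
    epochs: int = 30
    loss_kind: str = "weighted_ce"  # or "weighted_dice"
    shuffle_each_epoch: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0 < self.lr_drop_factor <= 1:
            raise ValueError("lr_drop_factor must lie in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss_kind not in ("weighted_ce", "weighted_dice"):
            raise ValueError(f"unknown loss_kind {self.loss_kind!r}")


@dataclass
class FoldSplit:
    k: int
    assignment: np.ndarray  # per-sample fold index

    def train_indices(self, fold):
        return np.where(self.assignment != fold)[0]

    def test_indices(self, fold):
        return np.where(self.assignment == fold)[0]


@dataclass
class TrainHistory:
    loss: list = field(default_factory=list)  # per iteration
    lr: list = field(default_factory=list)  # per epoch
    val_dice: list = field(default_factory=list)  # per epoch (mean over classes)
    pixel_accuracy: list = field(default_factory=list)  # per epoch


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step decay: initial_lr * factor^floor((epoch-1)/period), epoch 1-based."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return cfg.initial_lr * cfg.lr_drop_factor ** ((epoch - 1) // cfg.lr_drop_period)


def make_folds(n: int, k: int = 5, seed: int = 0) -> FoldSplit:
    """Seeded random permutation with round-robin fold assignment."""
    if k < 2 or n < k:
        raise ValueError("need n >= k >= 2")
    perm = np.random.default_rng(seed).permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    assignment[perm] = np.arange(n) % k
    return FoldSplit(k=k, assignment=assignment)


class Adam:
    """Adam with additive L2 decay applied to convolution weights only."""

    def __init__(self, params, l2=0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = [p for _, p in params]
        self.l2 = l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.l2 and getattr(p, "is_conv_weight", False):
                g = g + self.l2 * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _stack_pairs(pairs):
    images = np.stack([np.asarray(p[0] if isinstance(p, tuple) else p.image) for p in pairs])
    masks = np.stack([np.asarray(p[1] if isinstance(p, tuple) else p.mask) for p in pairs])
    return images, masks


def _loss_fn(kind):
    return weighted_cross_entropy if kind == "weighted_ce" else weighted_dice_loss


def evaluate_model(model: SegModel, pairs, batch_size=8):
    """Micro-averaged metrics plus pixel accuracy over a list of pairs."""
    images, masks = _stack_pairs(pairs)
    k = model.cfg.num_classes
    counts = None
    correct = 0
    for i in range(0, len(images), batch_size):
        probs = model.forward(images[i : i + batch_size])
        pred = predict_mask(probs)
        c = confusion_counts(pred, masks[i : i + batch_size], k)
        counts = c if counts is None else counts + c
        correct += int((pred == masks[i : i + batch_size]).sum())
    metrics = segmentation_metrics(counts)
    return metrics, correct / masks.size


def train_model(model: SegModel, train_pairs, val_pairs=None, cfg: TrainConfig | None = None,
                class_weights=None, max_iterations=None):
    """Train in place; returns (model, TrainHistory).

    Only trainable parameters are updated; frozen filter kernels are buffers
    and untouched by construction. Class weights default to inverse-frequency
    weights computed from the training masks.
    """
    cfg = cfg or TrainConfig()
    if len(train_pairs) == 0:
        raise ValueError("empty training set")
    images, masks = _stack_pairs(train_pairs)
    k = model.cfg.num_classes
    if class_weights is None:
        freq = np.bincount(masks.ravel(), minlength=k)
        class_weights = compute_class_weights(freq)
    loss_fn = _loss_fn(cfg.loss_kind)
    opt = Adam(model.trainable_parameters(), l2=cfg.l2)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    model.set_training(True)
    n = len(images)
    iters = 0
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_at_epoch(cfg, epoch)
        history.lr.append(lr)
        order = rng.permutation(n) if cfg.shuffle_each_epoch else np.arange(n)
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            x = Tensor(np.ascontiguousarray(images[idx].transpose(0, 3, 1, 2), dtype=np.float32))
            probs = model.forward_tensor(x)
            loss = loss_fn(probs, masks[idx], class_weights)
            val = float(loss.data)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, iteration {iters}: {val}"
                )
            history.loss.append(val)
            loss.backward()
            opt.step(lr)
            iters += 1
            if max_iterations is not None and iters >= max_iterations:
                break
        if val_pairs:
            metrics, acc = evaluate_model(model, val_pairs, cfg.batch_size)
            history.val_dice.append(metrics.mean("dice"))
            history.pixel_accuracy.append(acc)
        if max_iterations is not None and iters >= max_iterations:
            break
    model.set_training(False)
    return model, history


def cross_validate(dataset, k, cfg: TrainConfig, network_cfg: NetworkConfig, seed=0,
                   tolerance=None):
    """k-fold cross-validation; returns a DataFrame of per-fold rows plus an
    arithmetic-mean 'average' row (metrics x100, matching reported tables)."""
    split = make_folds(len(dataset), k, seed=seed)
    fold_metrics, names = [], []
    for fold in range(k):
        train_pairs = [dataset[i] for i in split.train_indices(fold)]
        test_pairs = [dataset[i] for i in split.test_indices(fold)]
        model = build_network(network_cfg, seed=seed * 1000 + fold)
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": seed * 1000 + fold})
        train_model(model, train_pairs, cfg=fold_cfg)
        metrics, _ = evaluate_model(model, test_pairs, cfg.batch_size)
        fold_metrics.append(metrics)
        names.append(f"fold_{fold + 1}")
    table = metrics_table(fold_metrics, names)
    table.loc["average"] = table.mean(axis=0)
    return table
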