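"""Optimization protocol: lr schedule, folds, frozen kernels stay frozen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import frozenseg as fs
from frozenseg.training import Adam, lr_at_epoch, make_folds


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------


def test_step_decay_values():
    cfg = fs.TrainConfig()  # 5e-4, period 10, factor 0.1
    assert lr_at_epoch(cfg, 1) == pytest.approx(5e-4)
    assert lr_at_epoch(cfg, 10) == pytest.approx(5e-4)
    assert lr_at_epoch(cfg, 11) == pytest.approx(5e-5)
    assert lr_at_epoch(cfg, 20) == pytest.approx(5e-5)
    assert lr_at_epoch(cfg, 21) == pytest.approx(5e-6)


def test_lr_is_nonincreasing():
    cfg = fs.TrainConfig()
    lrs = [lr_at_epoch(cfg, e) for e in range(1, 40)]
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))


def test_epochs_are_one_based():
    with pytest.raises(ValueError):
        lr_at_epoch(fs.TrainConfig(), 0)


def test_train_config_validation():
    with pytest.raises(ValueError):
        fs.TrainConfig(initial_lr=0)
    with pytest.raises(ValueError):
        fs.TrainConfig(lr_drop_factor=1.5)
    with pytest.raises(ValueError):
        fs.TrainConfig(loss_kind="hinge")


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------


@given(n=st.integers(10, 60), k=st.integers(2, 5), seed=st.integers(0, 100))
@settings(deadline=None, max_examples=40)
def test_folds_partition_the_dataset(n, k, seed):
    split = make_folds(n, k, seed=seed)
    all_test = np.concatenate([split.test_indices(f) for f in range(k)])
    assert sorted(all_test.tolist()) == list(range(n))
    sizes = [len(split.test_indices(f)) for f in range(k)]
    assert max(sizes) - min(sizes) <= 1  # balanced
    for f in range(k):
        train, test = split.train_indices(f), split.test_indices(f)
        assert set(train) & set(test) == set()
        assert len(train) + len(test) == n


def test_folds_are_seed_deterministic():
    a = make_folds(30, 5, seed=7)
    b = make_folds(30, 5, seed=7)
    c = make_folds(30, 5, seed=8)
    assert np.array_equal(a.assignment, b.assignment)
    assert not np.array_equal(a.assignment, c.assignment)


def test_fold_validation():
    with pytest.raises(ValueError):
        make_folds(3, 5)
    with pytest.raises(ValueError):
        make_folds(10, 1)


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------


def test_adam_first_step_is_signed_lr():
    """With bias correction, the first Adam step is lr * sign(grad) (eps aside)."""
    from frozenseg.autodiff import Parameter

    p = Parameter(np.array([1.0, -2.0], dtype=np.float32))
    p.grad = np.array([0.5, -3.0], dtype=np.float32)
    opt = Adam([("p", p)])
    opt.step(lr=0.1)
    assert np.allclose(p.data, [1.0 - 0.1, -2.0 + 0.1], atol=1e-5)


def test_l2_applies_only_to_conv_weights():
    from frozenseg.autodiff import Parameter

    w = Parameter(np.array([2.0], dtype=np.float32))
    w.is_conv_weight = True
    b = Parameter(np.array([2.0], dtype=np.float32))
    w.grad = np.zeros(1, dtype=np.float32)
    b.grad = np.zeros(1, dtype=np.float32)
    opt = Adam([("w", w), ("b", b)], l2=0.1)
    opt.step(lr=0.01)
    assert w.data[0] < 2.0  # decayed
    assert b.data[0] == 2.0  # untouched


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _tiny_pairs(n=4, size=16, seed=0):
    spec = fs.SceneSpec.sinus_like(size=size)
    return [(p.image, p.mask) for p in fs.generate_dataset(spec, n, seed=seed)]


def test_training_reduces_loss_and_records_lr(tiny_config):
    pairs = _tiny_pairs()
    model = fs.build_network(tiny_config, seed=0)
    cfg = fs.TrainConfig(initial_lr=1e-3, epochs=6, batch_size=4,
                         lr_drop_period=4, seed=0)
    model, history = fs.train_model(model, pairs, cfg=cfg)
    assert len(history.lr) == 6
    assert history.lr == [lr_at_epoch(cfg, e) for e in range(1, 7)]
    # loss should improve over the run (compare first vs last thirds)
    third = max(1, len(history.loss) // 3)
    assert np.mean(history.loss[-third:]) < np.mean(history.loss[:third])


def test_frozen_kernels_bit_identical_after_training(tiny_config):
    pairs = _tiny_pairs()
    model = fs.build_network(tiny_config, seed=0)
    (name, before), = model.frozen_kernel_buffers()
    before = before.copy()
    fs.train_model(model, pairs, cfg=fs.TrainConfig(epochs=2, batch_size=4, seed=0))
    (_, after), = model.frozen_kernel_buffers()
    assert np.array_equal(before, after)
    assert np.array_equal(after, fs.make_frozen_bank().kernels)


def test_training_is_seed_deterministic(tiny_config):
    pairs = _tiny_pairs()
    x = pairs[0][0][None]
    outs = []
    for _ in range(2):
        model = fs.build_network(tiny_config, seed=3)
        fs.train_model(model, pairs, cfg=fs.TrainConfig(epochs=2, batch_size=2, seed=5))
        outs.append(model.forward(x))
    assert np.array_equal(outs[0], outs[1])


def test_empty_training_set_rejected(tiny_config):
    model = fs.build_network(tiny_config, seed=0)
    with pytest.raises(ValueError):
        fs.train_model(model, [])


def test_evaluate_model_perfect_predictor_convention(tiny_config):
    """A model evaluated against its own predictions scores Dice 1."""
    pairs = _tiny_pairs(2)
    model = fs.build_network(tiny_config, seed=0)
    preds = [
        (img, fs.predict_mask(model.forward(img[None]))[0]) for img, _ in pairs
    ]
    metrics, acc = fs.evaluate_model(model, preds)
    assert acc == 1.0
    assert metrics.mean("dice") == pytest.approx(1.0)


def test_cross_validate_shape_and_determinism(tiny_config):
    pairs = _tiny_pairs(6)
    cfg = fs.TrainConfig(epochs=1, batch_size=4)
    t1 = fs.cross_validate(pairs, 3, cfg, tiny_config, seed=0)
    t2 = fs.cross_validate(pairs, 3, cfg, tiny_config, seed=0)
    assert list(t1.index) == ["fold_1", "fold_2", "fold_3", "average"]
    assert np.allclose(t1.values, t2.values)
    folds = t1.drop(index="average")
    assert np.allclose(t1.loc["average"].values, folds.mean(axis=0).values)
    assert ((t1.values >= 0) & (t1.values <= 100)).all()
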