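"""Desk-scale synthetic benchmarks: the overfit sanity run and the module
ablation comparison.

Both run on the packaged synthetic scenes at reduced canvas and channel
widths so they complete in minutes on one CPU. The short runs use the
Dice-targeting loss and a 1e-3 learning rate: a few hundred updates is far
less optimization than a full training schedule, and the sanity questions
asked here ("can the network fit?", "does removing a module hurt?") concern
the architecture, not the full-scale protocol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import NetworkConfig, build_network
from .synthetic import SceneSpec, generate_dataset
from .training import TrainConfig, evaluate_model, train_model

ABLATION_VARIANTS = {
    "full": {},
    "no_flfp": {"enable_flfp": False},
    "no_tab": {"enable_tab": False},
    "no_pspd_fusion": {"enable_pspd_fusion": False},
}


def overfit_benchmark(seed=42, n_pairs=8, size=64, iterations=200):
    """Train on a tiny fixed set and report the training-set foreground Dice.

    A healthy implementation should fit 8 images nearly perfectly within a
    couple hundred updates; failure signals a broken gradient path.
    """
    spec = SceneSpec.sinus_like(size=size)
    pairs = [(p.image, p.mask) for p in generate_dataset(spec, n_pairs, seed=seed)]
    model = build_network(NetworkConfig.small(input_height=size, input_width=size), seed=0)
    cfg = TrainConfig(
        initial_lr=1e-3,
        epochs=iterations,
        batch_size=n_pairs,
        lr_drop_period=10 * iterations,  # constant lr over this short run
        loss_kind="weighted_dice",
        seed=0,
    )
    model, history = train_model(model, pairs, cfg=cfg, max_iterations=iterations)
    metrics, acc = evaluate_model(model, pairs)
    return {
        "foreground_dice": float(metrics.dice[1]),
        "pixel_accuracy": float(acc),
        "history": history,
        "model": model,
    }


def ablation_benchmark(seeds=(0, 1, 2), n_train=40, n_test=12, size=64, epochs=24):
    """Mean test Dice of the full model vs single-module ablations.

    For each seed a fresh train/test split is generated and all four variants
    are trained identically on it. Returns a DataFrame indexed by variant with
    per-seed foreground Dice columns and a 'mean' column.
    """
    results = {name: [] for name in ABLATION_VARIANTS}
    for seed in seeds:
        spec = SceneSpec.sinus_like(size=size)
        train = [(p.image, p.mask) for p in generate_dataset(spec, n_train, seed=1000 + seed)]
        test = [(p.image, p.mask) for p in generate_dataset(spec, n_test, seed=2000 + seed)]
        for name, flags in ABLATION_VARIANTS.items():
            ncfg = NetworkConfig.small(input_height=size, input_width=size, **flags)
            model = build_network(ncfg, seed=seed)
            cfg = TrainConfig(
                initial_lr=1e-3,
                epochs=epochs,
                batch_size=8,
                lr_drop_period=10 * epochs,
                loss_kind="weighted_dice",
                seed=seed,
            )
            train_model(model, train, cfg=cfg)
            metrics, _ = evaluate_model(model, test)
            results[name].append(float(metrics.dice[1]))
    table = pd.DataFrame(results, index=[f"seed_{s}" for s in seeds]).T
    table["mean"] = table.mean(axis=1)
    return table
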