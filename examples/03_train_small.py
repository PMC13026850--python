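"""Train a reduced-width model on synthetic scenes, end to end on one CPU.

Uses the small preset at 64x64 so the run finishes in about a minute. The
same code path scales to the full 256x256 configuration; only widths and the
canvas change.
"""

import frozenseg as fs

spec = fs.SceneSpec.sinus_like(size=64)
train = [(p.image, p.mask) for p in fs.generate_dataset(spec, 16, seed=1)]
val = [(p.image, p.mask) for p in fs.generate_dataset(spec, 4, seed=2)]

model = fs.build_network(
    fs.NetworkConfig.small(input_height=64, input_width=64), seed=0
)
cfg = fs.TrainConfig(initial_lr=1e-3, epochs=20, batch_size=8,
                     lr_drop_period=200, loss_kind="weighted_dice", seed=0)
model, history = fs.train_model(model, train, val_pairs=val, cfg=cfg)

print(f"loss: first {history.loss[0]:.4f} -> last {history.loss[-1]:.4f}")
print(f"validation mean Dice per epoch: "
      + ", ".join(f"{d:.3f}" for d in history.val_dice[-5:]))

metrics, acc = fs.evaluate_model(model, val)
print(f"val pixel accuracy {acc:.4f}, foreground Dice {metrics.dice[1]:.4f}")

model.save("scratch/example_model.npz")
print("checkpoint written to scratch/example_model.npz")
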