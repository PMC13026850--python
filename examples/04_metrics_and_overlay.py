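"""Evaluate predictions and render a colour-coded error overlay.

Metrics follow the shared-count identities (Dice = 2*IoU/(1+IoU)); the
overlay paints true positives blue, false positives green, and false
negatives red over a dimmed grayscale of the input.
"""

import numpy as np
from PIL import Image

import frozenseg as fs

spec = fs.SceneSpec.sinus_like(size=128)
pair = fs.generate_scene(spec, seed=3)

# a deliberately imperfect "prediction": the true mask shifted by 2 px
pred = np.roll(pair.mask, 2, axis=1)

metrics = fs.metrics_from_masks(pred, pair.mask, num_classes=2)
table = fs.metrics_table([metrics], ["shifted"])
print(table.to_string())
print(f"boundary F1 (default tolerance): "
      f"{fs.bf_score(pred == 1, pair.mask == 1):.3f}")

overlay = fs.error_overlay(pred == 1, pair.mask == 1, pair.image)
Image.fromarray((overlay * 255).astype(np.uint8)).save("scratch/overlay.png")
print("overlay written to scratch/overlay.png")
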