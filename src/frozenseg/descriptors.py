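"""Deterministic scene descriptors derived from a prediction mask, and the
text prompt builder for a pluggable summarization backend.

The descriptors are pure functions of (image, mask): per-class area ratios,
class presence, whether the instrument touches the image border, and a
blur-related quality indicator (variance of the Laplacian response of the
luma channel — the standard focus measure). Actual language-model inference
is out of scope; any callable mapping a prompt string to text can serve as a
backend, and a trivial echo backend ships for tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .filters import apply_frozen_bank, make_frozen_bank

NON_CLINICAL_DISCLAIMER = (
    "This summary is generated automatically for non-clinical, illustrative "
    "purposes only and must not be used for clinical decision-making."
)


@dataclass
class SceneDescriptors:
    area_ratio: np.ndarray  # per class, sums to 1
    presence: np.ndarray  # per class, boolean
    instrument_border_touch: bool
    blur_score: float  # variance of Laplacian response; 0 for constant images
    image_size: tuple  # (H, W)

    def to_json(self):
        d = asdict(self)
        d["area_ratio"] = [float(v) for v in self.area_ratio]
        d["presence"] = [bool(v) for v in self.presence]
        d["image_size"] = list(self.image_size)
        return json.dumps(d, indent=2, sort_keys=True)


def blur_score(image):
    """Variance of the 4-neighbour Laplacian response of the luma channel."""
    image = np.asarray(image, dtype=np.float64)
    luma = image @ np.array([0.299, 0.587, 0.114]) if image.ndim == 3 else image
    responses = apply_frozen_bank(luma[:, :, None], make_frozen_bank())
    lap = responses[:, :, 2]  # bank order: sobel_x, sobel_y, laplacian
    return float(lap.var())


def compute_descriptors(image, mask, num_classes=None, instrument_class=1,
                        border_margin=1) -> SceneDescriptors:
    """Descriptors from an (image, mask) pair; both must share spatial size."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask sizes differ")
    if num_classes is None:
        num_classes = int(mask.max()) + 1
    h, w = mask.shape
    counts = np.bincount(mask.ravel(), minlength=num_classes).astype(float)
    area_ratio = counts / (h * w)
    presence = counts > 0
    frame = np.zeros_like(mask, bool)
    m = border_margin
    frame[:m, :] = frame[-m:, :] = frame[:, :m] = frame[:, -m:] = True
    touch = bool(np.any((mask == instrument_class) & frame))
    return SceneDescriptors(
        area_ratio=area_ratio,
        presence=presence,
        instrument_border_touch=touch,
        blur_score=blur_score(image),
        image_size=(h, w),
    )


def build_summary_prompt(d: SceneDescriptors, class_names) -> str:
    """Deterministic serialization of every descriptor field into a prompt.

    Identical descriptors yield byte-identical prompts; the prompt always ends
    with the non-clinical disclaimer.
    """
    if len(class_names) < len(d.area_ratio):
        raise ValueError("class_names must cover every class")
    lines = [
        "Summarize the following segmented endoscopic scene in plain language.",
        f"Image size: {d.image_size[0]}x{d.image_size[1]} pixels.",
        "Per-class area ratios:",
    ]
    for name, ratio, present in zip(class_names, d.area_ratio, d.presence):
        status = "present" if present else "absent"
        lines.append(f"  - {name}: {ratio * 100:.1f}% of the image ({status})")
    touch = "touches" if d.instrument_border_touch else "does not touch"
    lines.append(f"The instrument {touch} the image border.")
    lines.append(f"Blur indicator (variance of Laplacian): {d.blur_score:.6g}.")
    lines.append(NON_CLINICAL_DISCLAIMER)
    return "\n".join(lines)


class EchoBackend:
    """Trivial text backend returning a fixed-form digest of the prompt."""

    def __call__(self, prompt: str) -> str:
        return "SCENE SUMMARY (echo backend):\n" + prompt


def summarize_scene(image, mask, class_names, backend=None, **descriptor_kwargs):
    """Descriptors -> prompt -> backend text. Backend defaults to the echo one."""
    d = compute_descriptors(image, mask, num_classes=len(class_names), **descriptor_kwargs)
    prompt = build_summary_prompt(d, class_names)
    backend = backend or EchoBackend()
    return d, prompt, backend(prompt)
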