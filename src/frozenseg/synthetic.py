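"""Synthetic endoscopic-scene generator.

Emulates the challenge structure of endoscopic instrument datasets: thin,
elongated, bright metallic instruments entering from an image border over a
reddish low-frequency tissue texture, degraded by blur, glare, partial
occlusion, smoke, and low contrast. Masks are rendered before any
degradation, so artifacts corrupt the image but never the labels — matching
how real annotations describe the instrument rather than the artifact.

Scenes are fully determined by (spec, seed). A multi-class preset adds two
large amorphous anatomy regions echoing laparoscopic scenes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image
from scipy import ndimage

ARTIFACTS = ("blur", "glare", "occlusion", "smoke", "low_contrast")


@dataclass
class SceneSpec:
    height: int = 256
    width: int = 256
    num_classes: int = 2
    instrument_count_range: tuple = (1, 2)
    instrument_width_range: tuple = (5, 16)  # pixels (scaled with canvas below)
    instrument_length_range: tuple = (96, 240)
    artifact_probabilities: dict = field(
        default_factory=lambda: {
            "blur": 0.30,
            "glare": 0.30,
            "occlusion": 0.20,
            "smoke": 0.20,
            "low_contrast": 0.30,
        }
    )
    background_texture_scale: int = 32

    def __post_init__(self):
        lo, hi = self.instrument_count_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid instrument_count_range")
        for rng_ in (self.instrument_width_range, self.instrument_length_range):
            if not (0 < rng_[0] <= rng_[1]):
                raise ValueError("invalid instrument size range")
        for name, p in self.artifact_probabilities.items():
            if name not in ARTIFACTS:
                raise ValueError(f"unknown artifact {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError("artifact probabilities must lie in [0,1]")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")

    @classmethod
    def sinus_like(cls, size=256, **overrides):
        """Binary instrument-vs-background preset; 240 and 512 canvases supported."""
        scale = size / 256
        base = dict(
            height=size,
            width=size,
            num_classes=2,
            instrument_width_range=(max(3, int(5 * scale)), max(4, int(16 * scale))),
            instrument_length_range=(int(96 * scale), int(240 * scale)),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def cholec_like(cls, size=256, **overrides):
        """Multi-class preset: background, instrument, and two anatomy regions."""
        spec = cls.sinus_like(size=size, num_classes=4)
        for k, v in overrides.items():
            setattr(spec, k, v)
        return spec

    def to_dict(self):
        return asdict(self)


@dataclass
class SamplePair:
    image: np.ndarray  # H x W x 3 float in [0,1]
    mask: np.ndarray  # H x W integer labels
    seed: int
    applied_artifacts: list


def _smooth_noise(rng, h, w, scale):
    """Low-frequency noise in [0,1] from smoothed white noise."""
    raw = rng.standard_normal((h, w))
    field_ = ndimage.gaussian_filter(raw, sigma=max(scale / 2, 1.0), mode="reflect")
    lo, hi = field_.min(), field_.max()
    return (field_ - lo) / (hi - lo + 1e-12)


def _background(rng, spec):
    t = _smooth_noise(rng, spec.height, spec.width, spec.background_texture_scale)
    t2 = _smooth_noise(rng, spec.height, spec.width, spec.background_texture_scale / 4)
    img = np.empty((spec.height, spec.width, 3))
    img[:, :, 0] = 0.45 + 0.35 * t + 0.05 * t2  # reddish dominant channel
    img[:, :, 1] = 0.12 + 0.18 * t * t2
    img[:, :, 2] = 0.10 + 0.15 * t2
    return np.clip(img, 0, 1)


def _capsule_distance(h, w, p0, direction, length):
    """Distance from every pixel to the segment p0 -> p0 + length*direction."""
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d = np.asarray(direction, float)
    rel = np.stack([yy - p0[0], xx - p0[1]], axis=-1)
    t = np.clip(rel @ d, 0.0, length)
    closest = p0 + t[..., None] * d
    return np.hypot(yy - closest[..., 0], xx - closest[..., 1])


def _draw_anatomy(rng, spec, image, mask):
    """Two large amorphous regions (classes 2, 3) under the instruments."""
    for cls, tint in ((2, np.array([0.75, 0.65, 0.25])), (3, np.array([0.55, 0.30, 0.20]))):
        blob = _smooth_noise(rng, spec.height, spec.width, spec.background_texture_scale)
        cy, cx = rng.uniform(0.2, 0.8, 2) * (spec.height, spec.width)
        yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
        radial = np.hypot((yy - cy) / spec.height, (xx - cx) / spec.width)
        region = (blob - 2.0 * radial) > np.quantile(blob - 2.0 * radial, 0.85)
        mask[region] = cls
        alpha = 0.8
        image[region] = (1 - alpha) * image[region] + alpha * (
            tint * (0.7 + 0.3 * blob[region, None])
        )
    return image, mask


def _draw_instrument(rng, spec, image, mask):
    h, w = spec.height, spec.width
    width = rng.uniform(*spec.instrument_width_range)
    length = rng.uniform(*spec.instrument_length_range)
    if length >= np.hypot(h, w):
        raise ValueError("instrument length exceeds the frame diagonal")
    # entry point on a border, heading inward
    side = rng.integers(4)
    if side == 0:
        p0, base_angle = (0.0, rng.uniform(0, w)), np.pi / 2
    elif side == 1:
        p0, base_angle = (h - 1.0, rng.uniform(0, w)), -np.pi / 2
    elif side == 2:
        p0, base_angle = (rng.uniform(0, h), 0.0), 0.0
    else:
        p0, base_angle = (rng.uniform(0, h), w - 1.0), np.pi
    angle = base_angle + rng.uniform(-np.pi / 4, np.pi / 4)
    direction = np.array([np.sin(angle), np.cos(angle)])
    dist = _capsule_distance(h, w, np.asarray(p0, float), direction, length)

    radius = width / 2
    hard = dist <= radius
    if not hard.any():
        return image, mask
    mask[hard] = 1

    # metallic-gray shading with a specular stripe along the shaft axis
    alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)  # anti-aliased in the image only
    base_gray = rng.uniform(0.55, 0.85)
    stripe = np.exp(-((dist - radius * rng.uniform(0.1, 0.4)) ** 2) / (2 * (radius / 3) ** 2))
    shade = np.clip(base_gray + 0.35 * stripe, 0, 1)
    color = np.stack([shade, shade, shade * rng.uniform(0.95, 1.05)], axis=-1)
    image = (1 - alpha[..., None]) * image + alpha[..., None] * np.clip(color, 0, 1)
    return image, mask


def degrade(image, artifact, strength, seed=0):
    """Apply one named degradation to an RGB image in [0,1].

    Strength 0 is the identity for every artifact; outputs are clipped to
    [0,1]. The seed drives artifact geometry (blob placement, haze field).
    """
    image = np.asarray(image, dtype=np.float64)
    if artifact not in ARTIFACTS:
        raise ValueError(f"unknown artifact {artifact!r}")
    if strength == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]
    if artifact == "blur":
        out = ndimage.gaussian_filter(image, sigma=(3.0 * strength, 3.0 * strength, 0))
    elif artifact == "glare":
        cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
        yy, xx = np.mgrid[0:h, 0:w]
        blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (0.12 * min(h, w)) ** 2)))
        out = image + strength * blob[..., None]
    elif artifact == "occlusion":
        cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
        yy, xx = np.mgrid[0:h, 0:w]
        blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (0.18 * min(h, w)) ** 2)))
        blot = np.array([0.25, 0.02, 0.02])  # dark red
        a = strength * np.clip(blob, 0, 1)[..., None]
        out = (1 - a) * image + a * blot
    elif artifact == "smoke":
        haze = _smooth_noise(rng, h, w, min(h, w) / 6)
        a = strength * (0.3 + 0.7 * haze)[..., None]
        out = (1 - a) * image + a * 1.0
    else:  # low_contrast
        out = 0.5 + (image - 0.5) * (1.0 - strength)
    return np.clip(out, 0.0, 1.0)


def generate_scene(spec: SceneSpec, seed: int) -> SamplePair:
    """Render one (image, mask) pair, fully determined by (spec, seed)."""
    rng = np.random.default_rng(seed)
    image = _background(rng, spec)
    mask = np.zeros((spec.height, spec.width), dtype=np.int64)
    if spec.num_classes >= 4:
        image, mask = _draw_anatomy(rng, spec, image, mask)
    n_instr = int(rng.integers(spec.instrument_count_range[0], spec.instrument_count_range[1] + 1))
    for _ in range(n_instr):
        image, mask = _draw_instrument(rng, spec, image, mask)

    applied = []
    for name in ARTIFACTS:
        p = spec.artifact_probabilities.get(name, 0.0)
        roll = rng.uniform()
        strength = rng.uniform(0.2, 0.6)
        sub_seed = int(rng.integers(2**31))
        if roll < p:
            image = degrade(image, name, strength, seed=sub_seed)
            applied.append(name)
    return SamplePair(image=image, mask=mask, seed=int(seed), applied_artifacts=applied)


def generate_dataset(spec: SceneSpec, n: int, seed: int):
    """n scenes from a master seed via independent spawned substreams."""
    root = np.random.SeedSequence(seed)
    return [generate_scene(spec, int(s.generate_state(1)[0] % 2**31)) for s in root.spawn(n)]


def merge_rare_classes(mask, mapping):
    """Relabel pixels through an old-label -> new-label mapping.

    The mapping must cover every label present; pixel count is conserved.
    """
    mask = np.asarray(mask)
    present = np.unique(mask)
    missing = [int(v) for v in present if int(v) not in mapping]
    if missing:
        raise ValueError(f"labels without a mapping entry: {missing}")
    lut = np.arange(int(present.max()) + 1)
    for old, new in mapping.items():
        if old <= present.max():
            lut[old] = new
    return lut[mask]


# ---------------------------------------------------------------------------
# image/mask I/O — 8-bit RGB PNG + single-channel indexed-palette PNG
# ---------------------------------------------------------------------------

_PALETTE = [
    (0, 0, 0),
    (255, 64, 64),
    (64, 255, 64),
    (64, 64, 255),
    (255, 255, 64),
    (255, 64, 255),
    (64, 255, 255),
    (192, 192, 192),
]


def write_pair(path_prefix, pair: SamplePair):
    """Write `<prefix>_img.png` (8-bit RGB) and `<prefix>_mask.png` (indexed)."""
    img8 = np.clip(np.round(pair.image * 255), 0, 255).astype(np.uint8)
    Image.fromarray(img8, mode="RGB").save(f"{path_prefix}_img.png")
    m = Image.fromarray(pair.mask.astype(np.uint8), mode="P")
    palette = []
    for i in range(256):
        palette.extend(_PALETTE[i % len(_PALETTE)])
    m.putpalette(palette)
    m.save(f"{path_prefix}_mask.png")
    return f"{path_prefix}_img.png", f"{path_prefix}_mask.png"


def read_pair(path_prefix) -> SamplePair:
    """Inverse of :func:`write_pair`; rejects image/mask size mismatches."""
    img_path, mask_path = f"{path_prefix}_img.png", f"{path_prefix}_mask.png"
    with Image.open(img_path) as im:
        image = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    with Image.open(mask_path) as mm:
        mask = np.asarray(mm, dtype=np.int64)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image size {image.shape[:2]} does not match mask size {mask.shape}"
        )
    return SamplePair(image=image, mask=mask, seed=-1, applied_artifacts=[])


def write_dataset(outdir, spec: SceneSpec, n: int, seed: int):
    """Write n pairs plus a manifest CSV with per-class pixel totals."""
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    pairs = generate_dataset(spec, n, seed)
    rows = []
    for i, pair in enumerate(pairs):
        prefix = os.path.join(outdir, f"scene_{i:04d}")
        img_path, mask_path = write_pair(prefix, pair)
        counts = np.bincount(pair.mask.ravel(), minlength=spec.num_classes)
        row = {"image": img_path, "mask": mask_path, "seed": pair.seed}
        row.update({f"class_{k}_pixels": int(c) for k, c in enumerate(counts)})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.attrs["spec"] = spec.to_dict()
    manifest.attrs["master_seed"] = seed
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return manifest
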