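"""The full segmentation network.

Topology: a stem that fuses a learnable branch with frozen edge-filter
responses (the frozen-and-learnable feature pipeline), three stride-2 encoder
stages, a tri-atrous bottleneck blending three dilation rates, and a
structure-preserving decoder of three transposed-convolution upsamplings,
each fusing light-skip-path encoder features and aggregating a dilated and a
standard branch by element-wise addition. A 1x1 head plus per-pixel softmax
produces class probabilities.

The default channel plan keeps the trainable parameter count at or below
1.5 million; the frozen kernels are buffers and never counted or trained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .filters import make_frozen_bank
from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvBNReLU,
    ConvTranspose2d,
    FrozenFilterUnit,
    LightSkipPath,
    Module,
)

PARAM_BUDGET = 1_500_000


@dataclass
class NetworkConfig:
    """Architectural free parameters.

    Three encoder stride-2 stages mirror three decoder upsamplings, so the
    output resolution equals the input resolution and the input sides must be
    divisible by 8.
    """

    input_height: int = 256
    input_width: int = 256
    input_channels: int = 3
    num_classes: int = 2
    stem_width: int = 16
    encoder_widths: tuple = (32, 64, 128)
    tab_width: int = 64
    tab_dilations: tuple = (2, 4, 6)
    decoder_widths: tuple = (64, 32, 16)
    pspd_dilation: int = 2
    enable_flfp: bool = True
    enable_tab: bool = True
    enable_pspd_fusion: bool = True

    def __post_init__(self):
        self.encoder_widths = tuple(self.encoder_widths)
        self.tab_dilations = tuple(self.tab_dilations)
        self.decoder_widths = tuple(self.decoder_widths)
        if self.input_height % 8 or self.input_width % 8:
            raise ValueError("input sides must be divisible by 8 (three stride-2 stages)")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.encoder_widths) != 3 or len(self.decoder_widths) != 3:
            raise ValueError("exactly 3 encoder and 3 decoder stages")
        if len(self.tab_dilations) != 3 or list(self.tab_dilations) != sorted(
            set(self.tab_dilations)
        ):
            raise ValueError("tab_dilations must be 3 strictly increasing integers")
        widths = (self.stem_width, self.tab_width, *self.encoder_widths, *self.decoder_widths)
        if any(w <= 0 for w in widths):
            raise ValueError("channel widths must be positive")
        if self.pspd_dilation < 1:
            raise ValueError("pspd_dilation must be >= 1")

    @classmethod
    def small(cls, **overrides):
        """Reduced-width preset for fast experiments on small canvases."""
        base = dict(
            input_height=64,
            input_width=64,
            stem_width=8,
            encoder_widths=(16, 32, 64),
            tab_width=32,
            decoder_widths=(32, 16, 8),
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


class _Stem(Module):
    """Learnable branch || frozen-filter unit, concatenated then squeezed."""

    def __init__(self, rng, cfg):
        super().__init__()
        cin, w = cfg.input_channels, cfg.stem_width
        self.learn1 = self.add_child("learn1", ConvBNReLU(rng, cin, w))
        self.learn2 = self.add_child("learn2", ConvBNReLU(rng, w, w))
        self.ffu = self.add_child("ffu", FrozenFilterUnit(rng, cin, w, make_frozen_bank().kernels))
        self.squeeze = self.add_child("squeeze", ConvBNReLU(rng, w + 3 * w, w, k=1))

    def forward(self, x):
        learned = self.learn2(self.learn1(x))
        frozen = self.ffu(x)
        return self.squeeze(ad.concat([learned, frozen]))


class _PlainStem(Module):
    """Ablation stand-in: same width, no frozen branch."""

    def __init__(self, rng, cfg):
        super().__init__()
        cin, w = cfg.input_channels, cfg.stem_width
        self.learn1 = self.add_child("learn1", ConvBNReLU(rng, cin, w))
        self.learn2 = self.add_child("learn2", ConvBNReLU(rng, w, w))

    def forward(self, x):
        return self.learn2(self.learn1(x))


class _EncoderStage(Module):
    def __init__(self, rng, cin, cout):
        super().__init__()
        self.down = self.add_child("down", Conv2d(rng, cin, cout, k=3, stride=2, bias=True))
        self.refine = self.add_child("refine", ConvBNReLU(rng, cout, cout))

    def forward(self, x):
        return self.refine(self.down(x))


class _TriAtrousBlock(Module):
    """Three parallel dilated streams, each pointwise-squeezed, then fused."""

    def __init__(self, rng, cin, stream_width, dilations, cout):
        super().__init__()
        self.streams = []
        for i, d in enumerate(dilations):
            atr = self.add_child(f"atrous{i}", Conv2d(rng, cin, stream_width, k=3, dilation=d, bias=True))
            pw = self.add_child(f"pw{i}", Conv2d(rng, stream_width, stream_width, k=1, bias=True))
            self.streams.append((atr, pw))
        self.fuse = self.add_child("fuse", ConvBNReLU(rng, stream_width * len(dilations), cout))

    def forward(self, x):
        outs = [pw(ad.relu(atr(x))) for atr, pw in self.streams]
        return self.fuse(ad.concat(outs))


class _DecoderStage(Module):
    """Upsample, fuse skip features, aggregate dilated + standard branches."""

    def __init__(self, rng, cin, cout, skip_c, dilation, fusion):
        super().__init__()
        self.fusion = fusion
        self.up = self.add_child("up", ConvTranspose2d(rng, cin, cout))
        if fusion:
            merged = cout + skip_c
            self.dil = self.add_child("dil", Conv2d(rng, merged, cout, k=3, dilation=dilation, bias=True))
            self.std = self.add_child("std", Conv2d(rng, merged, cout, k=3, bias=True))
        self.refine = self.add_child("refine", ConvBNReLU(rng, cout, cout))

    def forward(self, x, skip):
        up = self.up(x)
        if not self.fusion:
            return self.refine(up)
        merged = ad.concat([up, skip])
        return self.refine(ad.add(self.dil(merged), self.std(merged)))


class SegModel(Module):
    """Built network handle; use :func:`build_network` to construct one."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        w = cfg.stem_width
        e1, e2, e3 = cfg.encoder_widths
        d1, d2, d3 = cfg.decoder_widths

        stem_cls = _Stem if cfg.enable_flfp else _PlainStem
        self.stem = self.add_child("stem", stem_cls(rng, cfg))
        self.enc1 = self.add_child("enc1", _EncoderStage(rng, w, e1))
        self.enc2 = self.add_child("enc2", _EncoderStage(rng, e1, e2))
        self.enc3 = self.add_child("enc3", _EncoderStage(rng, e2, e3))
        if cfg.enable_tab:
            self.bottleneck = self.add_child(
                "tab", _TriAtrousBlock(rng, e3, cfg.tab_width, cfg.tab_dilations, e3)
            )
        else:
            self.bottleneck = self.add_child("tab", ConvBNReLU(rng, e3, e3))
        if cfg.enable_pspd_fusion:
            self.lsp_c2 = self.add_child("lsp_c2", LightSkipPath(rng, e2, e2))
            self.lsp_c3 = self.add_child("lsp_c3", LightSkipPath(rng, e1, e1))
            self.lsp_c4 = self.add_child("lsp_c4", LightSkipPath(rng, w, w))
        self.dec1 = self.add_child(
            "dec1", _DecoderStage(rng, e3, d1, e2, cfg.pspd_dilation, cfg.enable_pspd_fusion)
        )
        self.dec2 = self.add_child(
            "dec2", _DecoderStage(rng, d1, d2, e1, cfg.pspd_dilation, cfg.enable_pspd_fusion)
        )
        self.dec3 = self.add_child(
            "dec3", _DecoderStage(rng, d2, d3, w, cfg.pspd_dilation, cfg.enable_pspd_fusion)
        )
        self.head = self.add_child("head", Conv2d(rng, d3, cfg.num_classes, k=1, bias=True))
        self.training = True

    # -- mode switching --------------------------------------------------
    def set_training(self, flag):
        self.training = flag
        stack = [self]
        while stack:
            m = stack.pop()
            if isinstance(m, BatchNorm2d):
                m.training = flag
            stack.extend(m._children.values())

    # -- forward ----------------------------------------------------------
    def forward_tensor(self, x: Tensor) -> Tensor:
        """NCHW tensor in, NCKHW... probability tensor out (graph retained)."""
        s = self.stem(x)  # full res, stem_width
        f1 = self.enc1(s)  # /2
        f2 = self.enc2(f1)  # /4
        f3 = self.enc3(f2)  # /8
        b = self.bottleneck(f3)
        if self.cfg.enable_pspd_fusion:
            y = self.dec1(b, self.lsp_c2(f2))  # fusion point C2 at /4
            y = self.dec2(y, self.lsp_c3(f1))  # fusion point C3 at /2
            y = self.dec3(y, self.lsp_c4(s))  # fusion point C4 at full res
        else:
            y = self.dec3(self.dec2(self.dec1(b, None), None), None)
        return ad.channel_softmax(self.head(y))

    def forward(self, batch):
        """Inference on an N x H x W x C array in [0,1] -> N x H x W x K probabilities."""
        x = np.asarray(batch, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        n, h, w, c = x.shape
        if (h, w, c) != (self.cfg.input_height, self.cfg.input_width, self.cfg.input_channels):
            raise ValueError(
                f"batch shape {(h, w, c)} does not match config "
                f"{(self.cfg.input_height, self.cfg.input_width, self.cfg.input_channels)}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in input batch")
        was_training = self.training
        self.set_training(False)
        try:
            xin = np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=ad.DTYPE)
            probs = self.forward_tensor(Tensor(xin)).data.astype(np.float64)
        finally:
            self.set_training(was_training)
        return probs.transpose(0, 2, 3, 1)

    # -- parameter bookkeeping ---------------------------------------------
    def trainable_parameters(self):
        return list(self.parameters())

    def frozen_kernel_buffers(self):
        return [(n, b) for n, b in self.buffers() if "mffl" in n]

    # -- checkpointing -----------------------------------------------------
    def save(self, path):
        arrays = {f"param:{n}": p.data for n, p in self.parameters()}
        arrays.update({f"buffer:{n}": b for n, b in self.buffers()})
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            cfg = NetworkConfig.from_dict(json.loads(bytes(z["config_json"]).decode()))
            model = build_network(cfg)
            params = dict(model.parameters())
            for key in z.files:
                if key.startswith("param:"):
                    params[key[6:]].data[...] = z[key]
                elif key.startswith("buffer:"):
                    name = key[7:]
                    for bn, b in model.buffers():
                        if bn == name:
                            if b.flags.writeable:
                                b[...] = z[key]
                            elif not np.array_equal(b, z[key]):
                                raise ValueError("checkpoint frozen kernels differ from canonical bank")
        model.set_training(False)
        return model


def build_network(cfg: NetworkConfig, seed=None, check_budget=False) -> SegModel:
    """Construct the model; He-uniform init, reproducible when `seed` is given."""
    rng = np.random.default_rng(seed)
    model = SegModel(cfg, rng)
    if check_budget and count_trainable_params(model) > PARAM_BUDGET:
        raise ValueError(
            f"configuration exceeds the {PARAM_BUDGET:,} trainable-parameter budget"
        )
    return model


def count_trainable_params(model: SegModel) -> int:
    """Total element count of learnable weights/biases/BN affine parameters.

    Frozen filter kernels are buffers, so they are excluded by construction.
    """
    return int(sum(p.data.size for _, p in model.parameters()))


def predict_mask(probs):
    """Per-pixel argmax over class probabilities; ties go to the lowest index."""
    p = np.asarray(probs)
    return np.argmax(p, axis=-1).astype(np.int64)
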