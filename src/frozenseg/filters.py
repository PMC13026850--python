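"""Frozen edge/curvature filter bank.

The multi-filter frozen layer (MFFL) holds three fixed 3x3 kernels — the two
Sobel first-derivative operators and the 4-neighbour Laplacian — that are
applied depthwise and never updated by training. They preserve instrument
edge and orientation information that learnable layers tend to wash out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, depthwise_frozen_conv

SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T.copy()
LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class FrozenKernelBank:
    """An immutable ordered bank of fixed 3x3 kernels."""

    kernels: np.ndarray  # (3, 3, 3), read-only
    names: tuple = ("sobel_x", "sobel_y", "laplacian")

    def __post_init__(self):
        k = np.asarray(self.kernels, dtype=np.float64)
        if k.shape != (len(self.names), 3, 3):
            raise ValueError(f"expected {(len(self.names), 3, 3)} kernels, got {k.shape}")
        k = k.copy()
        k.setflags(write=False)
        object.__setattr__(self, "kernels", k)

    def __getitem__(self, name):
        return self.kernels[self.names.index(name)]

    def to_text(self):
        """Plain-text serialization of the bank for inspection."""
        lines = []
        for name, k in zip(self.names, self.kernels):
            lines.append(name)
            for row in k:
                lines.append("  " + " ".join(f"{v:g}" for v in row))
        return "\n".join(lines) + "\n"


def make_frozen_bank():
    """The canonical bank: Sobel-x, Sobel-y (its transpose), 4-neighbour Laplacian."""
    return FrozenKernelBank(np.stack([SOBEL_X, SOBEL_Y, LAPLACIAN]))


def apply_frozen_bank(features, bank=None):
    """Convolve each channel of an H x W x C stack with every kernel in the bank.

    Borders are handled reflectively so responses exist at all H x W
    positions. Output channels are ordered channel-major, kernel-minor:
    (c0*sobel_x, c0*sobel_y, c0*laplacian, c1*sobel_x, ...). No learnable
    parameters are involved.

    Parameters
    ----------
    features : ndarray, H x W (single channel) or H x W x C
    bank : FrozenKernelBank, optional

    Returns
    -------
    ndarray, H x W x (C * 3)
    """
    if bank is None:
        bank = make_frozen_bank()
    f = np.asarray(features, dtype=np.float64)
    if f.ndim == 2:
        f = f[:, :, None]
    if f.ndim != 3:
        raise ValueError("features must be H x W or H x W x C")
    h, w, c = f.shape
    if h < 3 or w < 3:
        raise ValueError("input smaller than the 3x3 kernels")
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite values in input")
    x = Tensor(f.transpose(2, 0, 1)[None])  # 1,C,H,W
    out = depthwise_frozen_conv(x, bank.kernels).data[0]
    return out.transpose(1, 2, 0)
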