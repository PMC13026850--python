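"""Minimal reverse-mode autodiff over NumPy arrays for small CNNs.

Only the operations the segmentation network needs are provided: 2-D
convolution (strided / dilated / transposed), batch normalization, ReLU,
channel concatenation, element-wise addition, channel softmax, and the two
training losses. Convolutions are lowered to BLAS matmuls through im2col.

Array layout is NCHW throughout this module.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "conv2d",
    "conv_transpose2d",
    "depthwise_frozen_conv",
    "batch_norm",
    "relu",
    "add",
    "concat",
    "channel_softmax",
]


# training dtype; the public frozen-filter API overrides this with float64
DTYPE = np.float32


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, dtype=None):
        data = np.asarray(data)
        if dtype is not None:
            data = data.astype(dtype, copy=False)
        elif data.dtype not in (np.float32, np.float64):
            data = data.astype(DTYPE)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Accumulate gradients of a scalar-valued tensor into the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g


class Parameter(Tensor):
    """A trainable leaf tensor."""

    __slots__ = ("name", "is_conv_weight")

    def __init__(self, data, name=""):
        super().__init__(data, requires_grad=True)
        self.name = name
        self.is_conv_weight = False


# ---------------------------------------------------------------------------
# im2col machinery
# ---------------------------------------------------------------------------


def _same_padding(h, w, k, stride, dilation):
    """TensorFlow-style SAME padding so output size is ceil(in/stride)."""
    eff = dilation * (k - 1) + 1

    def axis(n):
        out = -(-n // stride)
        total = max((out - 1) * stride + eff - n, 0)
        return total // 2, total - total // 2

    return axis(h), axis(w)


def _im2col(xp, k, stride, dilation):
    """(N,C,Hp,Wp) padded input -> (N, C*k*k, Ho*Wo) patch matrix.

    Filled tap-by-tap with contiguous strided slices, so the copy is
    cache-friendly and the result feeds straight into batched matmuls.
    """
    n, c, hp, wp = xp.shape
    eff = dilation * (k - 1) + 1
    ho = (hp - eff) // stride + 1
    wo = (wp - eff) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[
                :,
                :,
                i * dilation : i * dilation + ho * stride : stride,
                j * dilation : j * dilation + wo * stride : stride,
            ]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(dcols, xp_shape, k, stride, dilation, ho, wo):
    """Adjoint of _im2col: scatter-add patches back onto the padded canvas."""
    n, c, hp, wp = xp_shape
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[
                :,
                :,
                i * dilation : i * dilation + ho * stride : stride,
                j * dilation : j * dilation + wo * stride : stride,
            ] += d[:, :, i, j]
    return dxp


def _pad_zero(x, ph, pw):
    return np.pad(x, ((0, 0), (0, 0), ph, pw))


def _unpad(dxp, ph, pw, h, w):
    return dxp[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + w]


# ---------------------------------------------------------------------------
# convolution ops
# ---------------------------------------------------------------------------


def conv2d(x, weight, bias=None, stride=1, dilation=1):
    """SAME-padded 2-D convolution. weight: (Cout, Cin, k, k)."""
    n, cin, h, w = x.data.shape
    cout, cin_w, k, _ = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    if k == 1 and stride == 1:
        # pointwise fast path: the patch matrix is the input itself
        cols, ho, wo = x.data.reshape(n, cin, h * w), h, w
        xp, ph, pw = None, None, None
    else:
        ph, pw = _same_padding(h, w, k, stride, dilation)
        xp = _pad_zero(x.data, ph, pw)
        cols, ho, wo = _im2col(xp, k, stride, dilation)  # N, Cin*k*k, P
    wmat = weight.data.reshape(cout, -1)
    out = np.matmul(wmat, cols)  # N, Cout, P
    if bias is not None:
        out = out + bias.data[None, :, None]
    out = out.reshape(n, cout, ho, wo)

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        gmat = g.reshape(n, cout, ho * wo)
        if weight.requires_grad:
            dw = np.tensordot(gmat, cols, axes=([0, 2], [0, 2]))
            weight._accumulate(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, gmat)  # N, Cin*k*k, P
            if xp is None:
                x._accumulate(dcols.reshape(n, cin, h, w))
            else:
                dxp = _col2im(dcols, xp.shape, k, stride, dilation, ho, wo)
                x._accumulate(_unpad(dxp, ph, pw, h, w))

    return Tensor(out, parents=parents, backward=backward)


def conv_transpose2d(x, weight, bias=None):
    """Learnable x2 upsampling: kernel 4, stride 2, padding 1.

    weight: (Cin, Cout, 4, 4). Output spatial size is exactly 2x the input.
    """
    n, cin, h, w = x.data.shape
    cin_w, cout, k, _ = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    if k != 4:
        raise ValueError("conv_transpose2d is fixed to kernel 4, stride 2")
    stride, pad = 2, 1
    ho, wo = 2 * h, 2 * w
    # forward of a transposed conv == input-gradient of the matching conv
    wmat = weight.data.reshape(cin, -1)  # Cin x (Cout*k*k)
    xmat = x.data.reshape(n, cin, h * w)  # N, Cin, P
    dcols = np.matmul(wmat.T, xmat)  # N, Cout*k*k, P
    yp_shape = (n, cout, ho + 2 * pad, wo + 2 * pad)
    yp = _col2im(dcols, yp_shape, k, stride, 1, h, w)
    out = yp[:, :, pad : pad + ho, pad : pad + wo]
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        gp = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        gcols, gh, gw = _im2col(gp, k, stride, 1)  # N, Cout*k*k, P(=h*w)
        if x.requires_grad:
            dx = np.matmul(wmat, gcols).reshape(n, cin, h, w)
            x._accumulate(dx)
        if weight.requires_grad:
            dw = np.tensordot(xmat, gcols, axes=([0, 2], [0, 2]))
            weight._accumulate(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor(out, parents=parents, backward=backward)


def _reflect_pad1(x):
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="reflect")


def _reflect_pad1_adjoint(dxp):
    """Fold gradients of reflect-padded (pad=1) borders back onto the interior."""
    dx = dxp[:, :, 1:-1, 1:-1].copy()
    dx[:, :, 1, :] += dxp[:, :, 0, 1:-1]
    dx[:, :, -2, :] += dxp[:, :, -1, 1:-1]
    dx[:, :, :, 1] += dxp[:, :, 1:-1, 0]
    dx[:, :, :, -2] += dxp[:, :, 1:-1, -1]
    # corners reflect both axes
    dx[:, :, 1, 1] += dxp[:, :, 0, 0]
    dx[:, :, 1, -2] += dxp[:, :, 0, -1]
    dx[:, :, -2, 1] += dxp[:, :, -1, 0]
    dx[:, :, -2, -2] += dxp[:, :, -1, -1]
    return dx


def depthwise_frozen_conv(x, kernels):
    """Apply fixed 3x3 kernels depthwise with reflective borders.

    kernels: (K, 3, 3) ndarray (NOT a Parameter; carries no gradient).
    Output has C*K channels ordered channel-major, kernel-minor.
    """
    kernels = np.asarray(kernels, dtype=x.data.dtype)
    nk = kernels.shape[0]
    n, c, h, w = x.data.shape
    if h < 3 or w < 3:
        raise ValueError("input smaller than the 3x3 kernels")
    xp = _reflect_pad1(x.data)
    cols, ho, wo = _im2col(xp, 3, 1, 1)  # N, C*9, P
    cols4 = cols.reshape(n, c, 9, ho * wo)
    kmat = kernels.reshape(nk, 9)
    out = np.matmul(kmat[None, None], cols4)  # N, C, K, P
    out = out.reshape(n, c * nk, h, w)

    def backward(g):
        if not x.requires_grad:
            return
        g4 = g.reshape(n, c, nk, h * w)
        dcols = np.matmul(kmat.T[None, None], g4).reshape(n, c * 9, h * w)
        dxp = _col2im(dcols, xp.shape, 3, 1, 1, ho, wo)
        x._accumulate(_reflect_pad1_adjoint(dxp))

    return Tensor(out, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# pointwise / structural ops
# ---------------------------------------------------------------------------


def relu(x):
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out, parents=(x,), backward=backward)


def add(a, b):
    if a.data.shape != b.data.shape:
        raise ValueError("add requires equal shapes")
    out = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return Tensor(out, parents=(a, b), backward=backward)


def concat(tensors):
    """Depth-wise (channel-axis) concatenation."""
    out = np.concatenate([t.data for t in tensors], axis=1)
    splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]

    def backward(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=1)):
            if t.requires_grad:
                t._accumulate(gpart)

    return Tensor(out, parents=tuple(tensors), backward=backward)


def batch_norm(x, gamma, beta, running_mean, running_var, training, momentum=0.1, eps=1e-5):
    """Batch normalization over (N, H, W) per channel.

    running_mean / running_var are plain ndarrays updated in place when
    training; they are buffers, not trainable parameters.
    """
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean = running_mean.astype(x.data.dtype)
        var = running_var.astype(x.data.dtype)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data[None, :, None, None] * inv[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                gm = g.mean(axis=(0, 2, 3))[None, :, None, None]
                gxm = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                dx = gi * (g - gm - xhat * gxm)
            else:
                dx = gi * g
            x._accumulate(dx)

    return Tensor(out, parents=(x, gamma, beta), backward=backward)


def channel_softmax(x):
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * p).sum(axis=1, keepdims=True)
            x._accumulate(p * (g - dot))

    return Tensor(p, parents=(x,), backward=backward)
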