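"""Layer modules built on the autodiff ops.

Modules own Parameters (trainable) and buffers (frozen kernels, batch-norm
running statistics). Initialization is He-uniform for convolution weights;
an RNG is threaded through construction so builds are reproducible on demand.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter


class Module:
    def __init__(self):
        self._params = {}
        self._buffers = {}
        self._children = {}

    def add_param(self, name, array):
        p = Parameter(np.asarray(array, dtype=ad.DTYPE), name=name)
        self._params[name] = p
        return p

    def add_buffer(self, name, array):
        self._buffers[name] = np.asarray(array, dtype=np.float64)
        return self._buffers[name]

    def add_child(self, name, module):
        self._children[name] = module
        return module

    def parameters(self, prefix=""):
        """Yield (qualified_name, Parameter) for all trainable parameters."""
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for cname, child in self._children.items():
            yield from child.parameters(prefix=f"{prefix}{cname}.")

    def buffers(self, prefix=""):
        for name, b in self._buffers.items():
            yield f"{prefix}{name}", b
        for cname, child in self._children.items():
            yield from child.buffers(prefix=f"{prefix}{cname}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_uniform(rng, shape, fan_in):
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    """SAME-padded convolution; `is_conv_weight` marks it for L2 decay."""

    def __init__(self, rng, cin, cout, k=3, stride=1, dilation=1, bias=True):
        super().__init__()
        fan_in = cin * k * k
        self.weight = self.add_param("weight", _he_uniform(rng, (cout, cin, k, k), fan_in))
        self.weight.is_conv_weight = True
        self.bias = self.add_param("bias", np.zeros(cout)) if bias else None
        self.stride, self.dilation = stride, dilation

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.dilation)


class ConvTranspose2d(Module):
    """Kernel-4 stride-2 transposed convolution (exact x2 upsampling)."""

    def __init__(self, rng, cin, cout):
        super().__init__()
        fan_in = cin * 16
        self.weight = self.add_param("weight", _he_uniform(rng, (cin, cout, 4, 4), fan_in))
        self.weight.is_conv_weight = True
        self.bias = self.add_param("bias", np.zeros(cout))

    def forward(self, x):
        return ad.conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(c))
        self.beta = self.add_param("beta", np.zeros(c))
        self.running_mean = self.add_buffer("running_mean", np.zeros(c))
        self.running_var = self.add_buffer("running_var", np.ones(c))
        self.momentum, self.eps = momentum, eps
        self.training = True

    def forward(self, x):
        return ad.batch_norm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class ConvBNReLU(Module):
    def __init__(self, rng, cin, cout, k=3, stride=1, dilation=1):
        super().__init__()
        self.conv = self.add_child("conv", Conv2d(rng, cin, cout, k, stride, dilation, bias=False))
        self.bn = self.add_child("bn", BatchNorm2d(cout))

    def forward(self, x):
        return ad.relu(self.bn(self.conv(x)))


class LightSkipPath(Module):
    """1x1 convolution + batch norm projecting encoder features for fusion."""

    def __init__(self, rng, cin, cout):
        super().__init__()
        self.conv = self.add_child("conv", Conv2d(rng, cin, cout, k=1, bias=False))
        self.bn = self.add_child("bn", BatchNorm2d(cout))

    def forward(self, x):
        return self.bn(self.conv(x))


class FrozenFilterUnit(Module):
    """Point-wise conv -> ReLU -> frozen filter bank (MFFL). The bank kernels
    live in a buffer and never receive gradients."""

    def __init__(self, rng, cin, width, bank_kernels):
        super().__init__()
        self.pw = self.add_child("pw", Conv2d(rng, cin, width, k=1, bias=True))
        self.kernels = self.add_buffer("mffl_kernels", bank_kernels)

    def forward(self, x):
        return ad.depthwise_frozen_conv(ad.relu(self.pw(x)), self.kernels)
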