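"""Standard layers built on the autodiff primitives.

Convolutions and linear layers participate in complexity profiling: when a
:class:`~starma.complexity.Profiler` is active they report their parameter and
multiply-accumulate counts, and may skip the actual arithmetic (shape-only
forward) since the counting convention depends only on tensor shapes.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Tensor
from .module import Module, Parameter, trunc_normal

# Set by complexity.Profiler while tracing a model; layers report into it.
_ACTIVE_PROFILER = None


def _profiler():
    return _ACTIVE_PROFILER


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel, stride=1, padding=0,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 init: str = "trunc_normal"):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel = (kh, kw)
        self.stride = (stride, stride) if isinstance(stride, int) else tuple(stride)
        self.padding = (padding, padding) if isinstance(padding, int) else tuple(padding)
        shape = (out_ch, in_ch, kh, kw)
        if init == "zeros":
            w = np.zeros(shape, dtype=np.float32)
        else:
            w = trunc_normal(rng or np.random.default_rng(0), shape)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        prof = _profiler()
        if prof is not None:
            (kh, kw), (sh, sw), (ph, pw) = self.kernel, self.stride, self.padding
            b, c, h, w = x.shape
            ho = (h + 2 * ph - kh) // sh + 1
            wo = (w + 2 * pw - kw) // sw + 1
            n_par = self.weight.data.size + (self.bias.data.size if self.bias is not None else 0)
            # scale by the local batch: channel groups are folded into the batch
            # axis, so a conv inside the attention block runs G times per input
            macs = self.out_ch * self.in_ch * kh * kw * ho * wo * b
            prof.record(self, "conv", n_par, macs)
            if prof.shapes_only:
                return Tensor(np.zeros((b, self.out_ch, ho, wo), dtype=x.dtype))
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, init: str = "trunc_normal"):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        shape = (in_features, out_features)
        if init == "zeros":
            w = np.zeros(shape, dtype=np.float32)
        else:
            w = trunc_normal(rng or np.random.default_rng(0), shape)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        prof = _profiler()
        if prof is not None:
            n_par = self.weight.data.size + (self.bias.data.size if self.bias is not None else 0)
            batch = int(np.prod(x.shape[:-1]))
            prof.record(self, "linear", n_par, self.in_features * self.out_features * batch)
            if prof.shapes_only:
                return Tensor(np.zeros(x.shape[:-1] + (self.out_features,), dtype=x.dtype))
        out = F.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel, with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        c = self.num_features
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
            self._set_buffer("running_mean", (1 - self.momentum) * self.running_mean
                             + self.momentum * mu.data.reshape(c))
            self._set_buffer("running_var", (1 - self.momentum) * self.running_var
                             + self.momentum * unbiased)
            inv = F.power(var + self.eps, -0.5)
            xn = xc * inv
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, c, 1, 1)
            xn = (x - mu) * inv
        return xn * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class GroupNorm(Module):
    """Group normalization; ``groups == channels`` gives per-channel spatial norm."""

    def __init__(self, groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        if num_channels % groups:
            raise ValueError(f"channels {num_channels} not divisible by groups {groups}")
        self.groups = groups
        self.num_channels = num_channels
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        g = self.groups
        xg = x.reshape((b, g, c // g, h, w))
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        xn = (xc * F.power(var + self.eps, -0.5)).reshape((b, c, h, w))
        return xn * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.gelu(x)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x: Tensor) -> Tensor:
        prof = _profiler()
        if prof is not None and prof.shapes_only:
            b, c, h, w = x.shape
            ho = (h + 2 * self.padding - self.kernel) // self.stride + 1
            wo = (w + 2 * self.padding - self.kernel) // self.stride + 1
            return Tensor(np.zeros((b, c, ho, wo), dtype=x.dtype))
        return F.maxpool2d(x, self.kernel, self.stride, self.padding)


class DropPath(Module):
    """Stochastic depth: zero a whole sample's branch with probability `rate`.

    At rate 0 (the experimental setting) this is the identity.  In a residual
    block the branch it wraps is dropped; applied to a non-residual block it
    zeroes the whole feature map of the dropped samples, which is documented
    behaviour and harmless at rate 0.
    """

    def __init__(self, rate: float = 0.0):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"drop-path rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self.forced_mask: np.ndarray | None = None  # test hook

    def forward(self, x: Tensor) -> Tensor:
        if self.forced_mask is not None:
            mask = self.forced_mask.reshape((-1,) + (1,) * (x.ndim - 1))
            return x * mask.astype(x.dtype)
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random((x.shape[0],) + (1,) * (x.ndim - 1)) < keep)
        return x * (mask.astype(x.dtype) / keep)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
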