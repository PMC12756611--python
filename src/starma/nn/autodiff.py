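"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations that produced
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients into every tensor that requires them.  The op set is
exactly what the attention module and backbone need: broadcast arithmetic,
batched matmul, 2-D convolution / max pooling, axis reductions, reshapes,
concatenation/slicing, the sigmoid/GELU/ReLU/softmax nonlinearities and a fused
softmax cross-entropy.  Gradients of broadcast operations are reduced back to
the operand shape by summing over the broadcast axes.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "add",
    "mul",
    "matmul",
    "conv2d",
    "maxpool2d",
    "sigmoid",
    "gelu",
    "relu",
    "softmax",
    "cross_entropy",
    "concatenate",
    "resize1d",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the context (evaluation / profiling)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    # -- public API -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Reverse-accumulate gradients from this tensor through the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** exponent

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    return Tensor._result(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return Tensor._result(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return Tensor._result(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    ax = axis if axis is None or isinstance(axis, tuple) else (axis,)

    def backward(g):
        if not a.requires_grad:
            return
        if ax is None:
            a._accumulate(np.broadcast_to(g, a.data.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return Tensor._result(out_data, (a,), backward)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(reduce_sum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return Tensor._result(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.transpose(g, inv))

    return Tensor._result(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

    return Tensor._result(out_data, (a,), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._result(out_data, tuple(ts), backward)


def resize1d(a, length: int, axis: int = 2, mode: str = "nearest") -> Tensor:
    """Resize along one axis by nearest-neighbour or linear interpolation."""
    a = _as_tensor(a)
    src = a.data.shape[axis]
    if mode == "nearest":
        idx = np.minimum((np.arange(length) * src) // length, src - 1)
        out_data = np.take(a.data, idx, axis=axis)

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                sl = [slice(None)] * a.data.ndim
                for j, i in enumerate(idx):
                    sl[axis] = i
                    gsl = [slice(None)] * g.ndim
                    gsl[axis] = j
                    full[tuple(sl)] += g[tuple(gsl)]
                a._accumulate(full)

        return Tensor._result(out_data, (a,), backward)
    if mode == "linear":
        # align-corners=False convention
        pos = (np.arange(length) + 0.5) * src / length - 0.5
        pos = np.clip(pos, 0, src - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, src - 1)
        w = (pos - lo).astype(a.data.dtype)
        shape = [1] * a.data.ndim
        shape[axis] = length
        w = w.reshape(shape)
        out_data = np.take(a.data, lo, axis=axis) * (1 - w) + np.take(a.data, hi, axis=axis) * w

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                for j in range(length):
                    gsl = [slice(None)] * g.ndim
                    gsl[axis] = j
                    piece = g[tuple(gsl)]
                    wj = float(np.ravel(w)[j])
                    sl = [slice(None)] * a.data.ndim
                    sl[axis] = lo[j]
                    full[tuple(sl)] += piece * (1 - wj)
                    sl[axis] = hi[j]
                    full[tuple(sl)] += piece * wj
                a._accumulate(full)

        return Tensor._result(out_data, (a,), backward)
    raise ValueError(f"unknown resize mode {mode!r}")


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._result(out_data, (a,), backward)


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a) -> Tensor:
    """Exact (erf) GELU: x * Phi(x)."""
    a = _as_tensor(a)
    x = a.data
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    out_data = x * cdf

    def backward(g):
        if a.requires_grad:
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
            a._accumulate(g * (cdf + x * pdf))

    return Tensor._result(out_data.astype(x.dtype, copy=False), (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor._result(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

    return Tensor._result(out_data, (a,), backward)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of integer class targets."""
    logits = _as_tensor(logits)
    targets = np.asarray(targets)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    nll = -np.log(np.maximum(p[np.arange(n), targets], 1e-30))
    out_data = np.array(nll.mean(), dtype=logits.data.dtype)

    def backward(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[np.arange(n), targets] -= 1.0
            logits._accumulate(grad * (g / n))

    return Tensor._result(out_data, (logits,), backward)


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    b, c, h, w = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * sh, s3 * sw),
        writeable=False,
    )
    cols = np.ascontiguousarray(view).reshape(b, c * kh * kw, ho * wo)
    return cols, ho, wo


def _col2im(cols: np.ndarray, x_shape, kh, kw, sh, sw, ph, pw, ho, wo) -> np.ndarray:
    b, c, h, w = x_shape
    xp = np.zeros((b, c, h + 2 * ph, w + 2 * pw), dtype=cols.dtype)
    cols = cols.reshape(b, c, kh, kw, ho, wo)
    for i in range(kh):
        hi = i + sh * ho
        for j in range(kw):
            wj = j + sw * wo
            xp[:, :, i:hi:sh, j:wj:sw] += cols[:, :, i, j]
    if ph or pw:
        return xp[:, :, ph:ph + h, pw:pw + w]
    return xp


def conv2d(x, weight, bias=None, stride=(1, 1), padding=(0, 0)) -> Tensor:
    """2-D cross-correlation with `weight` of shape (C_out, C_in, kh, kw)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    bias = _as_tensor(bias) if bias is not None else None
    sh, sw = stride
    ph, pw = padding
    co, ci, kh, kw = weight.data.shape
    cols, ho, wo = _im2col(x.data, kh, kw, sh, sw, ph, pw)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out = np.einsum("of,bfp->bop", wmat, cols, optimize=True)
    b = x.data.shape[0]
    out = out.reshape(b, co, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1)

    def backward(g):
        gmat = g.reshape(b, co, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.einsum("bop,bfp->of", gmat, cols, optimize=True)
            weight._accumulate(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = np.einsum("of,bop->bfp", wmat, gmat, optimize=True)
            gx = _col2im(gcols, x.data.shape, kh, kw, sh, sw, ph, pw, ho, wo)
            x._accumulate(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._result(out, parents, backward)


def maxpool2d(x, kernel: int = 2, stride: int | None = None, padding: int = 0) -> Tensor:
    """Max pooling; spatial output sizes use floor division."""
    x = _as_tensor(x)
    stride = stride or kernel
    b, c, h, w = x.data.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    hp, wp = xd.shape[2], xd.shape[3]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    s0, s1, s2, s3 = xd.strides
    view = np.lib.stride_tricks.as_strided(
        xd,
        shape=(b, c, ho, wo, kernel, kernel),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    windows = view.reshape(b, c, ho, wo, kernel * kernel)
    arg = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gcols = np.zeros((b, c, ho, wo, kernel * kernel), dtype=g.dtype)
        np.put_along_axis(gcols, arg[..., None], g[..., None], axis=-1)
        gcols = gcols.reshape(b, c, ho, wo, kernel, kernel)
        gx = np.zeros((b, c, hp, wp), dtype=g.dtype)
        for i in range(kernel):
            for j in range(kernel):
                gx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += gcols[..., i, j]
        if padding:
            gx = gx[:, :, padding:padding + h, padding:padding + w]
        x._accumulate(gx)

    return Tensor._result(np.ascontiguousarray(out), (x,), backward)
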