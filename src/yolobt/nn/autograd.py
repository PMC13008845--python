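"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The detector stack in this package is trained on CPU; this module provides
the small set of differentiable tensor operations the network needs
(convolution via im2col, pooling, broadcasting arithmetic, activations,
softmax, binary cross-entropy with logits, batched matmul).

A global multiply-accumulate counter can be armed with :func:`count_macs`;
while armed, ``conv2d`` / ``matmul`` record their MAC counts, which is how
the architecture profiler measures forward-pass compute.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "softmax",
    "bce_with_logits",
    "count_macs",
    "no_grad",
]

# ---------------------------------------------------------------------------
# MAC counting / grad-enabled state
# ---------------------------------------------------------------------------

_MAC_COUNTER: list[int] | None = None
_GRAD_ENABLED: bool = True


@contextlib.contextmanager
def count_macs():
    """Context manager yielding a one-element list accumulating MACs."""
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    _MAC_COUNTER = counter = [0]
    try:
        yield counter
    finally:
        _MAC_COUNTER = prev


def _add_macs(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER[0] += int(n)


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an attached backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (),
                 backward=None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = backward
        self._parents = parents if self.requires_grad else ()

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- autograd -----------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
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

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, pow_(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), pow_(self, -1.0))

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- shaping ------------------------------------------------------------
    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int)
                       else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def max(self, axis=None, keepdims=False):
        return max_(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32))


def tensor(data, requires_grad: bool = False, dtype=np.float32) -> Tensor:
    return Tensor(np.asarray(data, dtype=dtype), requires_grad=requires_grad)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if not req:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=tuple(parents), backward=backward)


# ---------------------------------------------------------------------------
# Elementwise ops
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    if isinstance(a, Tensor) and isinstance(b, (int, float)):
        s = float(b)
        out_data = a.data + s

        def backward_s(g):
            a._accumulate(g)

        return _make(out_data, (a,), backward_s)
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    if isinstance(a, Tensor) and isinstance(b, (int, float)):
        s = float(b)
        out_data = a.data * s

        def backward_s(g):
            a._accumulate(g * s)

        return _make(out_data, (a,), backward_s)
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def pow_(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return pow_(a, 0.5)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(out_data, (a,), backward)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    # clipping at +-80 avoids overflow (exp(80) < float32 max) without
    # changing the result at float precision
    z = np.exp(np.clip(x, -80.0, 80.0) if x.dtype == np.float32
               else np.clip(x, -700.0, 700.0))
    return z / (1.0 + z)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = _stable_sigmoid(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def silu(a) -> Tensor:
    a = _as_tensor(a)
    s = _stable_sigmoid(a.data)
    out_data = a.data * s

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (s + a.data * s * (1.0 - s)))

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


def atan(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.arctan(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / (1.0 + a.data ** 2))

    return _make(out_data, (a,), backward)


def clip(a, lo: float | None, hi: float | None) -> Tensor:
    a = _as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask = mask * (a.data >= lo)
    if hi is not None:
        mask = mask * (a.data <= hi)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


def maximum(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    mask = a.data >= b.data
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (~mask), b.shape))

    return _make(out_data, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    mask = a.data <= b.data
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (~mask), b.shape))

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# Reductions & shaping
# ---------------------------------------------------------------------------


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy()
                          if np.ndim(g) else np.full(a.shape, g, dtype=a.dtype))
            return
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        if not keepdims:
            g = np.expand_dims(g, tuple(ax % a.ndim for ax in axes))
        a._accumulate(np.broadcast_to(g, a.shape).astype(a.dtype))

    return _make(out_data, (a,), backward)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(sum_(a, axis, keepdims), 1.0 / n)


def max_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            full = out_data
            gg = g
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            full = a.data.max(axis=axis, keepdims=True)
            gg = g if keepdims else np.expand_dims(
                g, tuple(ax % a.ndim for ax in axes))
        mask = (a.data == full)
        counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
        a._accumulate(mask * (gg / counts))

    return _make(out_data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    shape = tuple(shape)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    out_data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

    return _make(np.ascontiguousarray(out_data), (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, ts, backward)


# ---------------------------------------------------------------------------
# Linear algebra
# ---------------------------------------------------------------------------


def matmul(a, b) -> Tensor:
    """Matrix product supporting 2-D and batched (3-D) operands."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.matmul(a.data, b.data)
    # MACs: product of output elements and inner dimension
    _add_macs(out_data.size * a.shape[-1])

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# Convolution / pooling
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            ph: int, pw: int) -> tuple[np.ndarray, int, int]:
    b, c, h, w = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - kh) // sh + 1
    ow = (wp - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(b, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * sh, s3 * sw), writeable=False)
    cols = np.ascontiguousarray(windows).reshape(b, c * kh * kw, oh * ow)
    return cols, oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int | tuple[int, int] = 1,
           padding: int | tuple[int, int] = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (OC, IC, KH, KW)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    b, c, h, w = x.shape
    oc, ic, kh, kw = weight.shape
    if ic != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ic}")
    if kh == kw == 1 and sh == sw == 1 and ph == pw == 0:
        return _conv1x1(x, weight, bias)
    cols, oh, ow = _im2col(x.data, kh, kw, sh, sw, ph, pw)
    wmat = weight.data.reshape(oc, ic * kh * kw)
    out = np.matmul(wmat[None], cols)  # (B, OC, OH*OW)
    _add_macs(out.size * ic * kh * kw // 1)
    out = out.reshape(b, oc, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, oc, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.reshape(b, oc, oh * ow)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T[None], gmat)  # (B, C*KH*KW, OH*OW)
            gcols = gcols.reshape(b, c, kh, kw, oh, ow)
            hp, wp = h + 2 * ph, w + 2 * pw
            gx = np.zeros((b, c, hp, wp), dtype=x.dtype)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += gcols[:, :, i, j]
            if ph or pw:
                gx = gx[:, :, ph:hp - ph if ph else hp, pw:wp - pw if pw else wp]
            x._accumulate(gx)

    return _make(out, parents, backward)


def _conv1x1(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Pointwise convolution as a plain matmul (no im2col copies)."""
    b, c, h, w = x.shape
    oc = weight.shape[0]
    xm = x.data.reshape(b, c, h * w)
    wmat = weight.data.reshape(oc, c)
    out = np.matmul(wmat[None], xm)
    _add_macs(out.size * c)
    out = out.reshape(b, oc, h, w)
    if bias is not None:
        out += bias.data.reshape(1, oc, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.reshape(b, oc, h * w)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.matmul(gmat, xm.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            gx = np.matmul(wmat.T[None], gmat)
            x._accumulate(gx.reshape(x.shape))

    return _make(out, parents, backward)


def batch_norm_train(x: Tensor, weight: Tensor, bias: Tensor,
                     eps: float = 1e-3) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch normalization over (0, 2, 3).

    Returns (output, batch_mean, batch_var) — the statistics as plain arrays
    for running-average updates.
    """
    b, c, h, w = x.shape
    xd = x.data
    mu = xd.mean(axis=(0, 2, 3))
    xc = xd - mu.reshape(1, c, 1, 1)
    var = np.mean(xc * xc, axis=(0, 2, 3))
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv.reshape(1, c, 1, 1)
    _add_macs(xd.size)  # scale-and-shift
    out = xhat * weight.data.reshape(1, c, 1, 1) + bias.data.reshape(1, c, 1, 1)
    n = b * h * w

    def backward(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            weight._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gh = g * weight.data.reshape(1, c, 1, 1)
            s1 = gh.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            s2 = (gh * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            gx = (gh - s1 / n - xhat * s2 / n) * inv.reshape(1, c, 1, 1)
            x._accumulate(gx)

    return _make(out, (x, weight, bias), backward), mu, var


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    x = _as_tensor(x)
    b, c, h, w = x.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    hp, wp = xd.shape[2], xd.shape[3]
    oh = (hp - kernel) // stride + 1
    ow = (wp - kernel) // stride + 1
    s0, s1, s2, s3 = xd.strides
    win = np.lib.stride_tricks.as_strided(
        xd, shape=(b, c, oh, ow, kernel, kernel),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3), writeable=False)
    flat = win.reshape(b, c, oh, ow, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros((b, c, hp, wp), dtype=x.dtype)
        ki, kj = np.unravel_index(arg, (kernel, kernel))
        bi, ci, oi, oj = np.indices(arg.shape, sparse=False)
        np.add.at(gx, (bi, ci, oi * stride + ki, oj * stride + kj), g)
        if padding:
            gx = gx[:, :, padding:hp - padding, padding:wp - padding]
        x._accumulate(gx)

    return _make(np.ascontiguousarray(out), (x,), backward)


# ---------------------------------------------------------------------------
# Composite helpers (built from primitives; gradients come for free)
# ---------------------------------------------------------------------------


def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    """Average pooling by an integer factor (kernel == stride == factor)."""
    b, c, h, w = x.shape
    if h % factor or w % factor:
        raise ValueError(f"avg_pool2d: {h}x{w} not divisible by {factor}")
    y = reshape(x, (b, c, h // factor, factor, w // factor, factor))
    return mean(y, axis=(3, 5))


def upsample_nearest2d(x: Tensor, factor: int) -> Tensor:
    b, c, h, w = x.shape
    y = reshape(x, (b, c, h, 1, w, 1))
    ones = np.ones((1, 1, 1, factor, 1, factor), dtype=x.dtype)
    y = mul(y, ones)
    return reshape(y, (b, c, h * factor, w * factor))


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Depth-to-space: out[c, h*r+i, w*r+j] = in[c*r^2 + i*r + j, h, w]."""
    b, c, h, w = x.shape
    if c % (r * r):
        raise ValueError(f"pixel_shuffle: {c} channels not divisible by r^2={r * r}")
    co = c // (r * r)
    y = reshape(x, (b, co, r, r, h, w))
    y = transpose(y, (0, 1, 4, 2, 5, 3))  # (B, Co, H, r_i, W, r_j)
    return reshape(y, (b, co, h * r, w * r))


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C) channel means."""
    return mean(x, axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    return max_(x, axis=(2, 3))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            inner = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - inner))

    return _make(s, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    reduction: str = "mean",
                    pos_weight: float | None = None) -> Tensor:
    """Numerically stable binary cross-entropy on logits; targets are constants.

    ``pos_weight`` scales the positive-class term (PyTorch convention):
    l = -[pw * t * log s(x) + (1 - t) * log(1 - s(x))].
    """
    logits = _as_tensor(logits)
    t = np.asarray(targets, dtype=logits.dtype)
    z = logits.data
    if pos_weight is None:
        loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    else:
        log_s = -np.logaddexp(0.0, -z)       # log sigmoid(z)
        log_1ms = -z + log_s                 # log(1 - sigmoid(z))
        loss = -(pos_weight * t * log_s + (1.0 - t) * log_1ms)
    if reduction == "mean":
        out_data = np.asarray(loss.mean(), dtype=logits.dtype)
    elif reduction == "sum":
        out_data = np.asarray(loss.sum(), dtype=logits.dtype)
    else:
        out_data = loss

    def backward(g):
        if not logits.requires_grad:
            return
        sig = _stable_sigmoid(z)
        if pos_weight is None:
            gl = sig - t
        else:
            gl = pos_weight * t * (sig - 1.0) + (1.0 - t) * sig
        if reduction == "mean":
            gl = gl * (g / z.size)
        else:
            gl = gl * g
        logits._accumulate(gl)

    return _make(out_data, (logits,), backward)
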