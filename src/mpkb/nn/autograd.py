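"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the segmentation network and its losses
need: broadcasted arithmetic, matmul, 3x3/1x1 convolutions (im2col), 2x2
average pooling, nearest-neighbour x2 upsampling, channel concatenation,
pointwise nonlinearities and reductions.  Gradients are accumulated through
a topologically sorted tape; every op is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents) if self.requires_grad else ()
        self._backward = None

    # -- introspection ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        g = np.asarray(g, dtype=self.data.dtype)
        self.grad = g if self.grad is None else self.grad + g

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other, self))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_wrap(other, self), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other, self), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, _wrap(other, self))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _wrap(other, self))

    def __rtruediv__(self, other):
        return div(_wrap(other, self), self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, _wrap(other, self))


def _wrap(x, like: "Tensor | None" = None) -> Tensor:
    """Wrap a scalar/array as a constant Tensor, matching ``like``'s dtype for
    python scalars so float32 graphs are not promoted to float64."""
    if isinstance(x, Tensor):
        return x
    if like is not None and np.isscalar(x):
        return Tensor(np.asarray(x, dtype=like.data.dtype))
    return Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / linear algebra

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = bw
    return out


def mul(a: Tensor, b) -> Tensor:
    b = _wrap(b, a)
    out = Tensor(a.data * b.data, _parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    out._backward = bw
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, _parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    out._backward = bw
    return out


def power(a: Tensor, exponent: float) -> Tensor:
    out = Tensor(a.data ** exponent, _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * exponent * a.data ** (exponent - 1))

    out._backward = bw
    return out


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * out.data)

    out._backward = bw
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0), _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    out._backward = bw
    return out


def sigmoid(a: Tensor) -> Tensor:
    x = a.data
    s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                 np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    out = Tensor(s.astype(x.dtype), _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * out.data * (1.0 - out.data))

    out._backward = bw
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))

    def bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape))
            return
        axes = (axis,) if np.isscalar(axis) else tuple(axis)
        if not keepdims:
            for ax in sorted(ax % a.ndim for ax in axes):
                g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.shape))

    out._backward = bw
    return out


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if np.isscalar(axis) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    out._backward = bw
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# spatial ops on (N, C, H, W)

def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (C*kh*kw, N*Ho*Wo) patch matrix (single copy)."""
    n, c, h, w = xp.shape
    ho, wo = h - kh + 1, w - kw + 1
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (c, kh, kw, n, ho, wo), (s[1], s[2], s[3], s[0], s[2], s[3]))
    return view.reshape(c * kh * kw, n * ho * wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int | None = None) -> Tensor:
    """2D convolution, stride 1, 'same' padding by default.

    Implemented as one large GEMM over an im2col patch matrix; the backward
    pass is likewise two GEMMs plus a kh*kw scatter-add.
    """
    n, c, h, wd = x.shape
    f, c2, kh, kw = w.shape
    assert c == c2, f"channel mismatch: {c} vs {c2}"
    if pad is None:
        pad = kh // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _im2col(xp, kh, kw)                       # (C*kh*kw, N*Ho*Wo)
    ho, wo = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1
    wf = w.data.reshape(f, -1)
    out_flat = wf @ cols + b.data[:, None]           # (F, N*Ho*Wo)
    out = Tensor(out_flat.reshape(f, n, ho, wo).transpose(1, 0, 2, 3),
                 _parents=(x, w, b))

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(f, n * ho * wo)
        if b.requires_grad:
            b._accumulate(g2.sum(axis=1))
        if w.requires_grad:
            w._accumulate((g2 @ cols.T).reshape(w.shape))
        if x.requires_grad:
            dcols = (wf.T @ g2).reshape(c, kh, kw, n, ho, wo)
            dxp = np.zeros((c, n, h + 2 * pad, wd + 2 * pad), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho, j:j + wo] += dcols[:, i, j]
            dxp = dxp.transpose(1, 0, 2, 3)
            x._accumulate(dxp[:, :, pad:pad + h, pad:pad + wd] if pad else dxp)

    out._backward = bw
    return out


def avg_pool2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    assert h % 2 == 0 and w % 2 == 0, f"spatial dims must be even, got {h}x{w}"
    out = Tensor(x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5)),
                 _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25)

    out._backward = bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3),
                 _parents=(x,))

    def bw(g):
        if x.requires_grad:
            n, c, h, w = x.shape
            x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    n, c, h, w = x.shape
    return reshape(tmean(x, axis=(2, 3)), (n, c))


def expand_spatial(z: Tensor, h: int, w: int) -> Tensor:
    """(N, D) -> (N, D, h, w) by broadcasting; gradient sums over space."""
    n, d = z.shape
    out = Tensor(np.broadcast_to(z.data[:, :, None, None], (n, d, h, w)).copy(),
                 _parents=(z,))

    def bw(g):
        if z.requires_grad:
            z._accumulate(g.sum(axis=(2, 3)))

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits (numerically stable)."""
    x, t = logits.data, np.asarray(targets, dtype=logits.data.dtype)
    val = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(np.asarray(val.mean(), dtype=x.dtype), _parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            e = np.exp(-np.abs(x))
            s = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
            logits._accumulate(g * (s - t) / x.size)

    out._backward = bw
    return out
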