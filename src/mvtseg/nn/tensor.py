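"""Compact reverse-mode automatic differentiation over NumPy arrays.

Sized for the small 3-D networks in this package: a ``Tensor`` wraps a
float32 ndarray, records its parents and a backward closure, and
``backward()`` walks the graph in reverse topological order.  Only the
operations the localizer and segmenter actually use are provided.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.float32(np.sqrt(2.0))
_INV_SQRT_2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad = None
        self._prev: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------------
    def _accum(self, g: np.ndarray):
        g = _sum_to_shape(np.asarray(g, dtype=np.float32), self.data.shape)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None else g
        else:
            self.grad += g

    # arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(g)
            if other.requires_grad or other._prev:
                other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(g * other.data)
            if other.requires_grad or other._prev:
                other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(g / other.data)
            if other.requires_grad or other._prev:
                other._accum(-g * self.data / (other.data * other.data))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad or other._prev:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = bw
        return out

    # shape ---------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = _make(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _make(np.ascontiguousarray(self.data.transpose(axes)), (self,))
        out._backward = lambda g: self._accum(g.transpose(tuple(inv)))
        return out

    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def narrow(self, axis: int, start: int, length: int):
        """Slice ``length`` entries from ``start`` along ``axis``."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out = _make(np.ascontiguousarray(self.data[idx]), (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        out._backward = bw
        return out


def _make(data: np.ndarray, prev: tuple) -> Tensor:
    out = Tensor(data)
    out._prev = tuple(p for p in prev if isinstance(p, Tensor))
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error linear unit, 0.5·x·(1+erf(x/√2))."""
    xd = x.data
    cdf = 0.5 * (1.0 + erf(xd / _SQRT2)).astype(np.float32)
    out = _make(xd * cdf, (x,))

    def bw(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * xd * xd)
        x._accum(g * (cdf + xd * pdf))

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-x.data)),
                 np.exp(x.data) / (1.0 + np.exp(x.data))).astype(np.float32)
    out = _make(s, (x,))
    out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def softplus(x: Tensor) -> Tensor:
    xd = x.data
    sp = (np.maximum(xd, 0.0) + np.log1p(np.exp(-np.abs(xd)))).astype(np.float32)
    out = _make(sp, (x,))

    def bw(g):
        s = np.where(xd >= 0, 1.0 / (1.0 + np.exp(-xd)),
                     np.exp(xd) / (1.0 + np.exp(xd)))
        x._accum(g * s)

    out._backward = bw
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = _make(e, (x,))
    out._backward = lambda g: x._accum(g * e)
    return out


def log(x: Tensor) -> Tensor:
    out = _make(np.log(x.data), (x,))
    out._backward = lambda g: x._accum(g / x.data)
    return out


def sqrt(x: Tensor) -> Tensor:
    """Square root with a zero subgradient at 0 (safe for hinge-like losses)."""
    r = np.sqrt(np.maximum(x.data, 0.0)).astype(np.float32)
    out = _make(r, (x,))

    def bw(g):
        denom = np.where(r > 0, 2.0 * r, 1.0)
        x._accum(np.where(r > 0, g / denom, 0.0))

    out._backward = bw
    return out


def absolute(x: Tensor) -> Tensor:
    out = _make(np.abs(x.data), (x,))
    out._backward = lambda g: x._accum(g * np.sign(x.data))
    return out


def clip_min(x: Tensor, lo: float) -> Tensor:
    """max(x, lo); gradient flows only where x > lo."""
    mask = x.data > lo
    out = _make(np.where(mask, x.data, lo), (x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def concat(tensors, axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out = _make(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accum(g[tuple(idx)])

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)  # constant shift, no grad needed
    e = exp(x - Tensor(m))
    return e / e.sum(axis=axis, keepdims=True)


def axis_matmul(x: Tensor, w: np.ndarray, axis: int) -> Tensor:
    """Apply a fixed linear map ``w`` (in_size × out_size) along ``axis``.

    Used for differentiable separable resampling; ``w`` carries no gradient.
    """
    w = np.asarray(w, dtype=np.float32)
    moved = np.moveaxis(x.data, axis, -1)
    res = moved @ w
    out_data = np.moveaxis(res, -1, axis)
    out = _make(np.ascontiguousarray(out_data), (x,))

    def bw(g):
        gm = np.moveaxis(g, axis, -1)
        gi = gm @ w.T
        x._accum(np.ascontiguousarray(np.moveaxis(gi, -1, axis)))

    out._backward = bw
    return out
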