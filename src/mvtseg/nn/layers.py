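"""Neural-network modules over the autodiff core.

3-D convolutions use gather/scatter index tables (im2col) so the heavy
lifting is BLAS matmuls; index tables are cached per geometry.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, gelu, softmax, _make

# ---------------------------------------------------------------------------
# index tables
# ---------------------------------------------------------------------------

_IDX_CACHE: dict = {}


def conv_output_shape(spatial, k, stride, pad):
    return tuple((d + 2 * pad - k) // stride + 1 for d in spatial)


def im2col_indices(spatial, k, stride, pad, channels):
    """Flat gather indices (L, channels*k^3) into a zero-padded (C, Xp, Yp, Zp) grid."""
    key = (tuple(spatial), k, stride, pad, channels)
    hit = _IDX_CACHE.get(key)
    if hit is not None:
        return hit
    X, Y, Z = spatial
    Xp, Yp, Zp = X + 2 * pad, Y + 2 * pad, Z + 2 * pad
    out = conv_output_shape(spatial, k, stride, pad)
    ox = np.arange(out[0]) * stride
    oy = np.arange(out[1]) * stride
    oz = np.arange(out[2]) * stride
    base = (ox[:, None, None] * (Yp * Zp) + oy[None, :, None] * Zp
            + oz[None, None, :]).ravel()
    dx, dy, dz = np.meshgrid(np.arange(k), np.arange(k), np.arange(k), indexing="ij")
    off = (dx * (Yp * Zp) + dy * Zp + dz).ravel()
    sp_idx = base[:, None] + off[None, :]                      # (L, k3)
    span = Xp * Yp * Zp
    full = (sp_idx[:, None, :] + (np.arange(channels) * span)[None, :, None])
    full = np.ascontiguousarray(full.reshape(sp_idx.shape[0], channels * k ** 3))
    entry = (full, sp_idx, (Xp, Yp, Zp), out)
    _IDX_CACHE[key] = entry
    return entry


def _pad_spatial(x, pad):
    if pad == 0:
        return x
    out = np.zeros(x.shape[:2] + tuple(d + 2 * pad for d in x.shape[2:]),
                   dtype=x.dtype)
    out[:, :, pad:-pad, pad:-pad, pad:-pad] = x
    return out


def _unpad_spatial(x, pad):
    if pad == 0:
        return x
    return x[:, :, pad:-pad, pad:-pad, pad:-pad]


# ---------------------------------------------------------------------------
# module base
# ---------------------------------------------------------------------------

class Module:
    def forward(self, *a, **kw):
        raise NotImplementedError

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield path, val
            elif isinstance(val, Module):
                yield from val.named_parameters(path + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()


def param(array) -> Tensor:
    return Tensor(array, requires_grad=True)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Linear(Module):
    def __init__(self, d_in, d_out, rng):
        scale = np.sqrt(1.0 / d_in)
        self.w = param(rng.uniform(-scale, scale, size=(d_in, d_out)))
        self.b = param(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        self.g = param(np.ones(dim))
        self.b = param(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        from .tensor import sqrt as t_sqrt
        return xc / t_sqrt(var + self.eps) * self.g + self.b


def _offset_slices(k, stride, out_sp):
    """Strided slice tuples into a padded grid, one per kernel offset."""
    slices = []
    for i in range(k):
        for j in range(k):
            for l in range(k):
                slices.append((i, j, l, tuple(
                    slice(o, o + stride * n, stride)
                    for o, n in zip((i, j, l), out_sp))))
    return slices


class Conv3d(Module):
    """3-D convolution, weight (Cout, Cin, k, k, k), stride s, zero padding p.

    Computed as a sum over kernel offsets of strided-slice GEMMs, which
    keeps the work in BLAS without large gather buffers.
    """

    def __init__(self, c_in, c_out, k, stride=1, pad=None, rng=None):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        fan = c_in * k ** 3
        scale = np.sqrt(1.0 / fan)
        self.w = param(rng.uniform(-scale, scale, size=(c_out, c_in, k, k, k)))
        self.b = param(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        N, C = x.shape[:2]
        spatial = x.shape[2:]
        out_sp = conv_output_shape(spatial, self.k, self.stride, self.pad)
        L = int(np.prod(out_sp))
        xp = _pad_spatial(x.data, self.pad)
        offs = _offset_slices(self.k, self.stride, out_sp)
        views = []
        y = np.zeros((N, self.c_out, L), dtype=np.float32)
        for i, j, l, sl in offs:
            v = np.ascontiguousarray(
                xp[(slice(None), slice(None)) + sl]).reshape(N, C, L)
            views.append(v)
            y += self.w.data[:, :, i, j, l] @ v
        y += self.b.data[None, :, None]
        out = _make(y.reshape(N, self.c_out, *out_sp), (x, self.w, self.b))
        w_t, b_t = self.w, self.b

        def bw(g):
            g2 = g.reshape(N, self.c_out, L)
            b_t._accum(g2.sum(axis=(0, 2)))
            dw = np.empty_like(w_t.data)
            need_dx = x.requires_grad or x._prev
            dxp = np.zeros_like(xp) if need_dx else None
            gT = np.ascontiguousarray(g2.transpose(0, 2, 1))    # (N, L, Cout)
            for (i, j, l, sl), v in zip(offs, views):
                # (Cout, L) x (L, C) summed over batch
                dw[:, :, i, j, l] = np.einsum("nol,ncl->oc", g2, v, optimize=True)
                if need_dx:
                    dxp[(slice(None), slice(None)) + sl] += (
                        w_t.data[:, :, i, j, l].T @ g2).reshape(N, C, *out_sp)
            w_t._accum(dw)
            if need_dx:
                x._accum(_unpad_spatial(dxp, self.pad))

        out._backward = bw
        return out


class ConvTranspose3d(Module):
    """Transposed 3-D convolution; output spatial = (in-1)*stride - 2*pad + k.

    Adjoint of ``Conv3d``: scatter-adds strided slices of the padded
    output, weight layout (Cin, Cout, k, k, k).
    """

    def __init__(self, c_in, c_out, k, stride=2, pad=1, rng=None):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride, self.pad = stride, pad
        fan = c_in * k ** 3
        scale = np.sqrt(1.0 / fan)
        self.w = param(rng.uniform(-scale, scale, size=(c_in, c_out, k, k, k)))
        self.b = param(np.zeros(c_out))

    def out_shape(self, spatial):
        return tuple((d - 1) * self.stride - 2 * self.pad + self.k for d in spatial)

    def forward(self, x: Tensor) -> Tensor:
        N, C = x.shape[:2]
        in_sp = x.shape[2:]
        out_sp = self.out_shape(in_sp)
        chk = conv_output_shape(out_sp, self.k, self.stride, self.pad)
        if chk != tuple(in_sp):
            raise ValueError("inconsistent transposed-conv geometry")
        L = int(np.prod(in_sp))
        xf = x.data.reshape(N, C, L)
        padded = tuple(d + 2 * self.pad for d in out_sp)
        yp = np.zeros((N, self.c_out) + padded, dtype=np.float32)
        offs = _offset_slices(self.k, self.stride, in_sp)
        for i, j, l, sl in offs:
            yp[(slice(None), slice(None)) + sl] += (
                self.w.data[:, :, i, j, l].T @ xf).reshape(N, self.c_out, *in_sp)
        y = np.ascontiguousarray(_unpad_spatial(yp, self.pad))
        y += self.b.data[None, :, None, None, None]
        out = _make(y, (x, self.w, self.b))
        w_t, b_t = self.w, self.b

        def bw(g):
            gp = _pad_spatial(g, self.pad)
            b_t._accum(g.sum(axis=(0, 2, 3, 4)))
            dw = np.empty_like(w_t.data)
            need_dx = x.requires_grad or x._prev
            dxf = np.zeros_like(xf) if need_dx else None
            for i, j, l, sl in offs:
                gv = np.ascontiguousarray(
                    gp[(slice(None), slice(None)) + sl]).reshape(N, self.c_out, L)
                dw[:, :, i, j, l] = np.einsum("ncl,nol->co", xf, gv, optimize=True)
                if need_dx:
                    dxf += w_t.data[:, :, i, j, l] @ gv
            w_t._accum(dw)
            if need_dx:
                x._accum(dxf.reshape(x.data.shape))

        out._backward = bw
        return out


class MultiHeadSelfAttention(Module):
    def __init__(self, dim, heads, rng):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads = dim, heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        N, T, D = x.shape
        H, Dh = self.heads, D // self.heads
        qkv = self.qkv(x)
        q = qkv.narrow(2, 0, D).reshape(N, T, H, Dh).transpose(0, 2, 1, 3)
        k = qkv.narrow(2, D, D).reshape(N, T, H, Dh).transpose(0, 2, 1, 3)
        v = qkv.narrow(2, 2 * D, D).reshape(N, T, H, Dh).transpose(0, 2, 1, 3)
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(Dh)), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(N, T, D)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block (MHSA + MLP, residual)."""

    def __init__(self, dim, heads, mlp_ratio, rng):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(gelu(self.fc1(self.ln2(x))))
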