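"""Learnable 3-D grayscale (non-flat) morphology.

Dilation: ``y(p) = max_q x(p+q) + se(q)``; erosion: ``y(p) = min_q x(p+q)
- se(q)``, with q ranging over a centered k³ window and out-of-bounds
positions excluded from the extremum (−∞/+∞ padding semantics).  The SE
weights are trainable; gradients flow through the arg-extremum
(subgradient), as in deep morphological networks.

``dilate``/``erode`` are the plain NumPy reference API on single 3-D
grids; ``MorphBlock`` is the trainable depthwise layer used inside the
segmenter (dilation and erosion branches concatenated channelwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .nn.layers import Module, im2col_indices, param
from .nn.tensor import Tensor, _make

_NEG = np.float32(-np.inf)


@dataclass
class StructuringElement:
    """k×k×k grid of additive offsets (odd k). ``flat`` marks the all-zero SE."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 3 or len(set(w.shape)) != 1:
            raise ConfigError("structuring element must be cubic (k,k,k)")
        if w.shape[0] % 2 == 0:
            raise ConfigError("structuring element side length must be odd")
        if not np.all(np.isfinite(w)):
            raise ConfigError("structuring element weights must be finite")
        self.weights = w

    @property
    def size(self) -> int:
        return self.weights.shape[0]

    @property
    def flat(self) -> bool:
        return bool(np.all(self.weights == 0))


def _window_vals(x: np.ndarray, k: int) -> np.ndarray:
    """(L, k^3) window view of a −∞-padded copy of ``x`` (stride 1, same size)."""
    pad = k // 2
    _, sp_idx, _, out = im2col_indices(x.shape, k, 1, pad, 1)
    xp = np.full(tuple(d + 2 * pad for d in x.shape), _NEG, dtype=np.float64)
    sl = tuple(slice(pad, pad + d) for d in x.shape)
    xp[sl] = x
    return xp.ravel()[sp_idx], out


def dilate(x: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Grayscale dilation of a 3-D grid by a non-flat SE; same output shape."""
    x = np.asarray(x, dtype=np.float64)
    vals, out = _window_vals(x, se.size)
    y = np.max(vals + se.weights.ravel()[None, :], axis=1)
    return y.reshape(out)


def erode(x: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Grayscale erosion; dual of dilation: erode(x, se) = −dilate(−x, se)."""
    return -dilate(-np.asarray(x, dtype=np.float64), se)


def make_se(size: int, rng: np.random.Generator | None = None,
            init_scale: float = 0.05) -> np.ndarray:
    """Near-identity SE init: small random negatives with se(origin)=0."""
    if size % 2 == 0:
        raise ConfigError("SE size must be odd")
    if rng is None:
        w = np.zeros((size, size, size), dtype=np.float32)
    else:
        w = -np.abs(rng.normal(0.0, init_scale, size=(size, size, size))
                    ).astype(np.float32)
    c = size // 2
    w[c, c, c] = 0.0
    return w


class MorphBlock(Module):
    """Depthwise learnable dilation + erosion, concatenated (2× channels out).

    One dilation SE and one erosion SE per input channel.
    """

    def __init__(self, channels: int, se_size: int = 5,
                 rng: np.random.Generator | None = None):
        if se_size % 2 == 0:
            raise ConfigError("SE size must be odd")
        self.channels = channels
        self.se_size = se_size
        self.se_dil = param(np.stack([make_se(se_size, rng) for _ in range(channels)]))
        self.se_ero = param(np.stack([make_se(se_size, rng) for _ in range(channels)]))

    # ------------------------------------------------------------------
    def _branch(self, x: Tensor, se: Tensor, sign: float) -> Tensor:
        """sign=+1: dilation of x; sign=−1 computes erosion via duality."""
        N, C = x.shape[:2]
        spatial = x.shape[2:]
        if C != self.channels:
            raise ConfigError(f"expected {self.channels} channels, got {C}")
        k = self.se_size
        pad = k // 2
        _, sp_idx, padded, out_sp = im2col_indices(spatial, k, 1, pad, 1)
        L, K = sp_idx.shape
        span = int(np.prod(padded))
        xp = np.full((N, C, span), _NEG, dtype=np.float32)
        sl = tuple(slice(pad, pad + d) for d in spatial)
        xp.reshape(N, C, *padded)[(slice(None), slice(None)) + sl] = sign * x.data
        vals = xp[:, :, sp_idx.ravel()].reshape(N, C, L, K)
        vals += se.data.reshape(1, C, 1, K)
        arg = np.argmax(vals, axis=3)                             # (N, C, L)
        y = np.take_along_axis(vals, arg[..., None], axis=3)[..., 0]
        y = sign * y
        out = _make(np.ascontiguousarray(y.reshape(N, C, *spatial)), (x, se))

        def bw(g):
            gs = (sign * g).reshape(N, C, L)
            onehot = (arg[..., None] == np.arange(K)).astype(np.float32)
            dse = np.einsum("nclk,ncl->ck", onehot, gs).reshape(se.data.shape)
            se._accum(dse)
            if x.requires_grad or x._prev:
                # dy/dx = sign(outer) * sign(inner) = +1 at the selected position
                picked = sp_idx[np.arange(L)[None, None, :], arg]  # (N, C, L)
                dxp = np.zeros(N * C * span, dtype=np.float32)
                flat_idx = (picked + (np.arange(N * C) * span).reshape(N, C, 1)
                            ).ravel()
                np.add.at(dxp, flat_idx, g.reshape(N, C, L).ravel())
                dxp = dxp.reshape(N, C, *padded)
                x._accum(dxp[(slice(None), slice(None)) + sl])

        out._backward = bw
        return out

    def forward(self, x: Tensor) -> Tensor:
        from .nn.tensor import concat
        d = self._branch(x, self.se_dil, +1.0)
        e = self._branch(x, self.se_ero, -1.0)
        return concat([d, e], axis=1)
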