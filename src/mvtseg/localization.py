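"""Hippocampus VOI detection and coordinate bookkeeping.

The localizer builds a multi-scale feature hierarchy with stride-2
convolutions and GeLU, fuses the levels by cubic resampling to a common
size followed by an elementwise sum, and regresses the VOI box
``C = [x_c, y_c, z_c, w_c, h_c, d_c]`` from globally pooled features.
Centers are produced through a sigmoid scaled by the image dimensions
(always inside the volume); extents through softplus + 1 (always ≥ 1).

The training objective is the Euclidean distance between box centers
plus a weighted, dimension-normalized size term
``λ · Σ sqrt(|e² − ê²|) / dim``; λ defaults to 0.5.

Crops are axis-aligned fixed-size windows around a box center with
zero-padding at volume borders; a ``CropRecord`` captures everything
needed to consolidate a cropped segmentation back into the original
frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .errors import (BoxError, ConfigError, DivergenceError, EmptyMaskError,
                     RecordError)
from .nn.tensor import Tensor
from .volume_io import LabelMap, Volume, read_volume


@dataclass
class BoundingBox:
    """Axis-aligned box: continuous voxel-space center and extents (≥ 1)."""

    center: tuple
    extent: tuple

    def __post_init__(self):
        self.center = tuple(float(c) for c in self.center)
        self.extent = tuple(float(e) for e in self.extent)
        if len(self.center) != 3 or len(self.extent) != 3:
            raise BoxError("box needs 3 center and 3 extent components")
        if not all(np.isfinite(self.center)):
            raise BoxError("box center must be finite")
        if any(e < 1 for e in self.extent):
            raise BoxError(f"extents must be >= 1, got {self.extent}")

    def as_array(self):
        return np.array(self.center + self.extent, dtype=np.float64)


@dataclass
class FeatureMap:
    """Channel-first feature grid at hierarchy level ``level``."""

    data: np.ndarray
    level: int


@dataclass
class LocalizerConfig:
    levels: int = 3
    base_channels: int = 16
    lam: float = 0.5            # weight of the size term in the box loss
    head_hidden: int = 32
    head_gain: float = 256.0    # pre-activation gain on the 6 raw outputs
    seed: int = 0

    def __post_init__(self):
        if self.levels < 2:
            raise ConfigError("levels must be >= 2")
        if self.lam < 0:
            raise ConfigError("lambda must be >= 0")


@dataclass
class CropRecord:
    source_shape: tuple
    crop_start: tuple
    crop_stop: tuple
    pad_before: tuple
    pad_after: tuple
    target_shape: tuple


# ---------------------------------------------------------------------------
# ground-truth boxes, cropping, consolidation
# ---------------------------------------------------------------------------

def derive_gt_box(truth: LabelMap, margin: int = 0) -> BoundingBox:
    """Tight box over union foreground, grown by ``margin`` and clipped."""
    fg = truth.data > 0
    if not fg.any():
        raise EmptyMaskError("cannot derive a box from an all-background map")
    lo, hi = [], []
    for ax in range(3):
        proj = fg.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.nonzero(proj)[0]
        lo.append(max(int(idx[0]) - margin, 0))
        hi.append(min(int(idx[-1]) + margin, truth.shape[ax] - 1))
    center = tuple((a + b) / 2.0 for a, b in zip(lo, hi))
    extent = tuple(float(b - a + 1) for a, b in zip(lo, hi))
    return BoundingBox(center, extent)


def crop_to_box(v, box: BoundingBox, target_shape):
    """Fixed-size crop around ``box.center``; border overhang zero-padded.

    Accepts a Volume or LabelMap; returns (same type, CropRecord).
    Window start is floor(center − target/2) per axis.
    """
    target = tuple(int(t) for t in target_shape)
    if any(t < 1 for t in target):
        raise BoxError("target shape components must be >= 1")
    shape = v.shape
    for c, s in zip(box.center, shape):
        if c < 0 or c > s - 1:
            raise BoxError(f"box center {box.center} outside volume {shape}")
    start = tuple(int(np.floor(c - t / 2.0)) for c, t in zip(box.center, target))
    stop = tuple(s + t for s, t in zip(start, target))
    cstart = tuple(max(s, 0) for s in start)
    cstop = tuple(min(e, d) for e, d in zip(stop, shape))
    pad_b = tuple(cs - s for cs, s in zip(cstart, start))
    pad_a = tuple(e - ce for e, ce in zip(stop, cstop))
    out = np.zeros(target, dtype=v.data.dtype)
    dst = tuple(slice(pb, pb + (ce - cs))
                for pb, cs, ce in zip(pad_b, cstart, cstop))
    src = tuple(slice(cs, ce) for cs, ce in zip(cstart, cstop))
    out[dst] = v.data[src]
    rec = CropRecord(tuple(shape), cstart, cstop, pad_b, pad_a, target)
    if isinstance(v, LabelMap):
        cropped = LabelMap(out, v.spacing, v.origin, v.classes)
    else:
        cropped = Volume(out, v.spacing, v.origin)
    return cropped, rec


def consolidate(seg_cropped: LabelMap, rec: CropRecord) -> LabelMap:
    """Place a cropped segmentation back into the original frame (class 0 outside)."""
    if tuple(seg_cropped.shape) != tuple(rec.target_shape):
        raise RecordError(
            f"cropped shape {seg_cropped.shape} != record target {rec.target_shape}")
    inner = seg_cropped.data[tuple(
        slice(pb, t - pa)
        for pb, pa, t in zip(rec.pad_before, rec.pad_after, rec.target_shape))]
    out = np.zeros(rec.source_shape, dtype=seg_cropped.data.dtype)
    out[tuple(slice(a, b) for a, b in zip(rec.crop_start, rec.crop_stop))] = inner
    return LabelMap(out, seg_cropped.spacing, seg_cropped.origin,
                    seg_cropped.classes)


# ---------------------------------------------------------------------------
# cubic resampling (Keys kernel) for multi-scale fusion
# ---------------------------------------------------------------------------

_RESAMPLE_CACHE: dict = {}


def _keys_kernel(s, a=-0.5):
    s = np.abs(s)
    out = np.zeros_like(s)
    m1 = s <= 1
    out[m1] = (a + 2) * s[m1] ** 3 - (a + 3) * s[m1] ** 2 + 1
    m2 = (s > 1) & (s < 2)
    out[m2] = a * s[m2] ** 3 - 5 * a * s[m2] ** 2 + 8 * a * s[m2] - 4 * a
    return out


def cubic_resample_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_in, n_out) cubic-convolution interpolation matrix, center-aligned.

    Rows of the transpose sum to 1, so constants are preserved exactly.
    """
    key = (n_in, n_out)
    if key in _RESAMPLE_CACHE:
        return _RESAMPLE_CACHE[key]
    w = np.zeros((n_in, n_out))
    ratio = n_in / n_out
    for i in range(n_out):
        x = (i + 0.5) * ratio - 0.5
        base = int(np.floor(x))
        for j in range(base - 1, base + 3):
            wt = _keys_kernel(np.array([x - j]))[0]
            jj = min(max(j, 0), n_in - 1)          # clamp at borders
            w[jj, i] += wt
    w = w.astype(np.float32)
    _RESAMPLE_CACHE[key] = w
    return w


def _resample_to(x: Tensor, spatial) -> Tensor:
    for axis, (n_out, n_in) in enumerate(zip(spatial, x.shape[2:])):
        if n_in != n_out:
            x = nn.axis_matmul(x, cubic_resample_matrix(n_in, n_out), axis + 2)
    return x


# ---------------------------------------------------------------------------
# localizer network
# ---------------------------------------------------------------------------

class LocalizerNet(nn.Module):
    """Hierarchical-contextualization localizer.

    Stem: 1³ conv on the intensity plus three normalized coordinate
    channels (global pooling in the head would otherwise discard absolute
    position).  Levels: ``levels`` stride-2 3³ convs at constant width.
    Head: global average pool → FC → GeLU → FC → 6 raw outputs.
    """

    def __init__(self, cfg: LocalizerConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        self.stem = nn.Conv3d(7, c, k=1, stride=1, pad=0, rng=rng)
        self.level_convs = [nn.Conv3d(c, c, k=3, stride=2, pad=1, rng=rng)
                            for _ in range(cfg.levels)]
        self._structured_init()
        self.fc1 = nn.Linear(4 * c, cfg.head_hidden, rng)
        self.fc2 = nn.Linear(cfg.head_hidden, 6, rng)
        self.fc2.w.data[:] = 0.0        # neutral start: midpoint center, unit-ish extents
        self.fc2.b.data[:] = 0.0

    def _structured_init(self):
        """Start the hierarchy at a useful operating point.

        The stem passes its 7 input features through unchanged; the first
        level's channel 0 is initialized as a matched filter for a
        compact bright object — 3³ average of the intensity followed by a
        GeLU threshold at the mid-intensity — so the pooled moments carry
        object position from the first step.  Coordinate channels
        propagate by center taps.  Training refines all of it.
        """
        c = self.cfg.base_channels
        n_pass = min(7, c)
        self.stem.w.data[:] = 0.0
        for i in range(n_pass):
            self.stem.w.data[i, i, 0, 0, 0] = 1.0
        k_gain, theta = 50.0, 0.5
        first = self.level_convs[0]
        first.w.data[0, :] *= 0.1
        first.w.data[0, 0, :, :, :] = k_gain / 27.0
        first.b.data[0] = -k_gain * theta
        for conv in self.level_convs[1:]:
            conv.w.data[0, :] *= 0.1
            conv.w.data[0, 0, :, :, :] = 2.0 / 27.0     # keep smoothing the mask
            conv.b.data[0] = 0.0
        for conv in self.level_convs:
            for i in range(1, n_pass):                  # center-tap pass-through
                conv.w.data[i, i, 1, 1, 1] += 1.0

    # -- feature extraction --------------------------------------------
    @staticmethod
    def _with_coords(x: np.ndarray) -> np.ndarray:
        """Append coordinate and intensity-weighted coordinate channels.

        Channels: [I, gx, gy, gz, I·gx, I·gy, I·gz] with normalized [0,1]
        coordinate ramps.  Global pooling of I·g relative to pooled I
        encodes the intensity centroid, which the box head regresses.
        """
        N, _, X, Y, Z = x.shape
        gx, gy, gz = np.meshgrid(
            np.linspace(0, 1, X, dtype=np.float32),
            np.linspace(0, 1, Y, dtype=np.float32),
            np.linspace(0, 1, Z, dtype=np.float32), indexing="ij")
        g = np.stack([gx, gy, gz])[None]                        # (1,3,X,Y,Z)
        coords = np.broadcast_to(g, (N, 3, X, Y, Z))
        return np.concatenate([x, coords, x * g], axis=1)

    def features(self, x: np.ndarray) -> list:
        """[F_1 ... F_K] for a (N,1,X,Y,Z) batch; F_k has spatial size /2^k."""
        spatial = x.shape[2:]
        if any(d < 2 ** self.cfg.levels for d in spatial):
            raise ConfigError(
                f"volume {spatial} too small for {self.cfg.levels} levels")
        f = self.stem(Tensor(self._with_coords(x)))   # F_0: initial conv, no activation
        feats = []
        for conv in self.level_convs:
            f = nn.gelu(conv(f))
            feats.append(f)
        return feats

    def fuse(self, feats: list) -> Tensor:
        if not feats:
            raise ConfigError("empty feature list")
        chans = {int(f.shape[1]) for f in feats}
        if len(chans) != 1:
            raise ConfigError(f"channel counts differ across levels: {chans}")
        target = feats[0].shape[2:]
        acc = feats[0]
        for f in feats[1:]:
            acc = acc + _resample_to(f, target)
        return acc

    def head_raw(self, fused: Tensor) -> Tensor:
        """GAP of the fused map's zeroth and first spatial moments → FC stack.

        Pooling F alongside F·g (normalized coordinate ramps g) retains
        the first-order position statistics that plain global averaging
        would discard; the FC stack regresses the box from them.
        """
        N, C = fused.shape[:2]
        spatial = fused.shape[2:]
        # centered ramps: the first moments of a homogeneous background
        # vanish, so the pooled statistics carry mostly object signal
        gx, gy, gz = np.meshgrid(*[np.linspace(-0.5, 0.5, s, dtype=np.float32)
                                   for s in spatial], indexing="ij")
        moments = [fused]
        for g in (gx, gy, gz):
            moments.append(fused * Tensor(g[None, None]) * 64.0)
        pooled = nn.concat([m.mean(axis=(2, 3, 4)) for m in moments], axis=1)
        return self.fc2(nn.gelu(self.fc1(pooled)))

    def forward_boxes(self, x: np.ndarray):
        """(centers, extents) Tensors of shape (N,3) for a volume batch."""
        raw = self.head_raw(self.fuse(self.features(x))) * self.cfg.head_gain
        dims = np.asarray(x.shape[2:], dtype=np.float32)
        centers = nn.sigmoid(raw.narrow(1, 0, 3)) * Tensor(dims)
        extents = nn.softplus(raw.narrow(1, 3, 3)) + 1.0
        return centers, extents

    def predict_box(self, v: Volume, normalize: bool = True) -> BoundingBox:
        x = v.data.astype(np.float32)
        if normalize:
            x = _minmax(x)
        c, e = self.forward_boxes(x[None, None])
        return BoundingBox(tuple(c.data[0]), tuple(e.data[0]))


def hierarchical_features(v: Volume, model: LocalizerNet) -> list:
    """Public wrapper: multi-scale features [F_1..F_K] for a single volume."""
    feats = model.features(_minmax(v.data.astype(np.float32))[None, None])
    return [FeatureMap(f.data[0], level=k + 1) for k, f in enumerate(feats)]


def localization_head(fused: FeatureMap, model: "LocalizerNet") -> BoundingBox:
    """Decode a VOI box from a fused feature map with the model's head.

    The fused grid is pooled (zeroth/first moments), passed through the
    FC stack, and mapped to an in-volume center (sigmoid · dims, where
    dims is the full-resolution grid implied by the level) and extents
    ≥ 1 (softplus + 1).
    """
    t = Tensor(fused.data[None])
    raw = model.head_raw(t) * model.cfg.head_gain
    dims = np.asarray(fused.data.shape[1:], dtype=np.float32) * (2 ** fused.level)
    center = 1.0 / (1.0 + np.exp(-raw.data[0, :3])) * dims
    extent = np.logaddexp(0.0, raw.data[0, 3:]) + 1.0
    return BoundingBox(tuple(center), tuple(extent))


def fuse_features(features: list) -> FeatureMap:
    """Cubic-resample every level to the first level's size and sum."""
    if not features:
        raise ConfigError("empty feature list")
    tensors = [Tensor(f.data[None]) for f in features]
    chans = {t.shape[1] for t in tensors}
    if len(chans) != 1:
        raise ConfigError(f"channel counts differ across levels: {chans}")
    target = tensors[0].shape[2:]
    acc = tensors[0].data.copy()
    for t in tensors[1:]:
        acc += _resample_to(t, target).data
    return FeatureMap(acc[0], level=features[0].level)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def localization_loss(c: BoundingBox, c_hat: BoundingBox, lam: float,
                      image_shape) -> float:
    """Center Euclidean distance + λ·Σ sqrt(|e²−ê²|)/dim.

    The absolute value inside the root makes the size term symmetric and
    defined for every box pair; it is 0 iff the extents agree.
    """
    c1 = np.asarray(c.center, dtype=np.float64)
    c2 = np.asarray(c_hat.center, dtype=np.float64)
    e1 = np.asarray(c.extent, dtype=np.float64)
    e2 = np.asarray(c_hat.extent, dtype=np.float64)
    dims = np.asarray(image_shape, dtype=np.float64)
    d = float(np.sqrt(np.sum((c1 - c2) ** 2)))
    size = float(np.sum(np.sqrt(np.abs(e1 ** 2 - e2 ** 2)) / dims))
    return d + lam * size


def _loss_autograd(centers: Tensor, extents: Tensor, tgt: np.ndarray,
                   lam: float, dims: np.ndarray) -> Tensor:
    """Batch-mean box loss on decoded (N,3)+(N,3) predictions."""
    tc, te = Tensor(tgt[:, :3]), Tensor(tgt[:, 3:])
    dc = centers - tc
    d = nn.sqrt((dc * dc).sum(axis=1))
    diff = nn.absolute(extents * extents - te * te)
    size = (nn.sqrt(diff) * Tensor(1.0 / dims)).sum(axis=1)
    return (d + lam * size).mean()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return np.zeros_like(x, dtype=np.float32)
    return ((x - lo) / (hi - lo)).astype(np.float32)


def load_manifest_volumes(manifest: pd.DataFrame, normalize: bool = True):
    """(images (n,1,X,Y,Z) float32, boxes (n,6)) from a dataset manifest."""
    imgs, boxes = [], []
    for _, row in manifest.iterrows():
        v = read_volume(row["image_path"])
        x = v.data.astype(np.float32)
        imgs.append(_minmax(x) if normalize else x)
        boxes.append([row["x_c"], row["y_c"], row["z_c"],
                      row["w_c"], row["h_c"], row["d_c"]])
    return np.stack(imgs)[:, None], np.asarray(boxes, dtype=np.float32)


def train_localizer(manifest: pd.DataFrame, cfg: LocalizerConfig,
                    epochs: int = 120, lr: float = 2e-4, batch: int = 4,
                    seed: int = 0, val_fraction: float = 0.2,
                    normalize: bool = True):
    """Train the localizer on a dataset manifest; returns (model, history).

    Minimizes the box loss with Adam (defaults lr 2e-4); keeps the
    best-on-validation parameter state.  Deterministic given ``seed``.
    """
    x, y = load_manifest_volumes(manifest, normalize=normalize)
    n = len(x)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction))) if n > 2 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = order, order
    dims = np.asarray(x.shape[2:], dtype=np.float32)

    model = LocalizerNet(cfg)
    opt = nn.Adam(model.parameters(), lr=lr)
    hist = {"epoch": [], "train_loss": [], "val_loss": []}
    best_state, best_val = None, np.inf

    def eval_loss(idx):
        tot = 0.0
        for s in range(0, len(idx), batch):
            b = idx[s:s + batch]
            c, e = model.forward_boxes(x[b])
            tot += _loss_autograd(c, e, y[b], cfg.lam, dims).item() * len(b)
        return tot / len(idx)

    for ep in range(epochs):
        perm = tr_idx[rng.permutation(len(tr_idx))]
        tot = 0.0
        for s in range(0, len(perm), batch):
            b = perm[s:s + batch]
            opt.zero_grad()
            c, e = model.forward_boxes(x[b])
            loss = _loss_autograd(c, e, y[b], cfg.lam, dims)
            val = loss.item()
            if not np.isfinite(val):
                raise DivergenceError(ep)
            loss.backward()
            opt.step()
            tot += val * len(b)
        train_loss = tot / len(perm)
        val_loss = eval_loss(val_idx) if len(val_idx) else train_loss
        if not np.isfinite(val_loss):
            raise DivergenceError(ep)
        hist["epoch"].append(ep)
        hist["train_loss"].append(train_loss)
        hist["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, pd.DataFrame(hist)
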