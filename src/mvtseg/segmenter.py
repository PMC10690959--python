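"""Morphological vision transformer (MVT) segmenter.

Architecture: ``enc_layers`` stride-2 3³ convolutions (GeLU) → depthwise
learnable dilation/erosion block, branches concatenated (identity when
``use_morphology`` is off) → 1³ projection convolution to the token
width → flatten spatial positions to tokens + linear projection +
learned positional embedding → pre-norm transformer encoder blocks →
unflatten → mirrored transposed convolutions → 1³ classification conv →
per-voxel softmax.  Input and output share the same spatial size.

Supervision is a weighted sum of generalized cross-entropy (per-voxel
negative log-likelihood of the true class) and a generalized Dice loss
over the two foreground classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .errors import ConfigError, DivergenceError
from .localization import (BoundingBox, LocalizerNet, crop_to_box, consolidate,
                           _minmax)
from .morphology import MorphBlock
from .nn.tensor import Tensor
from .volume_io import (LabelMap, OneHotMap, Volume, labels_to_onehot,
                        onehot_to_labels, read_labelmap, read_volume)


@dataclass
class MVTConfig:
    in_shape: tuple = (32, 32, 24)
    n_classes: int = 3
    enc_layers: int = 2
    enc_channels: tuple = (16, 32)
    se_size: int = 5
    token_dim: int = 96
    n_heads: int = 4
    n_tx_layers: int = 3
    mlp_ratio: float = 2.0
    loss_weights: tuple = (1.0, 1.0)   # (w_gce, w_gd)
    epsilon: float = 1e-6
    use_morphology: bool = True
    seed: int = 0

    def __post_init__(self):
        f = 2 ** self.enc_layers
        if any(d % f for d in self.in_shape):
            raise ConfigError(
                f"in_shape {self.in_shape} not divisible by 2^{self.enc_layers}")
        if len(self.enc_channels) != self.enc_layers:
            raise ConfigError("enc_channels length must equal enc_layers")
        if self.se_size % 2 == 0:
            raise ConfigError("se_size must be odd")
        if self.token_dim % self.n_heads:
            raise ConfigError("token_dim must be divisible by n_heads")
        if any(w < 0 for w in self.loss_weights) or sum(self.loss_weights) == 0:
            raise ConfigError("loss_weights must be >= 0 and not both zero")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")

    @property
    def token_grid(self):
        f = 2 ** self.enc_layers
        return tuple(d // f for d in self.in_shape)


class SegModel(nn.Module):
    """End-to-end MVT; forward maps (N,1,*in_shape) to per-voxel class probs."""

    def __init__(self, cfg: MVTConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        chans = [1] + list(cfg.enc_channels)
        self.enc = [nn.Conv3d(chans[i], chans[i + 1], k=3, stride=2, pad=1, rng=rng)
                    for i in range(cfg.enc_layers)]
        c_deep = cfg.enc_channels[-1]
        if cfg.use_morphology:
            self.morph = MorphBlock(c_deep, cfg.se_size, rng)
            c_morph = 2 * c_deep
        else:
            self.morph = None
            c_morph = c_deep
        self.proj = nn.Conv3d(c_morph, cfg.token_dim, k=1, stride=1, pad=0, rng=rng)
        grid = cfg.token_grid
        n_tokens = int(np.prod(grid))
        self.embed = nn.Linear(cfg.token_dim, cfg.token_dim, rng)
        self.pos = nn.param(rng.normal(0, 0.02,
                                       size=(1, n_tokens, cfg.token_dim)))
        self.blocks = [nn.TransformerBlock(cfg.token_dim, cfg.n_heads,
                                           cfg.mlp_ratio, rng)
                       for _ in range(cfg.n_tx_layers)]
        self.ln = nn.LayerNorm(cfg.token_dim)
        self.dec = []
        c_in = cfg.token_dim
        for i in range(cfg.enc_layers):
            c_out = cfg.enc_channels[max(cfg.enc_layers - 2 - i, 0)]
            self.dec.append(nn.ConvTranspose3d(c_in, c_out, k=4, stride=2,
                                               pad=1, rng=rng))
            c_in = c_out
        self.head = nn.Conv3d(c_in, cfg.n_classes, k=1, stride=1, pad=0, rng=rng)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if tuple(x.shape[2:]) != tuple(self.cfg.in_shape):
            raise ConfigError(
                f"input spatial shape {x.shape[2:]} != configured {self.cfg.in_shape}")
        f = x
        for conv in self.enc:
            f = nn.gelu(conv(f))
        if self.morph is not None:
            f = self.morph(f)
        f = self.proj(f)
        N, D = f.shape[0], f.shape[1]
        grid = self.cfg.token_grid
        tokens = f.reshape(N, D, int(np.prod(grid))).transpose(0, 2, 1)
        tokens = self.embed(tokens) + self.pos
        for blk in self.blocks:
            tokens = blk(tokens)
        tokens = self.ln(tokens)
        f = tokens.transpose(0, 2, 1).reshape(N, D, *grid)
        for deconv in self.dec:
            f = nn.gelu(deconv(f))
        logits = self.head(f)
        return nn.softmax(logits, axis=1)


def build_mvt(cfg: MVTConfig) -> SegModel:
    """Deterministic construction of the MVT from its configuration."""
    return SegModel(cfg)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _as_batched(x, dtype=np.float32) -> np.ndarray:
    a = x.data if isinstance(x, OneHotMap) else np.asarray(x)
    a = a.astype(dtype, copy=False)
    return a[None] if a.ndim == 4 else a


def _gce(t: np.ndarray, p: Tensor) -> Tensor:
    """Mean over voxels of −Σ_classes l·log(l̂), prediction clipped to ≥1e-7."""
    n_vox = int(np.prod([p.shape[0]] + list(p.shape[2:])))
    return -(Tensor(t) * nn.log(nn.clip_min(p, 1e-7))).sum() * (1.0 / n_vox)


def _gdl(t: np.ndarray, p: Tensor, eps: float) -> Tensor:
    """Generalized Dice loss averaged over foreground classes (1, 2...).

    A foreground class empty in both truth and prediction contributes a
    perfect-agreement term of 0.
    """
    n_cls = t.shape[1]
    terms, live = [], 0
    for c in range(1, n_cls):
        tc = t[:, c]
        pc = p.narrow(1, c, 1)
        if tc.sum() == 0 and pc.data.sum() == 0:
            continue
        inter = (Tensor(tc[:, None]) * pc).sum()
        denom = (pc * pc).sum() + float((tc * tc).sum())
        terms.append(1.0 - (inter + eps) * 2.0 / (denom + eps))
        live += 1
    if live == 0:
        return Tensor(0.0)
    acc = terms[0]
    for term in terms[1:]:
        acc = acc + term
    return acc * (1.0 / live)


def gce_loss(truth, pred) -> float:
    """Generalized cross entropy between hard truth and soft prediction.

    Mean over voxels of −Σ_classes l·log(l̂); prediction clipped to
    [1e-7, 1].  Double precision (the training loop uses the float32
    autodiff equivalent).
    """
    t64 = _as_batched(truth, np.float64)
    p64 = _as_batched(pred, np.float64)
    if t64.shape != p64.shape:
        raise ConfigError(f"shape mismatch {t64.shape} vs {p64.shape}")
    p64 = np.clip(p64, 1e-7, 1.0)
    n_vox = t64.shape[0] * int(np.prod(t64.shape[2:]))
    return float(-(t64 * np.log(p64)).sum() / n_vox)


def gdl_loss(truth, pred, epsilon: float = 1e-6) -> float:
    """Generalized Dice loss over foreground classes; background excluded.

    Per class: 1 − 2(Σ l·l̂ + ε)/(Σ l² + Σ l̂² + ε), averaged over
    foreground classes present in truth or prediction.
    """
    t64 = _as_batched(truth, np.float64)
    p64 = _as_batched(pred, np.float64)
    if t64.shape != p64.shape:
        raise ConfigError(f"shape mismatch {t64.shape} vs {p64.shape}")
    terms = []
    for c in range(1, t64.shape[1]):
        tc, pc = t64[:, c], p64[:, c]
        if tc.sum() == 0 and pc.sum() == 0:
            continue
        inter = (tc * pc).sum()
        denom = (tc * tc).sum() + (pc * pc).sum()
        terms.append(1.0 - 2.0 * (inter + epsilon) / (denom + epsilon))
    return float(np.mean(terms)) if terms else 0.0


def combined_loss(truth, pred, cfg: MVTConfig) -> float:
    """Weighted sum w_gce·GCE + w_gd·GDL."""
    w1, w2 = cfg.loss_weights
    out = 0.0
    if w1:
        out += w1 * gce_loss(truth, pred)
    if w2:
        out += w2 * gdl_loss(truth, pred, cfg.epsilon)
    return out


def _combined_t(t: np.ndarray, p: Tensor, cfg: MVTConfig) -> Tensor:
    w1, w2 = cfg.loss_weights
    loss = None
    if w1:
        loss = _gce(t, p) * w1
    if w2:
        g = _gdl(t, p, cfg.epsilon) * w2
        loss = g if loss is None else loss + g
    return loss


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def _load_cases(manifest: pd.DataFrame, normalize: bool):
    cases = []
    for _, row in manifest.iterrows():
        img = read_volume(row["image_path"])
        lab = read_labelmap(row["label_path"])
        x = img.data.astype(np.float32)
        if normalize:
            x = _minmax(x)
        center = np.array([row["x_c"], row["y_c"], row["z_c"]], dtype=np.float64)
        cases.append((Volume(x, img.spacing, img.origin), lab, center))
    return cases


def _crop_pair(vol: Volume, lab: LabelMap, center, in_shape):
    box = BoundingBox(tuple(center), (1, 1, 1))
    xc, _ = crop_to_box(vol, box, in_shape)
    yc, _ = crop_to_box(lab, box, in_shape)
    onehot = labels_to_onehot(yc)
    return xc.data[None], onehot.data


def _dsc_hard(pred_labels: np.ndarray, true_labels: np.ndarray, cls: int) -> float:
    a = pred_labels == cls
    b = true_labels == cls
    s = a.sum() + b.sum()
    if s == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / s


def train_segmenter(manifest: pd.DataFrame, cfg: MVTConfig, epochs: int = 30,
                    lr: float = 2e-4, batch: int = 4, seed: int = 0,
                    val_fraction: float = 0.2, jitter: int = 2,
                    aug_per_case: int = 0, normalize: bool = True):
    """Train the MVT on ground-truth-box crops; returns (model, history).

    Crop centers are jittered by ±``jitter`` voxels per case per epoch
    for robustness to localization error; validation crops are fixed.
    ``aug_per_case`` adds that many rigid/scale-augmented replicas of
    each training case per epoch (rotation ≤10°, scale ≤10 %, shift ≤2
    voxels), seeded and resampled every epoch.  Adam, defaults lr 2e-4;
    keeps the best-on-validation state.
    """
    cases = _load_cases(manifest, normalize)
    n = len(cases)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction))) if n > 2 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = order, order

    model = build_mvt(cfg)
    opt = nn.Adam(model.parameters(), lr=lr)
    hist = {"epoch": [], "train_loss": [], "val_loss": [],
            "val_dsc_c1": [], "val_dsc_c2": []}
    best_state, best_val = None, np.inf

    val_data = [_crop_pair(*cases[i][:2], cases[i][2], cfg.in_shape)
                for i in val_idx]

    from .phantoms import rigid_transform_pair
    from .localization import derive_gt_box

    def _augmented(i):
        vol, lab, _ = cases[i]
        for _try in range(5):
            rot = rng.uniform(-10.0, 10.0, 3)
            sc = 1.0 + rng.uniform(-0.1, 0.1)
            sh = rng.uniform(-2.0, 2.0, 3)
            try:
                av, al = rigid_transform_pair(vol, lab, tuple(rot), sc, tuple(sh))
            except Exception:
                continue
            return av, al, np.asarray(derive_gt_box(al, 0).center)
        return vol, lab, cases[i][2]

    for ep in range(epochs):
        pool = [("base", i) for i in tr_idx]
        pool += [("aug", i) for i in tr_idx for _ in range(aug_per_case)]
        order2 = rng.permutation(len(pool))
        samples = []
        jit = rng.integers(-jitter, jitter + 1, size=(len(pool), 3))
        for k, oi in enumerate(order2):
            kind, i = pool[oi]
            vol, lab, center = cases[i] if kind == "base" else _augmented(i)
            samples.append(_crop_pair(vol, lab, np.asarray(center) + jit[k],
                                      cfg.in_shape))
        tot = 0.0
        for s in range(0, len(samples), batch):
            chunk = samples[s:s + batch]
            xb = np.stack([c[0] for c in chunk])
            tb = np.stack([c[1] for c in chunk])
            opt.zero_grad()
            p = model.forward(xb)
            loss = _combined_t(tb, p, cfg)
            val = loss.item()
            if not np.isfinite(val):
                raise DivergenceError(ep)
            loss.backward()
            opt.step()
            tot += val * len(chunk)
        train_loss = tot / len(samples)

        vtot, d1, d2 = 0.0, [], []
        for x, t in val_data:
            p = model.forward(x[None])
            vtot += _combined_t(t[None], p, cfg).item()
            pl = np.argmax(p.data[0], axis=0)
            tl = np.argmax(t, axis=0)
            d1.append(_dsc_hard(pl, tl, 1))
            d2.append(_dsc_hard(pl, tl, 2))
        val_loss = vtot / max(len(val_data), 1) if val_data else train_loss
        if not np.isfinite(val_loss):
            raise DivergenceError(ep)
        hist["epoch"].append(ep)
        hist["train_loss"].append(train_loss)
        hist["val_loss"].append(val_loss)
        hist["val_dsc_c1"].append(float(np.mean(d1)) if d1 else np.nan)
        hist["val_dsc_c2"].append(float(np.mean(d2)) if d2 else np.nan)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, pd.DataFrame(hist)


def segment_case(image: Volume, loc_model: LocalizerNet, seg_model: SegModel,
                 cfg: MVTConfig, normalize: bool = True, tta_shifts: int = 0):
    """Full cascade: predict box → crop → MVT → argmax → consolidate.

    ``tta_shifts > 0`` averages the soft prediction over crops whose
    centers are shifted by ±tta_shifts voxels along each axis (6 extra
    forward passes), echoing the shift jitter used in training;
    deterministic.  Returns (LabelMap in the original frame, per-class
    soft maps in the original frame with background probability 1
    outside the VOI).
    """
    x = image.data.astype(np.float32)
    vnorm = Volume(_minmax(x) if normalize else x, image.spacing, image.origin)
    box = loc_model.predict_box(image, normalize=normalize)
    crop, rec = crop_to_box(vnorm, box, cfg.in_shape)
    probs = seg_model.forward(crop.data[None, None]).data[0]
    if tta_shifts:
        acc = probs.astype(np.float64)
        count = 1
        for ax in range(3):
            for sgn in (-tta_shifts, tta_shifts):
                c2 = list(box.center)
                c2[ax] += sgn
                if not (0 <= c2[ax] <= image.shape[ax] - 1):
                    continue
                crop2, rec2 = crop_to_box(vnorm, BoundingBox(tuple(c2), box.extent),
                                          cfg.in_shape)
                p2 = seg_model.forward(crop2.data[None, None]).data[0]
                # map the shifted prediction back into the reference crop frame
                back = np.zeros_like(probs)
                back[0] = 1.0
                src = tuple(slice(pb, t - pa) for pb, pa, t in
                            zip(rec2.pad_before, rec2.pad_after, rec2.target_shape))
                full_dst = tuple(slice(a, b) for a, b in
                                 zip(rec2.crop_start, rec2.crop_stop))
                tmp = np.zeros((cfg.n_classes,) + tuple(image.shape),
                               dtype=np.float32)
                tmp[0] = 1.0
                for c in range(cfg.n_classes):
                    tmp[(c,) + full_dst] = p2[(c,) + src]
                ref_src = tuple(slice(a, b) for a, b in
                                zip(rec.crop_start, rec.crop_stop))
                ref_dst = tuple(slice(pb, t - pa) for pb, pa, t in
                                zip(rec.pad_before, rec.pad_after,
                                    rec.target_shape))
                for c in range(cfg.n_classes):
                    back[(c,) + ref_dst] = tmp[(c,) + ref_src]
                acc += back
                count += 1
        probs = (acc / count).astype(np.float32)
    seg_crop = onehot_to_labels(OneHotMap(probs), image.spacing, image.origin)
    seg = consolidate(seg_crop, rec)

    full = np.zeros((cfg.n_classes,) + tuple(image.shape), dtype=np.float32)
    full[0] = 1.0
    inner = tuple(slice(pb, t - pa) for pb, pa, t in
                  zip(rec.pad_before, rec.pad_after, rec.target_shape))
    dst = tuple(slice(a, b) for a, b in zip(rec.crop_start, rec.crop_stop))
    for c in range(cfg.n_classes):
        full[(c,) + dst] = probs[(c,) + inner]
    return seg, full
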