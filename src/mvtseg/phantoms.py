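"""Synthetic 3-D phantoms of a small two-substructure gray-matter-like object.

Each phantom emulates the statistical structure the cascade assumes: a
compact, low-contrast organ (~1–3 % of the volume) made of two
face-adjacent substructures — an anterior part (class 1, standing in for
the hippocampus proper) and a posterior part (class 2, parts of the
subiculum) — inside a larger noisy volume, with inter-subject pose,
size and shape variation.

Geometry: two half-ellipsoids sharing their cross-section semi-axes on
a split plane through the object centroid; the plane is tilted by the
random pose rotation.  When the two along-axis semi-lengths agree this
is exactly one ellipsoid cut by a plane.  The shared plane guarantees
the substructures abut, and partial-volume blur makes the boundary
fuzzy — the property that makes the two-class problem nontrivial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import AugmentationError, ParameterError
from .localization import BoundingBox, derive_gt_box
from .volume_io import LabelMap, Volume, write_volume


@dataclass
class PhantomParams:
    """Study conditions for phantom generation.

    Intensities are arbitrary units; the foreground sits 15 % above the
    background with noise at half the contrast, and the two
    substructures differ by a small gap — solvable but not trivial.
    """

    volume_shape: tuple = (48, 48, 48)
    spacing: tuple = (1.0, 1.0, 1.0)
    anterior_semiaxes_range: tuple = (6.0, 10.0)   # voxels, all three axes
    posterior_semiaxes_range: tuple = (5.0, 9.0)   # voxels, along-axis length
    max_rotation_deg: float = 10.0
    max_translation: float = 4.0                   # voxels
    background_mean: float = 100.0
    foreground_mean: float = 115.0
    substructure_contrast: float = 6.0             # class1 − class2 intensity
    noise_sd: float = 7.5
    blur_sigma: float = 0.6                        # partial-volume blur, voxels
    gt_box_margin: int = 2
    seed: int = 0

    def __post_init__(self):
        for r in (self.anterior_semiaxes_range, self.posterior_semiaxes_range):
            if r[0] <= 0 or r[1] < r[0]:
                raise ParameterError(f"invalid semi-axis range {r}")
        if self.noise_sd < 0:
            raise ParameterError("noise sd must be >= 0")
        half = min(self.volume_shape) / 2.0
        reach = (max(self.anterior_semiaxes_range[1],
                     self.posterior_semiaxes_range[1])
                 + self.max_translation + 2.0)
        if reach >= half:
            raise ParameterError(
                f"object (reach {reach}) cannot fit inside {self.volume_shape} "
                "with 2-voxel clearance for all poses")


@dataclass
class PhantomCase:
    image: Volume
    truth: LabelMap
    gt_box: BoundingBox
    case_id: str
    seed_used: int


def _rotation_matrix(angles_deg):
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def generate_phantom(params: PhantomParams, seed: int,
                     case_id: str | None = None) -> PhantomCase:
    """One phantom; a pure function of (params, seed)."""
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in params.volume_shape)

    a = rng.uniform(*params.anterior_semiaxes_range, size=3)   # (ax, ay, az)
    p_len = rng.uniform(*params.posterior_semiaxes_range)
    angles = rng.uniform(-params.max_rotation_deg, params.max_rotation_deg, 3)
    rot = _rotation_matrix(angles)
    center = (np.asarray(shape) - 1) / 2.0 + rng.uniform(
        -params.max_translation, params.max_translation, 3)

    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    rel = np.stack([g - c for g, c in zip(grids, center)])     # (3, X, Y, Z)
    # object frame: rotate world offsets back
    u = np.einsum("ji,jxyz->ixyz", rot, rel)
    ant = (u[0] / a[0]) ** 2 + (u[1] / a[1]) ** 2 + (u[2] / a[2]) ** 2 <= 1.0
    post = (u[0] / p_len) ** 2 + (u[1] / a[1]) ** 2 + (u[2] / a[2]) ** 2 <= 1.0
    labels = np.zeros(shape, dtype=np.int16)
    labels[(u[0] >= 0) & ant] = 1
    labels[(u[0] < 0) & post] = 2
    if not (labels == 1).any() or not (labels == 2).any():
        raise ParameterError("degenerate phantom: a substructure is empty")

    gap = params.foreground_mean - params.background_mean
    img = np.full(shape, params.background_mean, dtype=np.float64)
    img[labels == 1] += gap
    img[labels == 2] += gap - params.substructure_contrast
    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=shape)

    truth = LabelMap(labels, params.spacing)
    case = PhantomCase(
        image=Volume(img.astype(np.float32), params.spacing),
        truth=truth,
        gt_box=derive_gt_box(truth, params.gt_box_margin),
        case_id=case_id or f"case_{seed:06d}",
        seed_used=seed,
    )
    return case


def generate_dataset(n: int, params: PhantomParams, seed: int,
                     outdir) -> pd.DataFrame:
    """Write n image/label NIfTI pairs plus a manifest CSV; returns the manifest.

    Per-case seeds are ``seed + index``; regeneration with the same
    arguments reproduces the files bit-exactly.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        case = generate_phantom(params, seed + i, case_id=f"case_{i:03d}")
        ip = outdir / f"{case.case_id}_image.nii.gz"
        lp = outdir / f"{case.case_id}_label.nii.gz"
        write_volume(case.image, ip)
        write_volume(case.truth, lp)
        b = case.gt_box
        rows.append({
            "case_id": case.case_id,
            "image_path": str(ip), "label_path": str(lp),
            "x_c": b.center[0], "y_c": b.center[1], "z_c": b.center[2],
            "w_c": b.extent[0], "h_c": b.extent[1], "d_c": b.extent[2],
            "vol_class1_voxels": int((case.truth.data == 1).sum()),
            "vol_class2_voxels": int((case.truth.data == 2).sum()),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# rigid/scale augmentation
# ---------------------------------------------------------------------------

def rigid_transform_pair(image: Volume, truth: LabelMap,
                         rotation_deg=(0.0, 0.0, 0.0), scale: float = 1.0,
                         shift=(0.0, 0.0, 0.0)):
    """Rotate/scale/shift an image+label pair about the volume center.

    Image resampled trilinearly, labels nearest-neighbor; raises if a
    substructure leaves the field of view.
    """
    shape = truth.shape
    center = (np.asarray(shape, dtype=np.float64) - 1) / 2.0
    rot = _rotation_matrix(rotation_deg) * scale
    # affine_transform maps output -> input: x_in = M @ x_out + offset
    m = np.linalg.inv(rot)
    offset = center - m @ (center + np.asarray(shift, dtype=np.float64))
    img = ndimage.affine_transform(image.data.astype(np.float64), m,
                                   offset=offset, order=1, mode="constant",
                                   cval=float(np.median(image.data)))
    lab = ndimage.affine_transform(truth.data, m, offset=offset,
                                   order=0, mode="constant", cval=0)
    out_truth = LabelMap(lab.astype(np.int16), truth.spacing,
                         truth.origin, truth.classes)
    if not (out_truth.data == 1).any() or not (out_truth.data == 2).any():
        raise AugmentationError("augmentation pushed a substructure out of view")
    return Volume(img.astype(np.float32), image.spacing, image.origin), out_truth


def apply_rigid(case: PhantomCase, rotation_deg=(0.0, 0.0, 0.0),
                scale: float = 1.0, shift=(0.0, 0.0, 0.0),
                margin: int = 2) -> PhantomCase:
    """Apply an explicit rotation/scale/shift about the volume center.

    The ground-truth box is recomputed from the transformed truth.
    """
    image, truth = rigid_transform_pair(case.image, case.truth,
                                        rotation_deg, scale, shift)
    return PhantomCase(image, truth, derive_gt_box(truth, margin),
                       case.case_id, case.seed_used)


def _fits(truth: LabelMap) -> bool:
    fg = truth.data > 0
    if not fg.any():
        return False
    for ax in range(3):
        proj = fg.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.nonzero(proj)[0]
        if idx[0] == 0 or idx[-1] == truth.shape[ax] - 1:
            return False
    return True


def rigid_augment(case: PhantomCase, max_rot_deg: float, max_scale: float,
                  max_shift: float, seed: int, margin: int = 2) -> PhantomCase:
    """Random rigid+scale augmentation; retries with damped magnitude (≤5)."""
    rng = np.random.default_rng(seed)
    rot = rng.uniform(-max_rot_deg, max_rot_deg, 3)
    scale = 1.0 + rng.uniform(-max_scale, max_scale)
    shift = rng.uniform(-max_shift, max_shift, 3)
    damp = 1.0
    for _ in range(6):
        try:
            out = apply_rigid(case, tuple(rot * damp), 1.0 + (scale - 1.0) * damp,
                              tuple(shift * damp), margin)
        except AugmentationError:
            damp *= 0.5
            continue
        if _fits(out.truth):
            return out
        damp *= 0.5
    raise AugmentationError("could not keep the object inside the volume "
                            "after 5 damped retries")
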