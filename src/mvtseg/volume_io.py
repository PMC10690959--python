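"""NIfTI volume / label-map I/O and one-hot conversions.

Conventions: array axes are ``(x, y, z) = (w, h, d)``; voxel indexing is
0-based; spacing is mm/voxel taken from the NIfTI header and written back
on save.  Label maps use the class alphabet {0 background, 1 hippocampus
proper, 2 parts of the subiculum}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, LabelError

DEFAULT_CLASSES = (0, 1, 2)


@dataclass
class Volume:
    """3-D scalar intensity grid with voxel spacing (mm) and origin (mm)."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3-D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMap:
    """3-D integer grid over a fixed class alphabet, paired with a Volume grid."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    classes: tuple = DEFAULT_CLASSES

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"label map must be 3-D, got ndim={arr.ndim}")
        self.classes = tuple(int(c) for c in self.classes)
        vals = np.unique(arr)
        bad = [v for v in vals if int(v) not in self.classes or v != int(v)]
        if bad:
            raise LabelError(f"label value(s) {bad} outside classes {self.classes}")
        self.data = arr.astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class OneHotMap:
    """(class, x, y, z) map; hard indicator or soft per-voxel probabilities."""

    data: np.ndarray
    classes: tuple = DEFAULT_CLASSES

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise FormatError("one-hot map must be 4-D (class, x, y, z)")
        if self.data.shape[0] != len(self.classes):
            raise FormatError("channel count must equal number of classes")
        sums = self.data.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise FormatError("per-voxel class probabilities must sum to 1")


def _affine(spacing, origin):
    a = np.eye(4)
    a[0, 0], a[1, 1], a[2, 2] = spacing
    a[:3, 3] = origin
    return a


def read_volume(path) -> Volume:
    """Load a 3-D NIfTI volume; header spacing/origin are honored."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D data, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return Volume(np.asarray(data, dtype=np.float32), spacing, origin)


def read_labelmap(path, classes=DEFAULT_CLASSES) -> LabelMap:
    """Load an integer label map; voxel values must round to members of ``classes``."""
    v = read_volume(path)
    rounded = np.rint(v.data)
    if np.max(np.abs(v.data - rounded)) > 1e-3:
        raise LabelError(f"{path}: voxel values are not integral")
    bad = sorted(set(np.unique(rounded).astype(int)) - set(int(c) for c in classes))
    if bad:
        raise LabelError(f"{path}: label value(s) {bad} outside classes {tuple(classes)}")
    return LabelMap(rounded.astype(np.int16), v.spacing, v.origin, tuple(classes))


def write_volume(v, path) -> None:
    """Write a Volume (float32) or LabelMap (int16) as NIfTI."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, LabelMap):
        data = v.data.astype(np.int16)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def labels_to_onehot(l: LabelMap) -> OneHotMap:
    """Hard one-hot encoding; channel k is the indicator of classes[k]."""
    chans = [(l.data == c).astype(np.float32) for c in l.classes]
    return OneHotMap(np.stack(chans, axis=0), l.classes)


def onehot_to_labels(p: OneHotMap, spacing=(1.0, 1.0, 1.0),
                     origin=(0.0, 0.0, 0.0)) -> LabelMap:
    """Per-voxel argmax; ties go to the lowest class index (background wins)."""
    idx = np.argmax(p.data, axis=0)
    labels = np.asarray(p.classes, dtype=np.int16)[idx]
    return LabelMap(labels, spacing, origin, p.classes)
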