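"""Segmentation evaluation metrics.

Overlap: DSC and Jaccard.  Surface distances (HD95 / MSD / RMSD) use the
pooled symmetric multiset of Euclidean distances (mm, voxel centers)
between 6-connectivity boundary voxels of the two masks; HD95 is the
95th percentile with linear interpolation.  COMD is the centroid
distance, VD the signed (truth − prediction) volume difference in mm³.
Cohort level: mean ± sample SD per metric, Bland–Altman limits of
agreement and volumetric Pearson correlation.

Conventions: DSC/Jaccard are 1 when both masks are empty and 0 when
exactly one is; distance metrics are undefined (NaN) for empty masks and
are propagated as missing, never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .errors import EmptyMaskError
from .volume_io import LabelMap

_FACE = ndimage.generate_binary_structure(3, 1)


def _check(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dsc(a, b) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); 1.0 if both empty."""
    a, b = _check(a, b)
    s = int(a.sum()) + int(b.sum())
    if s == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / s


def jaccard(a, b) -> float:
    """|A∩B|/|A∪B|; 1.0 if both empty."""
    a, b = _check(a, b)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def surface_voxels(mask) -> np.ndarray:
    """(n,3) indices of foreground voxels with a face-neighbor background
    (volume edges count as background)."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_FACE, border_value=0)
    return np.argwhere(mask & ~interior)


def surface_distances(a, b, spacing=(1.0, 1.0, 1.0)):
    """Two multisets (a→b, b→a) of nearest surface-to-surface distances in mm."""
    a, b = _check(a, b)
    if not a.any() or not b.any():
        raise EmptyMaskError("surface distances undefined for an empty mask")
    sp = np.asarray(spacing, dtype=np.float64)
    pa = surface_voxels(a) * sp
    pb = surface_voxels(b) * sp
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return d_ab, d_ba


def _pooled(a, b, spacing):
    d_ab, d_ba = surface_distances(a, b, spacing)
    return np.concatenate([d_ab, d_ba])


def hd95(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile (linear interpolation) of the pooled symmetric distances."""
    return float(np.percentile(_pooled(a, b, spacing), 95))


def msd(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Mean of the pooled symmetric surface distances."""
    return float(np.mean(_pooled(a, b, spacing)))


def rmsd(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Root mean square of the pooled symmetric surface distances."""
    return float(np.sqrt(np.mean(_pooled(a, b, spacing) ** 2)))


def comd(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Euclidean distance between foreground centers of mass, in mm."""
    a, b = _check(a, b)
    if not a.any() or not b.any():
        raise EmptyMaskError("center of mass undefined for an empty mask")
    sp = np.asarray(spacing, dtype=np.float64)
    ca = np.argwhere(a).mean(axis=0) * sp
    cb = np.argwhere(b).mean(axis=0) * sp
    return float(np.linalg.norm(ca - cb))


def volume_difference(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Signed (|A| − |B|)·voxel_volume in mm³ (truth minus prediction)."""
    a, b = _check(a, b)
    vox = float(np.prod(spacing))
    return (int(a.sum()) - int(b.sum())) * vox


def bland_altman(v_truth, v_pred):
    """(bias, lower LoA, upper LoA) of prediction − truth; limits ±1.96·SD."""
    t = np.asarray(v_truth, dtype=np.float64)
    p = np.asarray(v_pred, dtype=np.float64)
    if t.shape != p.shape or t.size < 2:
        raise ValueError("need two equal-length lists with n >= 2")
    d = p - t
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def pearson_volumes(v_truth, v_pred) -> float:
    """Sample Pearson correlation of truth vs predicted volumes."""
    t = np.asarray(v_truth, dtype=np.float64)
    p = np.asarray(v_pred, dtype=np.float64)
    if t.size < 2 or t.shape != p.shape:
        raise ValueError("need two equal-length lists with n >= 2")
    if t.std() == 0 or p.std() == 0:
        raise ValueError("correlation undefined for zero-variance volumes")
    return float(pearsonr(t, p)[0])


# ---------------------------------------------------------------------------
# case / cohort evaluation
# ---------------------------------------------------------------------------

PER_CASE_COLUMNS = ["case_id", "class", "dsc", "jac", "hd95_mm", "msd_mm",
                    "rmsd_mm", "comd_mm", "vd_mm3",
                    "vol_truth_mm3", "vol_pred_mm3"]


@dataclass
class MetricsReport:
    """Cohort summary: per-class mean ± SD plus volumetric agreement."""

    per_case: pd.DataFrame
    summary: pd.DataFrame                 # rows: class; columns: metric mean/sd
    bland_altman: dict                    # class -> (bias, lo, hi)
    pearson_r: dict                       # class -> r


def evaluate_case(truth: LabelMap, pred: LabelMap, case_id: str = "case",
                  classes=(1, 2)) -> list:
    """Per-class metric records; distance metrics NaN when a mask is empty."""
    if truth.shape != pred.shape:
        raise ValueError("truth/prediction shapes differ")
    if truth.spacing != pred.spacing:
        raise ValueError("truth/prediction spacings differ")
    sp = truth.spacing
    vox = float(np.prod(sp))
    records = []
    for c in classes:
        a = truth.data == c
        b = pred.data == c
        rec = {"case_id": case_id, "class": c,
               "dsc": dsc(a, b), "jac": jaccard(a, b),
               "vd_mm3": volume_difference(a, b, sp),
               "vol_truth_mm3": int(a.sum()) * vox,
               "vol_pred_mm3": int(b.sum()) * vox}
        if a.any() and b.any():
            pooled = _pooled(a, b, sp)
            rec["hd95_mm"] = float(np.percentile(pooled, 95))
            rec["msd_mm"] = float(np.mean(pooled))
            rec["rmsd_mm"] = float(np.sqrt(np.mean(pooled ** 2)))
            rec["comd_mm"] = comd(a, b, sp)
        else:
            rec.update({"hd95_mm": np.nan, "msd_mm": np.nan,
                        "rmsd_mm": np.nan, "comd_mm": np.nan})
        records.append(rec)
    return records


def evaluate_cohort(records: list) -> MetricsReport:
    """Aggregate per-case records into mean ± sample-SD summaries per class."""
    df = pd.DataFrame(records)[PER_CASE_COLUMNS]
    metrics = ["dsc", "jac", "hd95_mm", "msd_mm", "rmsd_mm", "comd_mm", "vd_mm3"]
    rows = []
    ba, rr = {}, {}
    for c, grp in df.groupby("class"):
        row = {"class": c, "n": len(grp),
               "n_missing_distance": int(grp["hd95_mm"].isna().sum())}
        for m in metrics:
            vals = grp[m].dropna().to_numpy()
            row[f"{m}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        rows.append(row)
        if len(grp) >= 2:
            ba[int(c)] = bland_altman(grp["vol_truth_mm3"], grp["vol_pred_mm3"])
            try:
                rr[int(c)] = pearson_volumes(grp["vol_truth_mm3"],
                                             grp["vol_pred_mm3"])
            except ValueError:
                rr[int(c)] = np.nan
    return MetricsReport(per_case=df, summary=pd.DataFrame(rows),
                         bland_altman=ba, pearson_r=rr)


def plot_bland_altman(report: MetricsReport, path, cls: int = 1) -> None:
    """Write a Bland–Altman scatter (volume agreement) for one class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grp = report.per_case[report.per_case["class"] == cls]
    t = grp["vol_truth_mm3"].to_numpy()
    p = grp["vol_pred_mm3"].to_numpy()
    mean = (t + p) / 2.0
    diff = p - t
    bias, lo, hi = report.bland_altman[cls]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(mean, diff, s=18)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="gray", linestyle=style, linewidth=1)
    ax.set_xlabel("mean volume (mm³)")
    ax.set_ylabel("prediction − truth (mm³)")
    ax.set_title(f"class {cls} volume agreement")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
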