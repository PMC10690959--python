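# mvtseg

Cascaded segmentation of hippocampus substructures in 3-D T1-weighted-like
volumes: a **localization network** first detects the volume of interest
(VOI) around the whole hippocampal formation, then a **morphological
vision transformer (MVT)** segments the two substructures — the
hippocampus proper (class 1) and parts of the subiculum (class 2) —
inside a fixed-size crop, and the result is consolidated back into the
original frame.

The hippocampus is a small (≈ 0.1 % of the head volume), low-contrast,
irregularly shaped gray-matter structure, which makes one-shot
whole-volume segmentation wasteful and imprecise; the cascade spends its
capacity inside a tight VOI instead.  Accurate substructure contours
matter for hippocampal-avoidance radiotherapy planning and for atrophy
measurement in neurodegeneration.

## The model

**Localization.**  A multi-scale feature hierarchy
`F_k = GeLU(Conv_{stride 2}(F_{k−1}))` is fused by cubic resampling to a
common grid and an elementwise sum, `F_m = Σ_k Resample(F_k)`; pooled
moment statistics of `F_m` feed a small fully connected head that
regresses the box `C = [x_c, y_c, z_c, w_c, h_c, d_c]` (sigmoid-scaled
centers, softplus + 1 extents).  Training minimizes

```
L_loc = ‖c − ĉ‖₂ + λ Σ_axes √|e² − ê²| / dim ,   λ = 0.5
```

**MVT.**  Stride-2 convolutions → a *learnable grayscale morphology*
block — depthwise non-flat dilation `max_q x(p+q) + se(q)` and erosion
`min_q x(p+q) − se(q)` with trainable structuring elements, outputs
concatenated — → projection convolution → transformer encoder over the
remaining spatial tokens → transposed convolutions back to full crop
resolution → per-voxel softmax over {background, proper, subiculum}.
Supervision is `GCE + GDL`: generalized cross entropy (per-voxel
negative log-likelihood) plus a generalized Dice loss over the two
foreground classes.

Everything runs on a compact NumPy autodiff core (`mvtseg.nn`) — no GPU
or deep-learning framework required.  Training is deterministic given a
seed.

Because the real task's data is an external download, the package ships
a **synthetic phantom generator** producing the regime the method
assumes: one small two-part ellipsoidal organ with a blurred internal
boundary, 15 % foreground contrast, heavy noise, and inter-subject
pose/size variation.  A full metric suite (DSC, Jaccard, HD95, MSD,
RMSD, COMD, volume difference, Bland–Altman, volumetric Pearson) with
brute-force-validated surface distances evaluates the cascade.

## Worked example

```python
import numpy as np
from mvtseg.phantoms import PhantomParams, generate_dataset
from mvtseg.pipeline import run_benchmark

out = run_benchmark(seed=17, workdir="runs/demo")
print(f"center error   {out['mean_center_error_voxels']:.2f} voxels")
print(f"DSC proper     {out['dsc_class1']:.3f}")
print(f"DSC subiculum  {out['dsc_class2']:.3f}")
print(f"MSD (mm)       {out['msd_mm_class1']:.3f} / {out['msd_mm_class2']:.3f}")
print(f"volume r       {out['pearson_r_union']:.3f} "
      f"(per structure {out['pearson_r_class1']:.3f} / {out['pearson_r_class2']:.3f})")
```

This generates 60 phantoms (48³ voxels, 1 mm), trains the tiny localizer
(60 epochs) and the tiny MVT (40 epochs, batch 4, lr 2·10⁻⁴) on the
first 45, and evaluates the cascade on the 15 held-out phantoms.  On one
CPU it takes about six minutes and prints

```
center error   1.44 voxels
DSC proper     0.890
DSC subiculum  0.873
MSD (mm)       0.439 / 0.458
volume r       0.984 (per structure 0.949 / 0.932)
```

meaning: the predicted VOI center lands within ~1.4 voxels of the true
box center (the 32×32×24 crop then contains the whole organ), both
substructures overlap their ground truth at Dice ≈ 0.87–0.89 with mean
surface errors under half a millimeter, and the predicted
whole-formation volume tracks the true volume closely (r = 0.98) — the
quantities a hippocampal-avoidance or atrophy workflow consumes.

The same workflow is scriptable from the shell:

```bash
mvtseg simulate  --config config.yaml
mvtseg train-loc --config config.yaml --manifest runs/demo/data/manifest.csv
mvtseg train-seg --config config.yaml --manifest runs/demo/data/manifest.csv
mvtseg infer     --config config.yaml --loc-checkpoint runs/demo/localizer.npz \
                 --seg-checkpoint runs/demo/segmenter.npz image.nii.gz
mvtseg evaluate  --config config.yaml --pred-dir preds/ --truth-dir truth/
```

`mvtseg train-seg --no-morphology` trains the ablation model (the MVT
with the morphology block replaced by identity).

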