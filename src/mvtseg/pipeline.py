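"""High-level orchestration: configs, checkpoints, and the full cascade.

The CLI and the reproducibility script are thin wrappers over this
module.  ``run_benchmark`` is the standard scaled-down end-to-end
experiment: generate a phantom cohort, train the localizer and the MVT
on the training split, run the cascade on the held-out split, and
report localization and segmentation quality.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .localization import (LocalizerConfig, LocalizerNet, crop_to_box,
                           train_localizer)
from .metrics import MetricsReport, evaluate_case, evaluate_cohort
from .phantoms import PhantomParams, generate_dataset
from .segmenter import MVTConfig, SegModel, build_mvt, segment_case, train_segmenter
from .volume_io import read_labelmap, read_volume, write_volume

log = logging.getLogger("mvtseg")


@dataclass
class TrainParams:
    loc_epochs: int = 80
    seg_epochs: int = 25
    lr: float = 2e-4
    batch: int = 4
    val_fraction: float = 0.2
    jitter: int = 2


@dataclass
class RunConfig:
    """Single-file configuration for the whole pipeline."""

    seed: int = 17
    outdir: str = "runs/default"
    n_cases: int = 60
    n_holdout: int = 15
    phantom: PhantomParams = field(default_factory=PhantomParams)
    localizer: LocalizerConfig = field(default_factory=LocalizerConfig)
    mvt: MVTConfig = field(default_factory=MVTConfig)
    train: TrainParams = field(default_factory=TrainParams)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for key, sub in (("phantom", PhantomParams), ("localizer", LocalizerConfig),
                         ("mvt", MVTConfig), ("train", TrainParams)):
            if key in kw and isinstance(kw[key], dict):
                sub_kw = {k: tuple(v) if isinstance(v, list) else v
                          for k, v in kw[key].items()}
                kw[key] = sub(**sub_kw)
        try:
            return cls(**kw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh,
                           sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def tiny_localizer_config(seed: int) -> LocalizerConfig:
    """Desk-scale localizer used by the standard benchmark."""
    return LocalizerConfig(levels=3, base_channels=8, head_hidden=32,
                           lam=0.5, seed=seed)


def tiny_mvt_config(seed: int, use_morphology: bool = True) -> MVTConfig:
    """Desk-scale MVT used by the standard benchmark."""
    return MVTConfig(in_shape=(32, 32, 24), enc_layers=3,
                     enc_channels=(8, 16, 32), se_size=5, token_dim=96,
                     n_heads=4, n_tx_layers=3, mlp_ratio=2.0,
                     use_morphology=use_morphology, seed=seed)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, cfg, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    meta = json.dumps({"config": asdict(cfg),
                       "kind": type(cfg).__name__})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path):
    """Returns (model, cfg) rebuilt from a saved checkpoint."""
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    kind = meta["kind"]
    ckw = {k: tuple(v) if isinstance(v, list) else v
           for k, v in meta["config"].items()}
    if kind == "LocalizerConfig":
        cfg = LocalizerConfig(**ckw)
        model = LocalizerNet(cfg)
    elif kind == "MVTConfig":
        cfg = MVTConfig(**ckw)
        model = build_mvt(cfg)
    else:
        raise ConfigError(f"unknown checkpoint kind {kind}")
    model.load_state_dict(state)
    return model, cfg


def dump_structuring_elements(model: SegModel, path) -> None:
    """Write per-channel SE weight grids to CSV for inspection."""
    if model.morph is None:
        raise ConfigError("model was built without morphology")
    rows = []
    for kind, se in (("dilation", model.morph.se_dil),
                     ("erosion", model.morph.se_ero)):
        k = model.morph.se_size
        for c in range(se.data.shape[0]):
            for (i, j, l), w in np.ndenumerate(se.data[c]):
                rows.append({"branch": kind, "channel": c, "i": i, "j": j,
                             "k": l, "weight": float(w)})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig):
    outdir = Path(cfg.outdir) / "data"
    manifest = generate_dataset(cfg.n_cases, cfg.phantom, cfg.seed, outdir)
    log.info("simulated %d cases into %s", len(manifest), outdir)
    return manifest, outdir / "manifest.csv"


def _write_run_record(cfg: RunConfig, stage: str, extra: dict):
    rec = {"stage": stage, "seed": cfg.seed, "config_sha": cfg.digest(), **extra}
    path = Path(cfg.outdir) / f"run_{stage}.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(rec, indent=2))
    return path


def stage_train_localizer(cfg: RunConfig, manifest: pd.DataFrame):
    t = cfg.train
    model, hist = train_localizer(manifest, cfg.localizer, epochs=t.loc_epochs,
                                  lr=t.lr, batch=t.batch, seed=cfg.seed,
                                  val_fraction=t.val_fraction)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_checkpoint(model, cfg.localizer, out / "localizer.npz")
    hist.to_csv(out / "localizer_history.csv", index=False)
    _write_run_record(cfg, "train_localizer",
                      {"final_train_loss": hist["train_loss"].iloc[-1],
                       "final_val_loss": hist["val_loss"].iloc[-1]})
    return model, hist


def stage_train_segmenter(cfg: RunConfig, manifest: pd.DataFrame):
    t = cfg.train
    model, hist = train_segmenter(manifest, cfg.mvt, epochs=t.seg_epochs,
                                  lr=t.lr, batch=t.batch, seed=cfg.seed,
                                  val_fraction=t.val_fraction, jitter=t.jitter)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_checkpoint(model, cfg.mvt, out / "segmenter.npz")
    hist.to_csv(out / "segmenter_history.csv", index=False)
    _write_run_record(cfg, "train_segmenter",
                      {"final_train_loss": hist["train_loss"].iloc[-1],
                       "final_val_loss": hist["val_loss"].iloc[-1]})
    return model, hist


def stage_infer(loc_model, seg_model, mvt_cfg: MVTConfig, image_paths,
                outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for p in image_paths:
        img = read_volume(p)
        seg, _ = segment_case(img, loc_model, seg_model, mvt_cfg)
        dst = outdir / (Path(p).name.replace(".nii", "_seg.nii")
                        if ".nii" in Path(p).name else Path(p).name + "_seg.nii.gz")
        write_volume(seg, dst)
        written.append(dst)
    return written


def stage_evaluate(pairs, outdir=None) -> MetricsReport:
    """pairs: iterable of (case_id, truth LabelMap, pred LabelMap)."""
    records = []
    for case_id, truth, pred in pairs:
        records.extend(evaluate_case(truth, pred, case_id))
    report = evaluate_cohort(records)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.per_case.to_csv(outdir / "metrics_per_case.csv", index=False)
        report.summary.to_csv(outdir / "metrics_cohort.csv", index=False)
        ba_rows = [{"class": c, "bias_mm3": b[0], "loa_low_mm3": b[1],
                    "loa_high_mm3": b[2], "pearson_r": report.pearson_r.get(c)}
                   for c, b in report.bland_altman.items()]
        pd.DataFrame(ba_rows).to_csv(outdir / "volume_agreement.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# standard end-to-end benchmark
# ---------------------------------------------------------------------------

def run_benchmark(seed: int, workdir, n_cases: int = 60, n_holdout: int = 15,
                  use_morphology: bool = True, loc_epochs: int = 60,
                  seg_epochs: int = 40, aug_per_case: int = 2,
                  tta_shifts: int = 2, val_fraction: float = 0.1,
                  manifest: pd.DataFrame | None = None,
                  loc_model=None, seg_seed: int | None = None) -> dict:
    """Scaled-down end-to-end experiment; returns measured quantities.

    Phantoms (default 60 at 48³) are split into the first ``n_cases −
    n_holdout`` for training and the remainder for held-out evaluation.
    A pre-generated manifest and/or trained localizer may be passed in
    to share work between the with/without-morphology arms.
    """
    workdir = Path(workdir)
    params = PhantomParams()
    if manifest is None:
        manifest = generate_dataset(n_cases, params, seed, workdir / "data")
    train_mf = manifest.iloc[: n_cases - n_holdout].reset_index(drop=True)
    hold_mf = manifest.iloc[n_cases - n_holdout:].reset_index(drop=True)

    if loc_model is None:
        loc_model, loc_hist = train_localizer(
            train_mf, tiny_localizer_config(seed), epochs=loc_epochs,
            lr=2e-4, batch=4, seed=seed)
    else:
        loc_hist = None
    seg_seed = seed if seg_seed is None else seg_seed
    mvt_cfg = tiny_mvt_config(seg_seed, use_morphology=use_morphology)
    seg_model, seg_hist = train_segmenter(train_mf, mvt_cfg, epochs=seg_epochs,
                                          lr=2e-4, batch=4, seed=seg_seed,
                                          aug_per_case=aug_per_case,
                                          val_fraction=val_fraction)

    # held-out evaluation ------------------------------------------------
    center_errors, coverages, records = [], [], []
    union_truth, union_pred = [], []
    for _, row in hold_mf.iterrows():
        img = read_volume(row["image_path"])
        truth = read_labelmap(row["label_path"])
        gt_center = np.array([row["x_c"], row["y_c"], row["z_c"]])
        box = loc_model.predict_box(img)
        center_errors.append(float(np.linalg.norm(
            np.asarray(box.center) - gt_center)))
        crop_t, _ = crop_to_box(truth, box, mvt_cfg.in_shape)
        fg_total = int((truth.data > 0).sum())
        coverages.append(int((crop_t.data > 0).sum()) / fg_total)
        seg, _ = segment_case(img, loc_model, seg_model, mvt_cfg,
                              tta_shifts=tta_shifts)
        records.extend(evaluate_case(truth, seg, row["case_id"]))
        union_truth.append(float((truth.data > 0).sum()))
        union_pred.append(float((seg.data > 0).sum()))
    report = evaluate_cohort(records)
    s = report.summary.set_index("class")

    out = {
        "n_holdout": len(hold_mf),
        "mean_center_error_voxels": float(np.mean(center_errors)),
        "box_foreground_coverage": float(np.mean(coverages)),
        "dsc_class1": float(s.loc[1, "dsc_mean"]),
        "dsc_class2": float(s.loc[2, "dsc_mean"]),
        "hd95_mm_class1": float(s.loc[1, "hd95_mm_mean"]),
        "hd95_mm_class2": float(s.loc[2, "hd95_mm_mean"]),
        "msd_mm_class1": float(s.loc[1, "msd_mm_mean"]),
        "msd_mm_class2": float(s.loc[2, "msd_mm_mean"]),
        "comd_mm_class1": float(s.loc[1, "comd_mm_mean"]),
        "comd_mm_class2": float(s.loc[2, "comd_mm_mean"]),
        "pearson_r_class1": float(report.pearson_r.get(1, np.nan)),
        "pearson_r_class2": float(report.pearson_r.get(2, np.nan)),
        # single volumetric agreement number: whole-formation (union)
        # volume correlation, the quantity an atrophy workflow consumes
        "pearson_r_union": float(np.corrcoef(union_truth, union_pred)[0, 1]),
        "loc_history": loc_hist,
        "seg_history": seg_hist,
        "report": report,
        "manifest": manifest,
        "loc_model": loc_model,
        "seg_model": seg_model,
        "mvt_cfg": mvt_cfg,
    }
    return out
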