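"""End-to-end orchestration: synth -> train -> quantify -> evaluate -> predict.

Every stage is a pure function of (inputs, config, seed); re-running the
pipeline with the same config reproduces all CSV outputs bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .biomarkers import extract_biomarkers
from .detection import (ClipCnnConfig, clip_labels, detect_layers,
                        slice_clips, train_clip_cnn)
from .metrics import evaluate_predictions
from .prognosis import ForestConfig, compare_variants, variant_table
from .segmentation import FcnConfig, segment, train_fcn
from .synthetic import (SceneSpec, cohort_feature_table, generate_cohort,
                        LABEL_CODES, LESION_CLASSES)

logger = logging.getLogger(__name__)

STAGES = ("synth", "train_detector", "train_segmenter", "quantify",
          "evaluate", "predict")

_DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "runs/demo",
    "stages": list(STAGES),
    "synth": {"n_eyes": 10, "height": 128, "width": 512,
              "speckle_sigma": 0.0, "train_fraction": 0.6},
    "detector": {"epochs": 6, "learning_rate": 0.02, "batch_size": 32,
                 "max_train_scenes": 6},
    "segmenter": {"epochs": 6, "learning_rate": 0.05, "batch_size": 2,
                  "max_train_scenes": 8},
    "predict": {"cv_folds": 5, "n_trees_min": 150, "n_trees_max": 300,
                "n_trees_step": 50},
}


class ConfigError(ValueError):
    pass


def _merge_validate(user: dict) -> dict:
    cfg = json.loads(json.dumps(_DEFAULT_CONFIG))
    for key, val in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key: {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {key!r} must be a mapping")
            for sub in val:
                if sub not in cfg[key]:
                    raise ConfigError(f"unknown config key: {key}.{sub}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    for stage in cfg["stages"]:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage: {stage!r}")
    return cfg


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: list[str], **extra) -> None:
        self.stages.append({"stage": name, "outputs": outputs, **extra})

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    user = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        user = {**user, **overrides}
    return _merge_validate(user)


def run_pipeline(config: dict | str | Path) -> RunManifest:
    """Execute the configured stages; returns the run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge_validate(config)
    seed = int(config["seed"])
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest()[:16],
        seed=seed, package_version=__version__)
    stages = config["stages"]

    # --- synth -------------------------------------------------------------
    scfg = config["synth"]
    spec = SceneSpec(image_height=int(scfg["height"]),
                     image_width=int(scfg["width"]),
                     speckle_sigma=float(scfg["speckle_sigma"]),
                     pixel_size_mm=8.0 / int(scfg["width"]))
    records = generate_cohort(int(scfg["n_eyes"]), seed=seed,
                              scene_spec=spec)
    n_train = max(1, int(round(scfg["train_fraction"] * len(records))))
    train_recs, test_recs = records[:n_train], records[n_train:]
    if "synth" in stages:
        sdir = out / "scenes"
        sdir.mkdir(exist_ok=True)
        rows = []
        outputs = []
        for rec in records:
            for visit, (img, ann, _t) in rec.visits.items():
                stem = f"{rec.eye_id}_{visit}"
                io.write_image_png(sdir / f"{stem}.png", img)
                io.write_mask_png(sdir / f"{stem}_mask.png", ann.lesion_mask)
                io.write_traces_csv(sdir / f"{stem}_traces.csv", ann)
                rows.append({"eye_id": rec.eye_id, "visit": visit,
                             "image": f"scenes/{stem}.png",
                             "mask": f"scenes/{stem}_mask.png",
                             "traces": f"scenes/{stem}_traces.csv",
                             "label": rec.label})
        pd.DataFrame(rows).to_csv(out / "cohort_manifest.csv", index=False)
        gt_table, gt_labels = cohort_feature_table(records)
        io.write_feature_table(out / "gt_features.csv", gt_table)
        gt_labels.rename_axis("eye_id").to_csv(out / "labels.csv")
        manifest.add("synth", ["cohort_manifest.csv", "gt_features.csv",
                               "labels.csv"], n_eyes=len(records))

    # --- train detectors ---------------------------------------------------
    det_models = {}
    if {"train_detector", "quantify", "evaluate"} & set(stages):
        dcfg = config["detector"]
        scenes = [(img, ann) for rec in train_recs
                  for (img, ann, _t) in rec.visits.values()
                  ][: int(dcfg["max_train_scenes"])]
        for layer in ("ez", "elm"):
            train_set = []
            for img, ann in scenes:
                grid = slice_clips(img)
                lbls = clip_labels(ann, layer)
                train_set += [(grid.clips[i], bool(lbls[i]))
                              for i in range(grid.n_clips)]
            cc = ClipCnnConfig(epochs=int(dcfg["epochs"]),
                               learning_rate=float(dcfg["learning_rate"]),
                               batch_size=int(dcfg["batch_size"]), seed=seed)
            det_models[layer] = train_clip_cnn(train_set, cc)
            det_models[layer].save(str(out / f"detector_{layer}.npz"))
        manifest.add("train_detector",
                     ["detector_ez.npz", "detector_elm.npz"],
                     n_train_scenes=len(scenes))

    # --- train segmenter ---------------------------------------------------
    seg_model = None
    if {"train_segmenter", "quantify", "evaluate"} & set(stages):
        gcfg = config["segmenter"]
        pairs = [(img, ann.lesion_mask) for rec in train_recs
                 for (img, ann, _t) in rec.visits.values()]
        pairs = pairs[: int(gcfg["max_train_scenes"])]
        fc = FcnConfig(epochs=int(gcfg["epochs"]),
                       learning_rate=float(gcfg["learning_rate"]),
                       batch_size=int(gcfg["batch_size"]), seed=seed)
        seg_model = train_fcn(pairs, fc)
        seg_model.save(str(out / "segmenter.npz"))
        manifest.add("train_segmenter", ["segmenter.npz"],
                     n_train_scenes=len(pairs),
                     final_loss=seg_model.loss_history[-1])

    # --- quantify ----------------------------------------------------------
    if "quantify" in stages:
        rows = []
        for rec in records:
            for visit, (img, ann, _t) in rec.visits.items():
                det_ez = detect_layers(det_models["ez"], img)
                det_elm = detect_layers(det_models["elm"], img)
                seg = segment(seg_model, img)
                vec = extract_biomarkers(img, seg.labels, det_ez.presence,
                                         det_elm.presence, img.pixel_size_mm)
                rows.append({"eye_id": rec.eye_id, "visit": visit,
                             **vec.as_dict()})
        pred_table = pd.DataFrame(rows)
        io.write_feature_table(out / "features.csv", pred_table)
        manifest.add("quantify", ["features.csv"], n_rows=len(rows))

    # --- evaluate ----------------------------------------------------------
    if "evaluate" in stages:
        per_scan: dict[str, list] = {b: [] for b in
                                     (*LESION_CLASSES, "EZ", "ELM")}
        eval_recs = test_recs if test_recs else records
        for rec in eval_recs:
            for visit, (img, ann, _t) in rec.visits.items():
                seg = segment(seg_model, img)
                for cls in LESION_CLASSES:
                    per_scan[cls].append(
                        (seg.labels == LABEL_CODES[cls],
                         ann.lesion_mask == LABEL_CODES[cls]))
                for layer, key in (("ez", "EZ"), ("elm", "ELM")):
                    det = detect_layers(det_models[layer], img)
                    per_scan[key].append((det.presence,
                                          clip_labels(ann, layer)))
        report = evaluate_predictions(per_scan, seed=seed)
        report.to_csv(out / "metrics.csv")
        manifest.add("evaluate", ["metrics.csv"],
                     avg_dice=float(report.table.loc["dice", "AVG"]))

    # --- predict -----------------------------------------------------------
    if "predict" in stages:
        gt_table, gt_labels = cohort_feature_table(records)
        counts = gt_labels.value_counts()
        pcfg = config["predict"]
        folds = min(int(pcfg["cv_folds"]), int(counts.min()))
        if counts.size < 2 or folds < 2:
            warnings.warn("predict stage skipped: degenerate cohort labels")
            manifest.add("predict", [], skipped=True)
        else:
            fcfg = ForestConfig(
                n_trees_grid=tuple(range(int(pcfg["n_trees_min"]),
                                         int(pcfg["n_trees_max"]) + 1,
                                         int(pcfg["n_trees_step"]))),
                cv_folds=folds, seed=seed)
            reports = compare_variants(gt_table, gt_labels, fcfg)
            table = variant_table(reports)
            table.to_csv(out / "prediction_metrics.csv",
                         float_format=io.FLOAT_FMT)
            imp = reports[("six_metric", "month3")].importances
            imp.rename("importance").rename_axis("feature").to_csv(
                out / "feature_importance.csv", float_format=io.FLOAT_FMT)
            manifest.add("predict",
                         ["prediction_metrics.csv", "feature_importance.csv"],
                         cv_folds=folds)

    manifest.write(out / "run_manifest.json")
    return manifest
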