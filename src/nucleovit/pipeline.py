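"""Orchestration: dataset splitting, run configuration, and the three-stage
workflow (segment -> enhance -> classify) including the four-arm ablation
(EVT, +wpe, +nie, +wpe+nie).

A run is a pure function of its configuration and seed: every random
decision traces back to ``RunConfig.seed`` and no stage consults the clock
or ambient randomness.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import __version__
from .enhancement import enhance_dataset
from .evt import (ClsTrainConfig, EVTConfig, deterministic_inference,
                  load_classification_samples, train_classifier,
                  write_predictions)
from .metrics import classification_report, write_report
from .segmentation import (ResUnetConfig, SegTrainConfig, predict_mask,
                           train_segmentation)
from .synthetic import (LabeledImage, benign_spec, generate_dataset,
                        load_image, load_mask, malignant_spec, read_manifest,
                        write_manifest)

__all__ = ["SplitSpec", "RunConfig", "split_dataset", "run_pipeline",
           "ABLATION_ARMS"]

ABLATION_ARMS = ("evt", "evt_wpe", "evt_nie", "evt_wpe_nie")


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (7.0, 2.0, 1.0)
    seed: int = 0
    stratify_by_label: bool = True

    def __post_init__(self):
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")


def _largest_remainder(n: int, ratios) -> list[int]:
    total = sum(ratios)
    exact = [n * r / total for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    leftover = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def split_dataset(rows: list[dict], spec: SplitSpec):
    """Per-class shuffled assignment by cumulative ratio with
    largest-remainder rounding; returns (train, val, test) row lists."""
    rows = list(rows)
    if spec.stratify_by_label and len(rows) < 10:
        raise ValueError("stratified splitting needs at least 10 items")
    rng = np.random.default_rng(spec.seed)
    groups: dict[str, list[dict]] = {}
    if spec.stratify_by_label:
        for row in rows:
            groups.setdefault(row.get("label", ""), []).append(row)
    else:
        groups[""] = rows
    parts = ([], [], [])
    for label in sorted(groups):
        members = groups[label]
        if len(members) < len(spec.ratios):
            import warnings
            warnings.warn(f"class {label!r} has fewer items than split parts")
        order = rng.permutation(len(members))
        sizes = _largest_remainder(len(members), spec.ratios)
        cursor = 0
        for part, size in zip(parts, sizes):
            part.extend(members[i] for i in order[cursor:cursor + size])
            cursor += size
    return parts


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "runs/pipeline"
    seed: int = 42
    n_per_class: int = 16
    image_size: int = 64
    split: SplitSpec = field(default_factory=SplitSpec)
    seg_model: ResUnetConfig = field(default_factory=lambda: ResUnetConfig(
        depth=3, base_channels=8))
    seg_train: SegTrainConfig = field(default_factory=lambda: SegTrainConfig(
        epochs=10))
    evt_model: EVTConfig = field(default_factory=lambda: EVTConfig(
        embed_dim=32, tokenizer_channels=(8, 16), encoder_layers=1,
        attention_heads=2, dropout=0.0))
    cls_train: ClsTrainConfig = field(default_factory=lambda: ClsTrainConfig(
        epochs=8, warmup=2))
    edge_gain: float = 0.0
    arms: tuple[str, ...] = ABLATION_ARMS


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {"nucleovit_version": __version__,
            "numpy_version": np.__version__,
            "python_version": platform.python_version(),
            "seed": config.seed,
            "config_hash": _config_hash(config)}


def _load_labeled(rows) -> list[LabeledImage]:
    return [LabeledImage(image=load_image(r["image"]),
                         mask=load_mask(r["mask"]) if r.get("mask") else None,
                         label=r.get("label") or None, id=r["id"])
            for r in rows]


def run_pipeline(config: RunConfig) -> dict:
    """Execute generate -> train-seg -> enhance -> train-cls -> evaluate.

    Returns the summary dict (one entry per ablation arm) and writes all
    artifacts plus a ``summary.json`` under ``config.out_dir``.  On stage
    failure the partially written artifacts remain on disk and the raised
    error names the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump({"config": asdict(config), "provenance": _provenance(config)},
                  fh, indent=2, default=str)
    stage = "generate"
    try:
        manifest = generate_dataset(
            config.n_per_class,
            benign_spec(width=config.image_size, height=config.image_size),
            malignant_spec(width=config.image_size, height=config.image_size),
            seed=config.seed, out_dir=out / "dataset")
        rows = read_manifest(manifest)
        train_rows, val_rows, test_rows = split_dataset(
            rows, replace(config.split, seed=config.seed))
        for name, part in (("train", train_rows), ("val", val_rows),
                           ("test", test_rows)):
            write_manifest(part, out / "dataset" / f"{name}.csv")

        stage = "train-seg"
        seg_model, seg_history = train_segmentation(
            _load_labeled(train_rows), _load_labeled(val_rows),
            config.seg_model, replace(config.seg_train, seed=config.seed))

        stage = "enhance"
        segmenter = lambda img: predict_mask(seg_model, img)  # noqa: E731
        enhanced_manifests = {}
        for name, part in (("train", train_rows), ("val", val_rows),
                           ("test", test_rows)):
            enhanced_manifests[name] = enhance_dataset(
                part, segmenter, out / "enhanced" / name,
                edge_gain=config.edge_gain)

        stage = "train-cls"
        datasets = {
            False: {name: load_classification_samples(part)
                    for name, part in (("train", train_rows), ("val", val_rows),
                                       ("test", test_rows))},
            True: {name: load_classification_samples(
                       read_manifest(enhanced_manifests[name]))
                   for name in ("train", "val", "test")},
        }
        summary = {}
        for arm in config.arms:
            use_wpe = "wpe" in arm
            use_nie = "nie" in arm
            data = datasets[use_nie]
            model_cfg = replace(config.evt_model, wpe_enabled=use_wpe)
            model, history = train_classifier(
                data["train"], data["val"], model_cfg,
                replace(config.cls_train, seed=config.seed))
            preds = deterministic_inference(model, data["test"])
            arm_dir = out / "arms" / arm
            arm_dir.mkdir(parents=True, exist_ok=True)
            write_predictions(preds, arm_dir / "predictions.csv")
            report = classification_report(
                [p["pred_label"] for p in preds],
                [p["true_label"] for p in preds],
                scores=[p["p_malignant"] for p in preds])
            write_report(report, arm_dir / "report.json")
            summary[arm] = {"accuracy": report["accuracy"],
                            "kappa": report["kappa"],
                            "youden": report["youden"],
                            "auc": report.get("auc"),
                            "per_class": report["per_class"]}
        stage = "summary"
        summary_doc = {"arms": summary, "provenance": _provenance(config),
                       "seg_final_val_dice": seg_history[-1]["val_dice"]}
        with open(out / "summary.json", "w") as fh:
            json.dump(summary_doc, fh, indent=2)
        return summary_doc
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
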