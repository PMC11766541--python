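"""End-to-end experiment orchestration: simulate, train, predict, evaluate.

An experiment mirrors the study pattern: train on mixes of clean
(high-quality, manually-corrected-style markup) and degraded (uncorrected,
box-derived markup) datasets, validate and test on clean held-out scene
sets, then compare texture profiles between the truth markup and the model
prediction on the test scenes.  Bundled dataset tags play the role of the
high/low-quality strata: ``hq-a``/``hq-b``/``hq-c`` are disjoint clean scene
sets (train/val/test), ``lq`` is a degraded-markup set.  Experiments are
described by a YAML manifest whose sections mirror the configuration types.
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

from .errors import ValidationError
from .evaluation import evaluate_masks
from .field_data import TileGrid, write_mask
from .segmentation import (
    AugConfig,
    SegModelConfig,
    TrainConfig,
    build_model,
    predict_mask,
    train,
    write_history_csv,
)
from .stand_counting import CountFilterConfig
from .synthetic_fields import (
    AnnotationDegradeSpec,
    FieldSpec,
    SegDataset,
    generate_dataset,
    generate_field,
    rasterize_centers,
)
from .texture import compare_markups, texture_profile

log = logging.getLogger(__name__)

_SPEC45 = FieldSpec(512, 512, row_spacing_cm=45.0, in_row_spacing_cm=20.0,
                    missing_rate=0.05, touch_rate=0.05, weed_rate=2.0)
_SPEC90 = FieldSpec(512, 512, row_spacing_cm=90.0, in_row_spacing_cm=25.0,
                    missing_rate=0.05, touch_rate=0.05, weed_rate=2.0)
_DEGRADE = AnnotationDegradeSpec(center_jitter_cm=2.0, drop_rate=0.1,
                                 spurious_rate=1.0, box_mode=True)

#: bundled desk-scale dataset tags; ``stream`` keeps scene seeds disjoint
DATASET_REGISTRY: dict[str, dict] = {
    "hq-a": {"specs": [_SPEC45, _SPEC90], "degrade": None, "stream": 1},
    "hq-b": {"specs": [_SPEC45, _SPEC90], "degrade": None, "stream": 2},
    "hq-c": {"specs": [_SPEC45, _SPEC90], "degrade": None, "stream": 3},
    "lq": {"specs": [_SPEC45, _SPEC90], "degrade": _DEGRADE, "stream": 4},
}


@dataclass
class ExperimentConfig:
    name: str = "pilot"
    train_sources: list[str] = field(default_factory=lambda: ["hq-a"])
    val_source: str = "hq-b"
    test_source: str = "hq-c"
    n_scenes_per_spec: int = 6
    n_val_scenes_per_spec: int = 1
    n_test_scenes_per_spec: int = 3
    model: SegModelConfig = field(default_factory=lambda: SegModelConfig("rn18", 0.25, 128))
    train_cfg: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=10, batch_size=8, lr_start=2e-3, lr_end=2e-5))
    augment: AugConfig | None = None
    counting: CountFilterConfig = field(default_factory=CountFilterConfig)
    eval_tile_px: int = 256
    texture_tile_px: int = 256
    seed: int = 0

    def validate(self) -> None:
        tags = self.train_sources + [self.val_source, self.test_source]
        for tag in tags:
            if tag not in DATASET_REGISTRY:
                raise ValidationError(
                    f"unknown dataset tag {tag!r}; available: {sorted(DATASET_REGISTRY)}"
                )
        if self.test_source in self.train_sources or self.val_source in self.train_sources:
            raise ValidationError(
                "train/val/test dataset tags must be disjoint (leakage guard)"
            )
        if self.test_source == self.val_source:
            raise ValidationError("val_source and test_source must differ")
        self.model.validate()
        self.train_cfg.validate()
        if self.augment is not None:
            self.augment.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = dict(doc)
        if "model" in kwargs:
            kwargs["model"] = SegModelConfig(**kwargs["model"])
        if "train_cfg" in kwargs:
            kwargs["train_cfg"] = TrainConfig(**kwargs["train_cfg"])
        if "augment" in kwargs and kwargs["augment"] is not None:
            kwargs["augment"] = AugConfig(**kwargs["augment"])
        if "counting" in kwargs:
            kwargs["counting"] = CountFilterConfig(**kwargs["counting"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
             for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _tag_seed(config_seed: int, tag: str) -> int:
    stream = DATASET_REGISTRY[tag]["stream"]
    return int(np.random.SeedSequence([config_seed, stream]).generate_state(1)[0]) % (2**31)


def build_tiles(config: ExperimentConfig, tag: str, n_scenes_per_spec: int) -> SegDataset:
    """All tiles of one dataset tag (no internal split; tags ARE the split)."""
    entry = DATASET_REGISTRY[tag]
    ds = generate_dataset(
        entry["specs"], n_scenes_per_spec, config.model.input_tile_px,
        _tag_seed(config.seed, tag), degrade=entry["degrade"],
        split_fractions=(1.0, 0.0, 0.0),
    )
    return ds


def pilot_benchmark(seed: int = 0, config: ExperimentConfig | None = None) -> dict:
    """Train the bundled desk-scale pilot and score it on held-out scenes.

    Returns validation IoU of the best epoch, the pooled per-tile count
    agreement across all held-out test scenes (the desk-scale analogue of the
    study's per-experiment accuracy table), mean whole-scene pixel IoU, and
    the pooled truth-vs-predicted texture comparison.
    """
    from .evaluation import CountSeries, count_metrics, pixel_iou, tile_counts

    config = config or ExperimentConfig(seed=seed)
    config.validate()
    train_parts = [build_tiles(config, tag, config.n_scenes_per_spec)
                   for tag in config.train_sources]
    train_split = SegDataset(
        np.concatenate([p.images for p in train_parts]),
        np.concatenate([p.masks for p in train_parts]),
        np.concatenate([p.split for p in train_parts]),
        np.concatenate([p.scene_id for p in train_parts]),
    )
    val_split = build_tiles(config, config.val_source, config.n_val_scenes_per_spec)
    model = build_model(config.model, seed=config.seed)
    model, history = train(model, train_split, val_split, config.train_cfg,
                           aug=config.augment)

    test_entry = DATASET_REGISTRY[config.test_source]
    test_ss = np.random.SeedSequence([_tag_seed(config.seed, config.test_source), 11])
    test_seeds = test_ss.generate_state(
        config.n_test_scenes_per_spec * len(test_entry["specs"]))
    grid = TileGrid(config.eval_tile_px, config.eval_tile_px)
    tgrid = TileGrid(config.texture_tile_px, config.texture_tile_px)
    pooled_x, pooled_y, ious = [], [], []
    profiles = []
    k = 0
    for spec in test_entry["specs"]:
        for _ in range(config.n_test_scenes_per_spec):
            scene_seed = int(test_seeds[k]) % (2**31)
            k += 1
            scene = generate_field(spec, scene_seed)
            pred = predict_mask(model, scene.image,
                                tile_px=config.model.input_tile_px, overlap=32)
            pooled_x.extend(tile_counts(scene.truth_mask, grid, config.counting))
            pooled_y.extend(tile_counts(pred, grid, config.counting))
            ious.append(pixel_iou(scene.truth_mask, pred))
            tag = f"rows{int(spec.row_spacing_cm)}-{scene_seed}"
            profiles.append((tag, texture_profile(scene.truth_mask, tgrid),
                             texture_profile(pred, tgrid)))
    counts = count_metrics(CountSeries(pooled_x, pooled_y,
                                       tile_size_m=config.eval_tile_px / 100.0))
    all_truth = pd.concat(
        [p[1].assign(tile_id=[f"{p[0]}-{t}" for t in p[1].tile_id]) for p in profiles],
        ignore_index=True)
    all_pred = pd.concat(
        [p[2].assign(tile_id=[f"{p[0]}-{t}" for t in p[2].tile_id]) for p in profiles],
        ignore_index=True)
    comparison = compare_markups(all_truth, all_pred)
    return {
        "history": history,
        "best_val_iou": float(max(h.val_iou for h in history)),
        "count_series": (pooled_x, pooled_y),
        "count_metrics": counts,
        "mean_scene_iou": float(np.mean(ious)),
        "n_test_scenes": len(ious),
        "texture_comparison": comparison,
        "model": model,
    }


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write report.json, history.csv, masks/, profiles/."""
    config.validate()
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "profiles").mkdir(exist_ok=True)
    log.info("experiment %s (config hash %s) seed %d",
             config.name, config.config_hash(), config.seed)

    train_parts = [build_tiles(config, tag, config.n_scenes_per_spec)
                   for tag in config.train_sources]
    train_split = SegDataset(
        np.concatenate([p.images for p in train_parts]),
        np.concatenate([p.masks for p in train_parts]),
        np.concatenate([p.split for p in train_parts]),
        np.concatenate([p.scene_id for p in train_parts]),
    )
    val_split = build_tiles(config, config.val_source, config.n_val_scenes_per_spec)
    log.info("tiles: %d train / %d val", len(train_split), len(val_split))

    model = build_model(config.model, seed=config.seed)
    model, history = train(model, train_split, val_split, config.train_cfg,
                           aug=config.augment)
    write_history_csv(history, out / "history.csv")
    model.save(out / "model.pkl")

    # held-out test scenes from the test tag's own seed stream
    test_entry = DATASET_REGISTRY[config.test_source]
    test_ss = np.random.SeedSequence(
        [_tag_seed(config.seed, config.test_source), 11])
    test_seeds = test_ss.generate_state(
        config.n_test_scenes_per_spec * len(test_entry["specs"]))
    per_scene = []
    profiles = []
    k = 0
    for spec in test_entry["specs"]:
        for _ in range(config.n_test_scenes_per_spec):
            seed = int(test_seeds[k]) % (2**31)
            k += 1
            scene = generate_field(spec, seed)
            pred = predict_mask(model, scene.image,
                                tile_px=config.model.input_tile_px, overlap=32)
            tag = f"rows{int(spec.row_spacing_cm)}-{seed}"
            write_mask(pred, out / "masks" / f"{tag}.png")
            report = evaluate_masks(scene.truth_mask, pred,
                                    tile_px=config.eval_tile_px,
                                    filter=config.counting)
            per_scene.append({"scene": tag, **report.as_dict()})
            grid = TileGrid(config.texture_tile_px, config.texture_tile_px)
            profiles.append((tag, texture_profile(scene.truth_mask, grid),
                             texture_profile(pred, grid)))

    all_truth = pd.concat(
        [p[1].assign(tile_id=[f"{p[0]}-{t}" for t in p[1].tile_id]) for p in profiles],
        ignore_index=True)
    all_pred = pd.concat(
        [p[2].assign(tile_id=[f"{p[0]}-{t}" for t in p[2].tile_id]) for p in profiles],
        ignore_index=True)
    all_truth.to_csv(out / "profiles" / "truth.csv", index=False)
    all_pred.to_csv(out / "profiles" / "predicted.csv", index=False)
    comparison = compare_markups(all_truth, all_pred)

    summary_cols = ("MAE", "MAPE_pct", "r", "r_s", "IoU")
    report = {
        "name": config.name,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "best_val_iou": max(h.val_iou for h in history),
        "per_scene": per_scene,
        "mean": {c: float(np.nanmean([s[c] for s in per_scene])) for c in summary_cols},
        "texture_comparison": comparison.to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
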