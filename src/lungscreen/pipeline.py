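"""End-to-end orchestration of the screening pipeline.

Stage order: load (or synthesize) images -> normalize -> stratified
train/validation/test split -> nine-fold stationary-wavelet + geometric
augmentation of the training set -> per-extractor feature generation ->
fusion -> iterative feature selection -> head training -> evaluation on the
held-out test set.  Every stage logs its input/output counts, derives its
own child seed from the master seed, and persists an artifact so any stage
can be replayed in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import augment as aug
from . import classifiers as clf
from .containers import FeatureMatrix, ImageSet
from .errors import ConfigurationError, ValidationError
from .evaluation import EvaluationReport, evaluate_holdout, fingerprint
from .features import default_extractors, extract_features, merge_features
from .fixtures import FixtureSpec, make_image_dataset
from .seeding import child_seed
from .selectors import holdout_loss, iterative_select

log = logging.getLogger("lungscreen.pipeline")

SCHEMA_VERSION = 1
STAGES = ("load", "split", "augment", "extract", "select", "train", "evaluate")


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration for one pipeline run."""

    schema_version: int = SCHEMA_VERSION
    # data source: a directory of class subfolders, or synthetic fixtures
    data_dir: str | None = None
    classes: tuple[str, ...] = ("normal", "pneumonia", "covid19")
    fixture_n_per_class: int = 10
    image_size: tuple[int, int, int] = (64, 64, 3)
    # split / augmentation
    split_ratios: tuple[float, float, float] = (0.60, 0.25, 0.15)
    swt_levels: int = 3
    wavelet: str = "db2"
    translation_range: tuple[float, float] = (-10.0, 10.0)
    rotation_range: tuple[float, float] = (-90.0, 90.0)
    shear_range: tuple[float, float] = (-30.0, 30.0)
    # features
    n_extractors: int = 3
    extractor_dim: int = 1000
    # selection
    selector_method: str = "chi2"
    k_min: int = 32
    k_max: int | None = None
    k_step: int = 4
    # head
    head: str = "svm"
    cv_folds: int = 0          # 0 = holdout evaluation only
    master_seed: int = 0

    def validate(self) -> None:
        if self.selector_method not in ("nca", "chi2", "mrmr", "mrmr_fcq"):
            raise ConfigurationError(f"unknown selector {self.selector_method!r}")
        if self.head not in ("cnn", "lda", "svm"):
            raise ConfigurationError(f"unknown head {self.head!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported config schema {raw.get('schema_version')}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        cfg.validate()
        return cfg


def _load_images(cfg: PipelineConfig) -> ImageSet:
    if cfg.data_dir is None:
        spec = FixtureSpec(n_per_class=cfg.fixture_n_per_class,
                           classes=tuple(cfg.classes),
                           image_size=tuple(cfg.image_size),
                           seed=child_seed(cfg.master_seed, "fixtures"))
        return make_image_dataset(spec)
    from PIL import Image
    root = Path(cfg.data_dir)
    images, labels, ids = [], [], []
    for label in cfg.classes:
        cls_dir = root / label
        if not cls_dir.is_dir():
            raise ValidationError(f"class directory missing: {cls_dir}")
        for p in sorted(cls_dir.glob("*")):
            if p.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            arr = np.asarray(Image.open(p).convert("RGB"))
            images.append(arr)
            labels.append(label)
            ids.append(p.stem)
    if not images:
        raise ValidationError(f"no images found under {root}")
    return ImageSet(images=images, labels=labels, ids=ids)


def _train_head(head: str, X: np.ndarray, y: np.ndarray, seed: int):
    if head == "cnn":
        return clf.train_cnn(X, y, clf.CnnSpec(seed=seed,
                                               n_classes=np.unique(y).size))
    if head == "lda":
        return clf.train_lda(X, y)
    return clf.train_svm(X, y)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path
                 ) -> EvaluationReport:
    """Execute the full pipeline; artifacts land in *out_dir*.

    Writes ``augment_manifest.csv``, ``features.npz`` (+ JSON sidecar),
    ``selection.json``, ``model.joblib`` (+ ``model.json`` sidecar), and
    ``report.json``; returns the held-out test-set evaluation report.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        data = _load_images(cfg)
        log.info("load: %d images, classes %s", len(data), data.class_counts())

        stage = "split"
        split_spec = aug.SplitSpec(ratios=tuple(cfg.split_ratios),
                                   seed=child_seed(cfg.master_seed, "split"))
        train, val, test = aug.split_dataset(data, split_spec)
        log.info("split: train=%d val=%d test=%d", len(train), len(val), len(test))

        stage = "augment"
        params = aug.AugmentationParams(
            translation_range=tuple(cfg.translation_range),
            rotation_range=tuple(cfg.rotation_range),
            shear_range=tuple(cfg.shear_range),
            seed=child_seed(cfg.master_seed, "augment"))
        train_aug = aug.augment_training_set(train, params,
                                             levels=cfg.swt_levels,
                                             wavelet=cfg.wavelet)
        assert len(train_aug) == 9 * len(train)
        with open(out / "augment_manifest.csv", "w") as fh:
            fh.write("id,label\n")
            for sid, lab in zip(train_aug.ids, train_aug.labels):
                fh.write(f"{sid},{lab}\n")
        log.info("augment: %d -> %d images (x9)", len(train), len(train_aug))

        stage = "extract"
        extractors = default_extractors(child_seed(cfg.master_seed, "extract"),
                                        n=cfg.n_extractors,
                                        output_dim=cfg.extractor_dim)
        train_fm = merge_features([extract_features(e, train_aug)
                                   for e in extractors])
        val_fm = (merge_features([extract_features(e, val) for e in extractors])
                  if len(val) else None)
        test_fm = merge_features([extract_features(e, test) for e in extractors])
        train_fm.save(out / "features.npz")
        log.info("extract: %d x %d fused training features",
                 train_fm.n_samples, train_fm.n_features)

        stage = "select"
        k_max = cfg.k_max if cfg.k_max is not None else train_fm.n_features
        k_min = min(cfg.k_min, k_max)
        # augmented variants of one source are near-duplicates, so the k-scan
        # loss is measured on the (untouched) validation split
        loss_spec = (holdout_loss(val_fm.values, val_fm.labels)
                     if val_fm is not None else None)
        sel = iterative_select(cfg.selector_method, train_fm.values,
                               train_fm.labels, k_min=k_min, k_max=k_max,
                               step=cfg.k_step, loss_spec=loss_spec,
                               seed=child_seed(cfg.master_seed, "select"))
        (out / "selection.json").write_text(json.dumps({
            "method": sel.method,
            "chosen_k": int(sel.chosen_k),
            "chosen_indices": sel.chosen_indices.tolist(),
            "k_grid": sel.k_grid.tolist(),
            "loss_curve": sel.loss_curve.tolist(),
            "ranking": sel.ranking.tolist(),
            "loss_classifier": sel.loss_classifier,
            "seed": sel.seed,
        }, indent=2))
        log.info("select: %s chose k=%d of %d", sel.method, sel.chosen_k,
                 train_fm.n_features)

        stage = "train"
        cols = sel.chosen_indices
        model = _train_head(cfg.head, train_fm.values[:, cols], train_fm.labels,
                            seed=child_seed(cfg.master_seed, "train"))
        joblib.dump(model, out / "model.joblib")
        (out / "model.json").write_text(json.dumps({
            "head": cfg.head,
            "selected_indices": cols.tolist(),
            "block_map": [list(b) for b in train_fm.block_map],
            "master_seed": cfg.master_seed,
            "config_fingerprint": fingerprint(asdict(cfg)),
        }, indent=2))

        stage = "evaluate"
        report = evaluate_holdout(model, test_fm.values[:, cols], test_fm.labels)
        report.config_fingerprint = fingerprint(asdict(cfg))
        report.extra["stage_counts"] = {
            "images_in": len(data), "train": len(train), "val": len(val),
            "test": len(test), "augmented": len(train_aug),
            "feature_rows": train_fm.n_samples, "fused_dim": train_fm.n_features,
            "selected_k": int(sel.chosen_k),
        }
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        log.info("evaluate: test accuracy %.3f%%", report.per_fold[0]["accuracy"])
        return report
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage {stage!r} (artifacts under {out}): {exc}"
        ) from exc
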