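"""End-to-end orchestration: augmentation, fine-tuning, feature extraction,
ensemble training, evaluation.

The full run performs, in order:

1. load (or generate) the labelled image data and split it per class;
2. train one GAN per class on the training split and sample synthetic
   images (skippable);
3. assemble the mixed training set (originals + synthetics); the test split
   is never augmented and is read exactly once, after all training;
4. build the frozen-trunk backbone with the six-layer head and fine-tune the
   head (skippable);
5. tap 128-dimensional features for the train and test splits;
6. train the voting ensemble of randomized networks on the training
   features;
7. evaluate on the test split and write the metric report.

A features-only mode bypasses the image stages entirely and runs the
classifier stack on synthetic Gaussian feature clouds, which is the fastest
way to exercise the ensemble and evaluation machinery.

Every artifact (synthetic images, weights, features, models, reports, run
manifest) is persisted under the configured output directory, and every
source of randomness derives from the configured seeds, so a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .backbone import BackboneModel, FeatureMatrix, TinyConvTrunk, \
    build_modified_backbone, extract_features, finetune_backbone
from .config import PipelineConfig
from .datasets import LabeledImageSet, assemble_mixed_dataset, \
    make_gaussian_features, make_synthetic_cell_images, load_image_dataset, \
    split_dataset
from .ensemble import predict_etrn, train_etrn_labels
from .gan import GANConfig, sample_images, train_bcgan, write_loss_history
from .metrics import MetricsReport, aggregate_runs, evaluate

logger = logging.getLogger(__name__)


def _load_or_make_images(cfg: PipelineConfig) -> LabeledImageSet:
    if cfg.data_root is not None:
        return load_image_dataset(cfg.data_root, image_size=cfg.image_size)
    return make_synthetic_cell_images(cfg.n_per_class, cfg.n_classes,
                                      cfg.image_size, seed=cfg.seed)


def _prepare_features(cfg: PipelineConfig, out: Path
                      ) -> tuple[FeatureMatrix, FeatureMatrix, list[str]]:
    """Stages 1-5: everything upstream of the ensemble."""
    if cfg.fixture_mode == "features" and cfg.data_root is None:
        x, y = make_gaussian_features(cfg.n_per_class, cfg.n_classes,
                                      cfg.feature_dim, cfg.separation,
                                      seed=cfg.seed)
        rng = np.random.default_rng(cfg.split.seed)
        names = [f"class_{k}" for k in range(cfg.n_classes)]
        tr_idx, te_idx = [], []
        for k in range(cfg.n_classes):
            idx = rng.permutation(np.flatnonzero(y == k))
            n_tr = int(round(cfg.split.train_fraction * len(idx)))
            tr_idx.extend(idx[:n_tr])
            te_idx.extend(idx[n_tr:])
        train = FeatureMatrix(x[tr_idx], y[tr_idx])
        test = FeatureMatrix(x[te_idx], y[te_idx])
        return train, test, names

    data = _load_or_make_images(cfg)
    train_set, test_set = split_dataset(data, cfg.split)

    if not cfg.skip_gan:
        synth_parts = []
        for k, cls in enumerate(train_set.class_names):
            t0 = time.time()
            class_imgs = train_set.subset(np.flatnonzero(train_set.labels == k))
            gan_cfg = GANConfig(**{**cfg.gan.__dict__,
                                   "seed": cfg.gan.seed + k})
            pair = train_bcgan(class_imgs, gan_cfg)
            write_loss_history(pair, out / f"gan_loss_{cls}.csv")
            part = sample_images(pair, cfg.n_synthetic_per_class, k,
                                 seed=cfg.seed + 100 + k,
                                 class_names=train_set.class_names,
                                 out_size=cfg.image_size)
            synth_parts.append(part)
            logger.info("stage gan class=%s %.1fs", cls, time.time() - t0)
        synthetic = LabeledImageSet(
            images=sum((p.images for p in synth_parts), []),
            labels=np.concatenate([p.labels for p in synth_parts]),
            class_names=list(train_set.class_names),
            provenance=["synthetic"] * sum(len(p) for p in synth_parts))
        synthetic.write_tree(out / "synthetic_images", split="train")
        train_set = assemble_mixed_dataset(train_set, synthetic)

    model = build_modified_backbone(TinyConvTrunk(cfg.trunk_dim, seed=cfg.seed),
                                    num_classes=cfg.n_classes,
                                    head_seed=cfg.seed)
    if not cfg.skip_finetune:
        t0 = time.time()
        finetune_backbone(model, train_set, cfg.finetune)
        logger.info("stage finetune %.1fs (%d batches)",
                    time.time() - t0, len(model.loss_history))
    model.save(out / "backbone")
    train_fm = extract_features(model, train_set)
    test_fm = extract_features(model, test_set)
    train_fm.to_csv(out / "features_train.csv")
    test_fm.to_csv(out / "features_test.csv")
    return train_fm, test_fm, train_set.class_names


def run_dlbcnet(cfg: PipelineConfig) -> MetricsReport:
    """One full pipeline run; returns the test-set metric report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train_fm, test_fm, names = _prepare_features(cfg, out)
    model = train_etrn_labels(train_fm.values, train_fm.labels, cfg.Z,
                              cfg.seed, n_classes=len(names),
                              class_names=names)
    model.save(out / "etrn")
    y_pred = predict_etrn(model, test_fm.values)
    report = evaluate(test_fm.labels, y_pred, names, run_id="run1")
    report.to_csv(out / "report.csv", decimals=6)
    report.to_json(out / "report.json")
    manifest = {"config": _jsonable(cfg.to_dict()), "version": __version__,
                "n_train": len(train_fm.labels), "n_test": len(test_fm.labels)}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def run_five_runs(cfg: PipelineConfig, n_runs: int = 5) -> MetricsReport:
    """Repeat ensemble training/evaluation with run-indexed seeds.

    The upstream stages (augmentation, fine-tuning, feature extraction) are
    executed once; only the random hidden layers of the ensemble members are
    re-drawn per run, which is what the run-to-run variability of these
    classifiers comes from.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train_fm, test_fm, names = _prepare_features(cfg, out)
    reports = []
    for run in range(n_runs):
        seed = cfg.seed + 1000 * run
        model = train_etrn_labels(train_fm.values, train_fm.labels, cfg.Z,
                                  seed, n_classes=len(names), class_names=names)
        y_pred = predict_etrn(model, test_fm.values)
        rep = evaluate(test_fm.labels, y_pred, names, run_id=f"run{run + 1}")
        rep.to_csv(out / f"report_run{run + 1}.csv", decimals=6)
        reports.append(rep)
    agg = aggregate_runs(reports)
    agg.to_csv(out / "report_aggregate.csv", decimals=6)
    agg.to_json(out / "report_aggregate.json")
    return agg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
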