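"""End-to-end orchestration: enhance → split → (augment) → features →
(PCA) → fuse → train → evaluate.

``run_pipeline`` is fully reproducible from (config, seed): the data
generator, split, backbone weights, label shuffling and head training
all draw from seeds derived from ``config.seed``. When ``out_dir`` is
set, the run writes its split CSV, feature CSV, metrics JSON and a
stage-timing log.
"""

from __future__ import annotations

import json
import logging
import os
import time
from typing import Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .classify import (ann_predict, svm_decision_scores, svm_predict,
                       train_ann, train_linear_svm)
from .config import PipelineConfig
from .dataset import augment_training_set, stratified_split
from .deep import extract_deep_features
from .evaluate import POSITIVE_LABEL, confusion, error_histogram, metrics, roc_auc
from .fusion import fuse, pca_fit, pca_transform
from .handcrafted import extract_handcrafted, feature_names
from .preprocessing import enhance_pipeline

__all__ = ["run_pipeline"]

log = logging.getLogger("histofusion.pipeline")


class _StageTimer:
    def __init__(self):
        self.timings: dict[str, float] = {}

    def run(self, name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        self.timings[name] = dt
        log.info("stage %-12s %8.2f s", name, dt)
        return result


def _load_data(cfg: PipelineConfig) -> synthetic.LabeledImageSet:
    if cfg.source in ("separable", "hard"):
        maker = synthetic.separable_spec if cfg.source == "separable" else synthetic.hard_spec
        spec = maker(image_size=cfg.image_size, seed=cfg.seed)
        return synthetic.generate_dataset(spec, cfg.n_per_class)
    return synthetic.read_manifest(cfg.source)


def _shuffle_labels(labels: Sequence[str], phases: Sequence[str], seed: int) -> list[str]:
    """Permute the train+val labels among themselves; test labels stay."""
    rng = np.random.default_rng(seed)
    labels = list(labels)
    idx = [i for i, p in enumerate(phases) if p in ("train", "val")]
    vals = [labels[i] for i in idx]
    order = rng.permutation(len(vals))
    for i, j in zip(idx, order):
        labels[i] = vals[j]
    return labels


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured pipeline and return the metrics report.

    The report dictionary contains the confusion counts, the percent
    metric panel (with the trapezoidal ROC AUC as the headline AUC), the
    feature widths actually used, split counts and stage timings.
    """
    timer = _StageTimer()
    data = timer.run("load", _load_data, cfg)

    enhanced = timer.run(
        "enhance",
        lambda: [enhance_pipeline(img, sigma=cfg.sigma, size=cfg.kernel_size,
                                  sign=cfg.enhance_sign) for img in data.images],
    )

    split = timer.run("split", stratified_split,
                      dict(zip(data.ids, data.labels)), cfg.seed)
    phases = [split.phase[i] for i in data.ids]

    labels = list(data.labels)
    if cfg.shuffle_labels:
        labels = _shuffle_labels(labels, phases, cfg.seed + 17)

    train_imgs = [im for im, p in zip(enhanced, phases) if p == "train"]
    train_lbls = [l for l, p in zip(labels, phases) if p == "train"]
    train_ids = [i for i, p in zip(data.ids, phases) if p == "train"]
    if cfg.augment:
        aug = timer.run(
            "augment", augment_training_set,
            synthetic.LabeledImageSet(images=train_imgs, labels=train_lbls,
                                      ids=train_ids),
            split,
        )
        train_imgs = train_imgs + aug.images
        train_lbls = train_lbls + aug.labels
        train_ids = train_ids + aug.ids

    val_imgs = [im for im, p in zip(enhanced, phases) if p == "val"]
    val_lbls = [l for l, p in zip(labels, phases) if p == "val"]
    test_imgs = [im for im, p in zip(enhanced, phases) if p == "test"]
    test_lbls = [l for l, p in zip(labels, phases) if p == "test"]
    test_ids = [i for i, p in zip(data.ids, phases) if p == "test"]

    def _features(images):
        blocks = {}
        if cfg.features in ("deep", "fused"):
            blocks["deep"] = extract_deep_features(images, cfg.backbone_spec())
        if cfg.features in ("handcrafted", "fused"):
            blocks["hand"] = extract_handcrafted(images)
        return blocks

    f_train = timer.run("features_train", _features, train_imgs)
    f_val = timer.run("features_val", _features, val_imgs)
    f_test = timer.run("features_test", _features, test_imgs)

    pca_model = None
    if cfg.features in ("deep", "fused"):
        if cfg.pca_fit_on == "train":
            fit_rows = f_train["deep"]
        else:
            fit_rows = np.vstack([f_train["deep"], f_val["deep"], f_test["deep"]])
        pca_model = timer.run("pca", pca_fit, fit_rows, cfg.pca_components)
        for f in (f_train, f_val, f_test):
            f["deep_pca"] = pca_transform(pca_model, f["deep"])

    def _assemble(blocks):
        if cfg.features == "deep":
            return blocks["deep_pca"]
        if cfg.features == "handcrafted":
            return blocks["hand"]
        return fuse(blocks["deep_pca"], blocks["hand"]).values

    X_train = _assemble(f_train)
    X_val = _assemble(f_val)
    X_test = _assemble(f_test)

    if cfg.head == "svm":
        model = timer.run("train", train_linear_svm, X_train, train_lbls, cfg.svm_C)
        y_pred = svm_predict(model, X_test)
        raw = svm_decision_scores(model, X_test)
        scores = 1.0 / (1.0 + np.exp(-raw))      # positive-class score for ROC
        extra = {}
    else:
        model = timer.run("train", train_ann, X_train, train_lbls,
                          cfg.train_config(), X_val, val_lbls)
        y_pred, probs = ann_predict(model, X_test)
        scores = probs[:, model.classes.index(POSITIVE_LABEL)
                       if POSITIVE_LABEL in model.classes else 1]
        extra = {"stop_reason": model.stop_reason, "best_epoch": model.best_epoch,
                 "epochs_run": len(model.train_loss)}

    cm = confusion(test_lbls, y_pred)
    panel = metrics(cm)
    panel.roc_auc = roc_auc(test_lbls, scores) if len(set(test_lbls)) == 2 else None
    targets = np.array([1.0 if l == POSITIVE_LABEL else 0.0 for l in test_lbls])
    edges, counts = error_histogram(targets, scores)

    report = {
        "config": cfg.as_dict(),
        "counts": {
            "n_images": len(data),
            "n_train": len(train_imgs),
            "n_val": len(val_imgs),
            "n_test": len(test_imgs),
            "per_class": split.counts(dict(zip(data.ids, data.labels))),
        },
        "feature_width": int(X_train.shape[1]),
        "pca_components": int(pca_model.k) if pca_model is not None else None,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "metrics": panel.as_dict(),
        "error_histogram": {"edges": edges.tolist(), "counts": counts.tolist()},
        "timings_s": timer.timings,
    }
    report.update(extra)

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        pd.DataFrame({"id": list(split.phase), "phase": list(split.phase.values())}) \
            .to_csv(os.path.join(cfg.out_dir, "split.csv"), index=False)
        if "hand" in f_test:
            pd.DataFrame(f_test["hand"], columns=feature_names(), index=test_ids) \
                .to_csv(os.path.join(cfg.out_dir, "handcrafted_test.csv"))
        with open(os.path.join(cfg.out_dir, "metrics.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    return report
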