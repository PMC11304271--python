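"""End-to-end workflow: simulate -> qc -> pretrain -> distill -> evaluate.

:func:`run_pipeline` chains the stages, writes every artifact (dataset,
checkpoints, histories, feature tables, summary JSON stamped with the config
hash and seed) under an output directory, and returns the summary dict.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import (
    BackboneConfig,
    TrainConfig,
    build_backbone,
    pretrain_backbone,
    save_model,
)
from .distillator import (
    ClassifierTrainConfig,
    DenseClassifier,
    LossWeights,
    _fit_classifier,
    _onehot,
    pretrain_classifiers,
    train_cytomad,
)
from .features import PHOTOMETRIC_FEATURES, extract_features_table
from .io import write_dataset
from .metrics import (
    across_batch_classify,
    batch_distance,
    correction_ratio,
    rmse_cell,
    ssim_cell,
)
from .qc import GateSpec, gate_dataset
from .synthetic import Dataset, SimConfig, default_sim_config, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "demo_run_config"]

log = logging.getLogger("cytomad")


@dataclass
class RunConfig:
    outdir: str
    sim: SimConfig
    backbone: BackboneConfig
    pretrain: TrainConfig
    distill: TrainConfig
    gates: GateSpec | None = None
    weights: LossWeights = field(default_factory=LossWeights)
    classifier: ClassifierTrainConfig = field(default_factory=ClassifierTrainConfig)
    retrain_interval_epochs: int = 10
    batch_loss: str = "confusion"
    holdout_train_batch: str | None = None  # default: first batch
    eval_classifier_epochs: int = 60
    seed: int = 0

    def config_hash(self) -> str:
        """Stamp of the scientific configuration (output location excluded)."""
        d = _as_jsonable(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def demo_run_config(outdir: str, seed: int = 0, n_cells: int = 100) -> RunConfig:
    """The reference desk-scale demonstration (2 types x 3 batches, 32 px)."""
    return RunConfig(
        outdir=outdir,
        sim=default_sim_config(
            n_cells_per_type_per_batch=n_cells, image_size_px=32, seed=seed
        ),
        backbone=BackboneConfig(
            image_size_px=32, bottleneck_dim=64, n_levels=3, base_filters=12
        ),
        pretrain=TrainConfig(epochs=8, minibatch_size=16, seed=seed + 1),
        distill=TrainConfig(epochs=10, minibatch_size=16, seed=seed + 2),
        gates=GateSpec(min_area_px=20),
        classifier=ClassifierTrainConfig(
            epochs=15, refit_epochs=5, seed=seed + 3
        ),
        retrain_interval_epochs=1,
        eval_classifier_epochs=40,
        seed=seed,
    )


def _split_classify_accuracy(
    x_train, y_train, x_test, y_test, epochs, seed
) -> float:
    """Accuracy of a fresh dense classifier (75/50/25) on held-out cells."""
    classes = sorted(set(y_train) | set(y_test))
    rng = np.random.default_rng(seed)
    clf = DenseClassifier(x_train.shape[1], len(classes), rng)
    cfg = ClassifierTrainConfig(epochs=epochs, seed=seed)
    _fit_classifier(clf, x_train, _onehot(y_train, classes), cfg, rng)
    pred = clf.predict(np.asarray(x_test, dtype=np.float32))
    y_idx = np.asarray([classes.index(v) for v in y_test])
    return float((pred == y_idx).mean())


def _stage_metrics(model, dataset: Dataset, test: Dataset) -> dict:
    """SSIM/RMSE of translated test images against the clean targets."""
    _, pred = model.infer(test.bf)
    ssims, rmses = [], []
    for i, pair in enumerate(test.pairs):
        ssims.append(ssim_cell(pred[i], pair.qpi_clean, pair.mask))
        rmses.append(rmse_cell(pred[i], pair.qpi_clean, pair.mask))
    return {"ssim_mean": float(np.mean(ssims)), "rmse_mean": float(np.mean(rmses))}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the summary dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }

    # ---- simulate ------------------------------------------------------
    log.info("simulate: %s", cfg.sim)
    dataset = generate_dataset(cfg.sim)
    write_dataset(dataset, out / "dataset.h5", out / "metadata.csv")
    summary["stages"]["simulate"] = {"n_cells": len(dataset)}

    # ---- qc ------------------------------------------------------------
    if cfg.gates is not None:
        dataset, qc_summary = gate_dataset(dataset, cfg.gates)
        qc_summary.to_csv(out / "qc_summary.csv", index=False)
        summary["stages"]["qc"] = {"n_survivors": len(dataset)}

    meta = dataset.meta
    train = dataset.subset((meta["split"] == "train").to_numpy())
    test = dataset.subset((meta["split"] == "test").to_numpy())

    # ---- pretrain (no-CytoMAD stage) ------------------------------------
    model = build_backbone(cfg.backbone, seed=cfg.seed)
    model, pre_hist = pretrain_backbone(
        model, train, cfg.pretrain, (cfg.weights.W_gen, cfg.weights.W_dis)
    )
    pre_hist.to_csv(out / "pretrain_history.csv", index=False)
    save_model(model, str(out / "model_no_cytomad"))
    profiles_no = model.infer(dataset.bf)[0]
    summary["stages"]["pretrain"] = {
        "epochs": cfg.pretrain.epochs,
        **_stage_metrics(model, dataset, test),
    }
    no_cyto_metrics = summary["stages"]["pretrain"]

    # ---- classifier pretraining + distillation --------------------------
    train_profiles, train_images = model.infer(train.bf)
    cs = pretrain_classifiers(
        train_profiles,
        train_images,
        train.meta["batch_id"].to_numpy(),
        train.meta["cell_type"].to_numpy(),
        cfg.classifier,
    )
    model, distill_hist = train_cytomad(
        model,
        cs,
        train,
        cfg.distill,
        cfg.weights,
        retrain_interval_epochs=cfg.retrain_interval_epochs,
        batch_loss=cfg.batch_loss,
    )
    distill_hist.to_csv(out / "distill_history.csv", index=False)
    save_model(model, str(out / "model_cytomad"))
    profiles_cyto, images_cyto = model.infer(dataset.bf)
    summary["stages"]["distill"] = {
        "epochs": cfg.distill.epochs,
        **_stage_metrics(model, dataset, test),
    }

    # ---- evaluation -----------------------------------------------------
    batch_ids = meta["batch_id"].to_numpy()
    type_labels = meta["cell_type"].to_numpy()
    train_batch = cfg.holdout_train_batch or meta["batch_id"].iloc[0]

    res_no = across_batch_classify(
        profiles_no, type_labels, batch_ids, [train_batch],
        epochs=cfg.eval_classifier_epochs, seed=cfg.seed + 11,
    )
    res_cyto = across_batch_classify(
        profiles_cyto, type_labels, batch_ids, [train_batch],
        epochs=cfg.eval_classifier_epochs, seed=cfg.seed + 11,
    )
    res_cyto.confusion_matrix.to_csv(out / "confusion_cytomad.csv")

    train_sel = (meta["split"] == "train").to_numpy()
    test_sel = (meta["split"] == "test").to_numpy()
    held_sel = ~train_sel  # val + test: larger held-out set for accuracy
    batch_acc_no = _split_classify_accuracy(
        profiles_no[train_sel], batch_ids[train_sel],
        profiles_no[held_sel], batch_ids[held_sel],
        cfg.eval_classifier_epochs, cfg.seed + 12,
    )
    batch_acc_cyto = _split_classify_accuracy(
        profiles_cyto[train_sel], batch_ids[train_sel],
        profiles_cyto[held_sel], batch_ids[held_sel],
        cfg.eval_classifier_epochs, cfg.seed + 12,
    )

    feats_before = extract_features_table(
        test.bf, test.qpi, test.masks, cell_ids=test.meta["cell_id"]
    )
    feats_after = extract_features_table(
        test.bf, images_cyto[test_sel], test.masks,
        cell_ids=test.meta["cell_id"], provenance="cytomad",
    )
    feats_after.to_csv(out / "features_cytomad.csv")
    test_batches = test.meta["batch_id"].to_numpy()
    dist_before = batch_distance(feats_before, test_batches)
    dist_after = batch_distance(feats_after, test_batches)
    ratio, _flag = correction_ratio(dist_before, dist_after)
    pd.DataFrame(
        {"distance_before": dist_before, "distance_after": dist_after,
         "correction_ratio": ratio}
    ).to_csv(out / "batch_distance.csv")

    summary["stages"]["evaluate"] = {
        "ssim_mean_no_cytomad": no_cyto_metrics["ssim_mean"],
        "ssim_mean_cytomad": summary["stages"]["distill"]["ssim_mean"],
        "rmse_mean_no_cytomad": no_cyto_metrics["rmse_mean"],
        "rmse_mean_cytomad": summary["stages"]["distill"]["rmse_mean"],
        "holdout_type_accuracy_no_cytomad": res_no.overall_accuracy,
        "holdout_type_accuracy_cytomad": res_cyto.overall_accuracy,
        "batch_accuracy_no_cytomad": batch_acc_no,
        "batch_accuracy_cytomad": batch_acc_cyto,
        "correction_ratio_median": float(ratio.median()),
        "correction_ratio_median_photometric": float(
            ratio[PHOTOMETRIC_FEATURES].median()
        ),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
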