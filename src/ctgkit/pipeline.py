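"""End-to-end orchestration: simulate -> preprocess -> render/sequence ->
train -> evaluate.

``run_end_to_end`` is the programmatic core behind ``ctgkit run``; it works
at a configurable scale (record count, image downsampling, filter widths,
epochs) so desk-scale experiments finish in minutes on one CPU.  Full-scale
geometry (120 x 2400 rasters, filters 8/16/32, 70 epochs) is the same code
path with different numbers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ctgkit import baselines, evaluate, models
from ctgkit.preprocess import CleanSignal, QCConfig, run_pipeline
from ctgkit.render import clip_range, downsample, render_image
from ctgkit.simulate import (
    SimParams,
    abnormal_params,
    derive_feature_vector,
    simulate_dataset,
)

log = logging.getLogger("ctgkit")


@dataclass
class RunConfig:
    """Parameters of one end-to-end run; the seed reaches every stage."""

    n_records: int = 400
    class_balance: float = 0.5
    seed: int = 0
    qc: QCConfig = field(default_factory=QCConfig)
    arch: str = "mknet-a"
    epochs: int = 8
    batch_size: int = 32
    learning_rate: float = 1e-3
    augmentation: bool = False
    # reduced training geometry: 120x2400 rasters block-pooled by these factors
    image_downsample: tuple = (4, 8)
    filters: tuple = (4, 8, 16)
    fc_units: tuple = (32, 16, 8)
    rnn_time_step_stride: int = 30  # 2400 -> 80 steps for the LSTM
    params_class0: Optional[SimParams] = None
    params_class1: Optional[SimParams] = None


@dataclass
class RunResult:
    n_input: int
    n_rejected: int
    n_clean: int
    neural: dict
    svm: dict
    rf: dict

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def preprocess_records(records, qc: QCConfig):
    """Run the QC/repair pipeline; returns (clean signals, their labels,
    rejected-count)."""
    clean, labels, rejected = [], [], 0
    for rec in records:
        out = run_pipeline(rec, qc)
        if isinstance(out, CleanSignal):
            clean.append(out)
            labels.append(rec.label)
        else:
            rejected += 1
    return clean, np.asarray(labels, dtype=int), rejected


def images_from_clean(clean_signals, downsample_blocks=None) -> np.ndarray:
    """Render every clean trace; optionally block-pool for reduced-scale
    training."""
    imgs = []
    for cs in clean_signals:
        img = render_image(clip_range(cs.values), source_id=cs.source_id)
        px = img.pixels.astype(np.float32)
        if downsample_blocks is not None:
            px = downsample(img.pixels, *downsample_blocks)
        imgs.append(px)
    return np.stack(imgs)


def sequences_from_clean(clean_signals, stride: int = 1) -> np.ndarray:
    """Clipped, [0,1]-scaled traces (optionally time-decimated) for MKRNN."""
    seqs = np.stack([clip_range(cs.values)[::stride] for cs in clean_signals])
    return models.scale_sequences(seqs)


def run_end_to_end(cfg: RunConfig) -> RunResult:
    p0 = cfg.params_class0 or SimParams(seed=cfg.seed)
    p1 = cfg.params_class1 or abnormal_params(p0, seed=cfg.seed)
    records = simulate_dataset(
        cfg.n_records, cfg.class_balance, p0, p1, seed=cfg.seed
    )
    log.info("simulated %d records", len(records))

    clean, labels, rejected = preprocess_records(records, cfg.qc)
    log.info("preprocessing kept %d, rejected %d", len(clean), rejected)

    # neural model on images or sequences, 60/20/20 holdout
    if cfg.arch.startswith("mknet"):
        X = images_from_clean(clean, cfg.image_downsample)
        variant = cfg.arch.split("-")[-1]
        h, w = X.shape[1:3]
        spec = models.build_mknet(
            variant, filters=cfg.filters, fc_units=cfg.fc_units,
            input_shape=(h, w, 1),
        )
    elif cfg.arch == "mkrnn":
        X = sequences_from_clean(clean, stride=cfg.rnn_time_step_stride)
        spec = models.build_mkrnn(units=32, time_steps=X.shape[1])
    else:
        raise ValueError(f"unknown arch {cfg.arch!r}")

    tr, te, va = evaluate.split_dataset(
        labels, evaluate.SplitSpec(seed=cfg.seed)
    )
    tcfg = models.TrainConfig(
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        augmentation=cfg.augmentation,
        seed=cfg.seed,
    )
    model = models.train(
        spec, X[tr], labels[tr], tcfg, validation=(X[va], labels[va])
    )
    probs = models.predict_proba(model, X[te])
    y_pred = probs.argmax(axis=1)
    m = evaluate.compute_metrics(labels[te], y_pred)
    roc = evaluate.roc_curve_auc(labels[te], probs[:, 1])
    neural = {
        "arch": cfg.arch,
        "holdout_accuracy": m.accuracy,
        "holdout_auc": roc.auc,
        "avg_f1": m.avg_f1,
        "history": model.history,
    }
    log.info("%s holdout accuracy %.3f, AUC %.3f", cfg.arch, m.accuracy, roc.auc)

    # feature baselines, stratified 5-fold CV on the full corpus
    features = [
        derive_feature_vector(cs.values, label=lab)
        for cs, lab in zip(clean, labels)
    ]
    Xf = np.asarray([fv.as_row()[:-1] for fv in features], dtype=float)

    svm_report = _baseline_report(Xf, labels, "svm", cfg.seed)
    rf_report = _baseline_report(Xf, labels, "rf", cfg.seed)

    return RunResult(
        n_input=len(records),
        n_rejected=rejected,
        n_clean=len(clean),
        neural=neural,
        svm=svm_report,
        rf=rf_report,
    )


class _BaselinePredictor:
    """SVM (grid-searched per training fold, as in the source protocol) or
    random forest on the feature table."""

    def __init__(self, method: str, seed: int, grid: bool = True):
        self.method = method
        self.seed = seed
        self.grid = grid
        self._clf = None

    def fit(self, X, y):
        if self.method == "svm":
            min_support = int(np.bincount(np.asarray(y, dtype=int)).min())
            if self.grid and min_support >= 2:
                spec = baselines.GridSearchSpec(folds=min(5, min_support))
                best = baselines.grid_search(X, y, spec, seed=self.seed)
                self._clf = baselines.fit_svm(
                    X, y, kernel=best["kernel"], C=best["C"], gamma=best["gamma"]
                )
            else:
                self._clf = baselines.fit_svm(X, y)
        else:
            self._clf = baselines.fit_rf(X, y, seed=self.seed)
        return self

    def predict(self, X):
        return self._clf.predict(X)

    def score(self, X):
        if hasattr(self._clf, "predict_proba"):
            return self._clf.predict_proba(X)[:, 1]
        return self._clf.decision_function(X)


def _baseline_report(Xf, labels, method: str, seed: int) -> dict:
    report = evaluate.evaluate_model(
        lambda: _BaselinePredictor(method, seed),
        Xf,
        labels,
        protocol="kfold5",
        seed=seed,
    )
    s = report.summary()
    log.info("%s 5-fold accuracy %.3f, mean AUC %.3f",
             method, s["accuracy_mean"], s["mean_auc"])
    return {
        "cv_accuracy": s["accuracy_mean"],
        "mean_auc": s["mean_auc"],
        "per_fold_accuracy": s["accuracy_per_fold"],
    }
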