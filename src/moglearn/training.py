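"""Training loop, cross-validation folds, and classification metrics.

Training follows a fixed optimization protocol: Adam at an initial
learning rate of 0.001, 100 epochs of full-batch gradient steps on the
cross-entropy of the training nodes/graphs, and a reduce-on-plateau
schedule driven by validation accuracy.  Evaluation reports accuracy and
macro-averaged precision, recall, F1, one-vs-rest ROC-AUC and AUPR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from .nn.models import BaseModel, GraphBatch
from .nn.optim import Adam, ReduceLROnPlateau

METRICS = ("accuracy", "precision", "recall", "f1", "roc_auc", "aupr")


@dataclass
class TrainConfig:
    """Optimization settings (Adam, 0.001, 100 epochs, plateau schedule)."""

    learning_rate: float = 0.001
    epochs: int = 100
    scheduler_factor: float = 0.5
    scheduler_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass
class FoldMasks:
    """Stratified k-fold masks; within each fold the non-test portion is
    split 80/20 into train/validation (stratified)."""

    folds: list = field(default_factory=list)  # (train, val, test) bool arrays

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_folds(labels, k: int = 5, seed: int = 0, val_fraction: float = 0.2) -> FoldMasks:
    """Stratified k-fold train/validation/test masks over samples."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < k]
    if too_small.size:
        raise ValueError(
            f"classes with fewer than k={k} members: {too_small.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (nontest, test) in enumerate(skf.split(np.zeros_like(y), y)):
        train_idx, val_idx = train_test_split(
            nontest,
            test_size=val_fraction,
            stratify=y[nontest],
            random_state=seed + 1000 * (i + 1),
        )
        train = np.zeros(y.size, dtype=bool)
        val = np.zeros(y.size, dtype=bool)
        tst = np.zeros(y.size, dtype=bool)
        train[train_idx] = True
        val[val_idx] = True
        tst[test] = True
        folds.append((train, val, tst))
    return FoldMasks(folds)


def train_model(
    model: BaseModel,
    batch: GraphBatch,
    y: np.ndarray,
    masks: tuple,
    config: TrainConfig,
) -> pd.DataFrame:
    """Train in place; returns the per-epoch history.

    ``masks`` is one fold's (train, val, test) boolean triple over the
    rows the model's logits correspond to (nodes in node mode, graphs in
    graph mode).  Aborts with a diagnostic on non-finite loss.
    """
    train_mask, val_mask, _ = masks
    y = np.asarray(y)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    sched = ReduceLROnPlateau(
        opt, mode="max", factor=config.scheduler_factor, patience=config.scheduler_patience
    )
    rng = np.random.default_rng(config.seed)
    records = []
    for epoch in range(config.epochs):
        model.zero_grad()
        loss, dlogits = model.loss_and_grad(batch, y, train_mask, training=True, rng=rng)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}: {loss}")
        model.backward(dlogits)
        opt.step()
        if val_mask.any():
            proba = model.predict_proba(batch)
            val_acc = float((proba[val_mask].argmax(axis=1) == y[val_mask]).mean())
        else:
            val_acc = np.nan
        sched.step(val_acc)
        records.append({"epoch": epoch, "loss": loss, "val_accuracy": val_acc, "lr": opt.lr})
    return pd.DataFrame(records)


def compute_metrics(y_true: np.ndarray, proba: np.ndarray, classes=None) -> dict:
    """The six metrics from predicted class probabilities.

    Macro averages skip (with a warning) classes absent from ``y_true``.
    """
    y_true = np.asarray(y_true)
    n_classes = proba.shape[1]
    all_classes = np.arange(n_classes) if classes is None else np.asarray(classes)
    present = np.intersect1d(np.unique(y_true), all_classes)
    if present.size < all_classes.size:
        missing = np.setdiff1d(all_classes, present)
        warnings.warn(
            f"classes absent from evaluation mask skipped in macro averages: "
            f"{missing.tolist()}",
            stacklevel=2,
        )
    y_pred = proba.argmax(axis=1)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="macro", zero_division=0
    )
    aucs, auprs = [], []
    for c in present:
        pos = y_true == c
        if pos.all() or not pos.any():
            continue
        aucs.append(roc_auc_score(pos, proba[:, c]))
        auprs.append(average_precision_score(pos, proba[:, c]))
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
        "roc_auc": float(np.mean(aucs)) if aucs else np.nan,
        "aupr": float(np.mean(auprs)) if auprs else np.nan,
    }


def evaluate(model: BaseModel, batch: GraphBatch, y: np.ndarray, mask: np.ndarray) -> dict:
    """One metrics-table row for the rows selected by ``mask``."""
    proba = model.predict_proba(batch)
    return compute_metrics(np.asarray(y)[mask], proba[mask])


def aggregate_metrics(rows: pd.DataFrame, by=("combination", "architecture")) -> pd.DataFrame:
    """Mean +/- sd over folds for every configuration."""
    agg = rows.groupby(list(by))[list(METRICS)].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg
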