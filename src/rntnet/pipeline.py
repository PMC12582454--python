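"""Training loop, dataset splitting, cross-validation, ablation arms and the
patch-size sweep.

The training protocol follows the published settings (Adam, initial learning
rate 1e-4, batch size 64, fixed epoch budget, categorical cross-entropy).
Splitting is stratified — classes are balanced in the target datasets, so
stratified and simple random splits nearly coincide, and stratified is
testable.  Best-checkpoint selection by validation accuracy is an addition
over the fixed-epoch protocol and is flagged in the run log.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .config import SplitSpec, TrainConfig
from .metrics import MetricsReport, classification_metrics, confusion_matrix, roc_auc
from .model import RNTNet
from .nn import Adam, softmax_cross_entropy

logger = logging.getLogger("rntnet")

__all__ = [
    "split_dataset", "train", "FoldResult", "cross_validate",
    "average_fold_metrics", "patch_size_sweep", "ablation_estimator",
    "ABLATION_ARMS",
]


def split_dataset(labels: Sequence[int], spec: SplitSpec
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation index split.

    The train set has exactly ``floor(train_fraction * n)`` members and
    per-class proportions are preserved within one item (largest-remainder
    apportionment).  Reproducible from ``spec.seed``.
    """
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("empty dataset")
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 1):
        raise ValueError("every class needs at least one item")
    rng = np.random.default_rng(spec.seed)
    n_train = int(np.floor(spec.train_fraction * y.size))
    if not spec.stratified:
        perm = rng.permutation(y.size)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    quota = {c: int(np.floor(spec.train_fraction * nc))
             for c, nc in zip(classes, counts)}
    remainder = sorted(
        classes, key=lambda c: -(spec.train_fraction * np.sum(y == c) - quota[c]))
    i = 0
    while sum(quota.values()) < n_train:
        quota[remainder[i % len(remainder)]] += 1
        i += 1
    train_idx, val_idx = [], []
    for c in classes:
        idx = rng.permutation(np.flatnonzero(y == c))
        train_idx.extend(idx[:quota[c]])
        val_idx.extend(idx[quota[c]:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def train(model: RNTNet, train_data, val_data, cfg: TrainConfig,
          early_stop_acc: Optional[float] = None) -> Tuple[Dict, Dict]:
    """Mini-batch training; returns ``(history, best_state)``.

    ``train_data``/``val_data`` are ``(X, y)`` with X standardized NCHW
    float32.  Per-epoch train/val loss and accuracy are logged; the state
    dict with the best validation accuracy is kept.  A non-finite loss
    aborts with a diagnostic naming the learning rate and batch index.
    ``early_stop_acc`` stops once validation accuracy reaches the threshold
    (used by desk-scale sanity jobs; None reproduces the fixed-epoch
    protocol).
    """
    x_tr, y_tr = train_data
    x_val, y_val = val_data
    if len(x_tr) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    n_classes = model.cfg.head.n_classes
    eye = np.eye(n_classes, dtype=np.float32)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    logger.info(
        "train start: optimizer=%s lr=%g epochs=%d batch_size=%d seed=%d "
        "(best-checkpoint selection by val accuracy is an addition to the "
        "fixed-epoch protocol)",
        cfg.optimizer, cfg.learning_rate, cfg.epochs, cfg.batch_size, cfg.seed)
    history: Dict[str, list] = {"train_loss": [], "train_acc": [],
                                "val_loss": [], "val_acc": []}
    best = {"val_acc": -1.0, "state": None, "epoch": -1}
    for epoch in range(cfg.epochs):
        t0 = time.time()
        model.train()
        order = rng.permutation(len(x_tr))
        tot_loss = tot_correct = 0.0
        for bi, start in enumerate(range(0, len(order), cfg.batch_size)):
            sel = order[start:start + cfg.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            logits = model.forward(xb)
            loss = softmax_cross_entropy(logits, eye[yb])
            lval = float(loss.numpy())
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} batch {bi} "
                    f"(lr={cfg.learning_rate})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot_loss += lval * len(sel)
            tot_correct += (logits.numpy().argmax(axis=1) == yb).sum()
        train_loss = tot_loss / len(order)
        train_acc = tot_correct / len(order)
        val_probs = model.predict_proba(x_val, batch_size=cfg.batch_size)
        val_loss = float(-np.log(np.maximum(
            val_probs[np.arange(len(y_val)), y_val], 1e-12)).mean())
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        history["train_loss"].append(train_loss)
        history["train_acc"].append(float(train_acc))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        logger.info("epoch %d/%d: train_loss=%.4f train_acc=%.4f val_loss=%.4f "
                    "val_acc=%.4f (%.1fs)", epoch + 1, cfg.epochs, train_loss,
                    train_acc, val_loss, val_acc, time.time() - t0)
        if val_acc > best["val_acc"]:
            best = {"val_acc": val_acc, "state": model.state_dict(),
                    "epoch": epoch}
        if early_stop_acc is not None and val_acc >= early_stop_acc:
            logger.info("early stop: val accuracy %.3f reached threshold %.3f",
                        val_acc, early_stop_acc)
            break
    return history, best


@dataclass
class FoldResult:
    fold_id: int
    metrics: MetricsReport
    history: Dict[str, list] = field(default_factory=dict)


def average_fold_metrics(reports: Sequence[MetricsReport]) -> Dict[str, float]:
    """Arithmetic mean of each metric column across folds."""
    keys = ("accuracy", "precision", "recall", "f1", "kappa")
    out = {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}
    aucs = [r.auc for r in reports if np.isfinite(r.auc)]
    out["auc"] = float(np.mean(aucs)) if aucs else float("nan")
    return out


def cross_validate(x: np.ndarray, y: np.ndarray, k: int = 5,
                   estimator=None, seed: int = 0
                   ) -> Tuple[List[FoldResult], Dict[str, float]]:
    """Stratified k-fold cross-validation of an estimator.

    Every sample is validated exactly once; fold sizes differ by at most 1.
    Returns per-fold results and the arithmetic-mean row.
    """
    y = np.asarray(y)
    if k > y.size:
        raise ValueError(f"k={k} exceeds dataset size {y.size}")
    if estimator is None:
        from .estimator import RNTNetClassifier
        estimator = RNTNetClassifier(preset="reduced", random_state=seed)
    from sklearn.base import clone
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: List[FoldResult] = []
    for fold_id, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y), start=1):
        est = clone(estimator)
        est.fit(x[tr], y[tr])
        probs = est.predict_proba(x[va])
        pred = probs.argmax(axis=1)
        cm = confusion_matrix(y[va], pred, len(est.classes_))
        report = classification_metrics(cm)
        try:
            report.auc = roc_auc(y[va], probs)["micro"]
        except ValueError:
            pass
        folds.append(FoldResult(fold_id, report,
                                getattr(est, "history_", {})))
        logger.info("fold %d/%d: accuracy=%.4f", fold_id, k, report.accuracy)
    return folds, average_fold_metrics([f.metrics for f in folds])


def patch_cells_for_pixels(size_px: int, total_stride: int, grid_side: int) -> int:
    """Pixel patch size -> token-grid cells: clamp(round(px / stride), 1, side)."""
    return int(np.clip(round(size_px / total_stride), 1, grid_side))


def patch_size_sweep(x: np.ndarray, y: np.ndarray,
                     sizes: Sequence[int] = (4, 8, 16, 64, 128),
                     estimator=None, seed: int = 0) -> List[dict]:
    """Train/evaluate once per patch size, all other settings fixed.

    Pixel sizes are mapped to token-grid cells through the backbone's total
    stride of 32; several small pixel sizes can collapse onto the same cell
    count, which is logged.  One result row per attempted size.
    """
    from sklearn.base import clone
    from .estimator import RNTNetClassifier
    if estimator is None:
        estimator = RNTNetClassifier(preset="reduced", random_state=seed)
    image_size = estimator.get_params()["image_size"]
    grid_side = -(-image_size // 32)
    rows: List[dict] = []
    seen: Dict[int, int] = {}
    for size_px in sizes:
        cells = patch_cells_for_pixels(size_px, 32, grid_side)
        if cells in seen:
            logger.warning("patch size %dpx maps to %d cells, same as %dpx",
                           size_px, cells, seen[cells])
        seen.setdefault(cells, size_px)
        try:
            est = clone(estimator).set_params(patch_cells=cells)
            tr, va = split_dataset(y, SplitSpec(seed=seed))
            est.fit(x[tr], y[tr])
            probs = est.predict_proba(x[va])
            cm = confusion_matrix(y[va], probs.argmax(axis=1), len(est.classes_))
            report = classification_metrics(cm)
            rows.append({"size_px": size_px, "patch_cells": cells,
                         "metrics": report})
        except ValueError as exc:  # unmappable size: skip with a warning
            logger.warning("patch size %dpx skipped: %s", size_px, exc)
    return rows


ABLATION_ARMS = ("backbone", "encoder", "mhsa", "oba", "ga", "oba+ga")


def ablation_estimator(arm: str, **params):
    """Estimator for one ablation arm, constructible from config alone."""
    from .estimator import RNTNetClassifier
    if arm not in ABLATION_ARMS:
        raise ValueError(f"unknown ablation arm {arm!r}; one of {ABLATION_ARMS}")
    if arm in ("backbone", "encoder"):
        return RNTNetClassifier(arm=arm, **params)
    return RNTNetClassifier(arm="full", attention_variant=arm, **params)
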