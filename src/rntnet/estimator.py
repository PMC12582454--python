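"""Scikit-learn style estimator wrapping the full model and training loop.

``RNTNetClassifier`` follows the sklearn estimator contract — ``fit`` /
``predict`` / ``predict_proba`` / ``get_params`` / ``set_params``, fitted
attributes with a trailing underscore — so it composes with sklearn
pipelines, ``clone`` and model selection.  ``X`` is a (n, h, w, 3) uint8 (or
[0, 255] float) image batch; images are resized to ``image_size`` and
standardized internally.
"""
from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import (ModelConfig, SplitSpec, TrainConfig, default_model_config,
                     reduced_model_config)
from .data import resize_batch, standardize
from .model import RNTNet, assemble_rntnet

__all__ = ["RNTNetClassifier"]


class RNTNetClassifier(BaseEstimator, ClassifierMixin):
    """Hybrid residual/mixed-attention image classifier.

    Parameters
    ----------
    preset : {"reduced", "full"}
        Architecture scale. ``"full"`` is the calibrated published-size
        configuration; ``"reduced"`` divides all widths by 4 with a single
        encoder layer (CPU-scale).
    arm : {"full", "backbone", "encoder"}
        Ablation arm: whole model, feature extractor only, or encoder only.
    attention_variant : {"mhsa", "oba", "ga", "oba+ga"}
        Attention branches of the encoder.
    val_fraction : float
        Fraction held out (stratified) from ``fit`` data for per-epoch
        validation and best-checkpoint selection.
    early_stop_acc : float or None
        Stop training once validation accuracy reaches this threshold.
    """

    def __init__(self, preset: str = "reduced", arm: str = "full",
                 attention_variant: str = "oba+ga", patch_cells: int = 1,
                 block_size: int = 4, block_stride: int = 2,
                 grid_count: int = 2, softmax_attention: bool = True,
                 embed_dim: Optional[int] = None, depth: Optional[int] = None,
                 hidden_units: int = 256, dropout_rate: float = 0.2,
                 learning_rate: float = 1e-4, epochs: int = 180,
                 batch_size: int = 64, image_size: int = 300,
                 val_fraction: float = 0.2,
                 early_stop_acc: Optional[float] = None,
                 random_state: int = 0, verbose: int = 0):
        self.preset = preset
        self.arm = arm
        self.attention_variant = attention_variant
        self.patch_cells = patch_cells
        self.block_size = block_size
        self.block_stride = block_stride
        self.grid_count = grid_count
        self.softmax_attention = softmax_attention
        self.embed_dim = embed_dim
        self.depth = depth
        self.hidden_units = hidden_units
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.image_size = image_size
        self.val_fraction = val_fraction
        self.early_stop_acc = early_stop_acc
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _model_config(self, n_classes: int) -> ModelConfig:
        if self.preset == "full":
            cfg = default_model_config(n_classes)
        elif self.preset == "reduced":
            cfg = reduced_model_config(n_classes)
        else:
            raise ValueError(f"unknown preset {self.preset!r}")
        att = dataclasses.replace(
            cfg.attention, variant=self.attention_variant,
            patch_cells=self.patch_cells, block_size=self.block_size,
            block_stride=self.block_stride, grid_count=self.grid_count,
            softmax_attention=self.softmax_attention)
        if self.embed_dim is not None:
            att = dataclasses.replace(att, embed_dim=self.embed_dim,
                                      ffn_hidden=4 * self.embed_dim)
        if self.depth is not None:
            att = dataclasses.replace(att, depth=self.depth)
        head = dataclasses.replace(cfg.head, hidden_units=self.hidden_units,
                                   dropout_rate=self.dropout_rate,
                                   n_classes=n_classes)
        return ModelConfig(backbone=cfg.backbone, attention=att, head=head,
                           image_size=self.image_size)

    def build_model(self, n_classes: int) -> RNTNet:
        """Assemble the (untrained) network for ``n_classes`` classes."""
        return assemble_rntnet(self._model_config(n_classes),
                               seed=self.random_state, arm=self.arm)

    def _prepare(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be (n, h, w, 3) images, got {X.shape}")
        return standardize(resize_batch(X.astype(np.uint8), self.image_size))

    # ------------------------------------------------------------------
    def fit(self, X, y):
        from .pipeline import split_dataset, train  # local: avoid cycle

        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        xs = self._prepare(X)
        self.model_ = self.build_model(self.classes_.size)
        self.config_ = self.model_.cfg
        cfg = TrainConfig(learning_rate=self.learning_rate, epochs=self.epochs,
                          batch_size=self.batch_size, seed=self.random_state)
        if self.val_fraction > 0:
            tr, va = split_dataset(y_enc, SplitSpec(
                train_fraction=1.0 - self.val_fraction, seed=self.random_state))
        else:  # validate on the training data itself
            tr = va = np.arange(len(y_enc))
        self.history_, best = train(
            self.model_, (xs[tr], y_enc[tr]), (xs[va], y_enc[va]), cfg,
            early_stop_acc=self.early_stop_acc)
        if best["state"] is not None:
            self.model_.load_state_dict(best["state"])
        self.best_epoch_ = best["epoch"]
        self.model_.eval()
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._prepare(X),
                                         batch_size=self.batch_size)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]
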