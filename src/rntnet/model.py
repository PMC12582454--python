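"""Classification head, loss, and full model assembly.

The head pools the fused tokens globally, passes them through a 256-unit
ReLU layer with 20% dropout, and maps to class logits; softmax turns the
logits into a probability distribution over the classes.  Training minimises
categorical cross-entropy ``L = -sum_i p_i log p_hat_i``.

``assemble_rntnet`` wires backbone -> patch embedding -> mixed-attention
encoder -> head.  Two ablation arms replace parts of the chain: the
backbone-only arm feeds the final feature map straight to the head, and the
encoder-only arm tokenizes the raw image (no convolutional features).
"""
from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np

from . import nn
from .attention import Encoder
from .backbone import Backbone, PatchEmbedding
from .config import (AttentionConfig, BackboneConfig, HeadConfig, ModelConfig,
                     default_model_config)
from .nn import Tensor

__all__ = [
    "ClassificationHead", "cross_entropy", "RNTNet", "assemble_rntnet",
    "save_checkpoint", "load_checkpoint",
]


class ClassificationHead(nn.Module):
    """Global average over tokens -> Dense(256) + ReLU -> Dropout -> logits."""

    def __init__(self, in_dim: int, cfg: HeadConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.dense = nn.Linear(in_dim, cfg.hidden_units, rng=rng, name="head_dense")
        self.dropout = nn.Dropout(cfg.dropout_rate, rng)
        self.out = nn.Linear(cfg.hidden_units, cfg.n_classes, rng=rng, name="head_out")

    def forward(self, tokens: Tensor) -> Tensor:
        """``tokens``: (N, H, W, D) -> (N, n_classes) logits."""
        with nn.scope("head"):
            n, h, w, d = tokens.shape
            pooled = tokens.reshape(n, h * w, d).mean(axis=1)
            hid = self.dropout(self.dense(pooled).relu())
            return self.out(hid)

    def probabilities(self, tokens: Tensor) -> np.ndarray:
        return self.forward(tokens).softmax(axis=-1).numpy()


def cross_entropy(true_onehot: np.ndarray, predicted: np.ndarray,
                  eps: float = 1e-12) -> float:
    """Categorical cross-entropy ``-sum_i p_i log p_hat_i`` (nats).

    ``predicted`` must be a valid probability vector; it is clipped at
    ``eps`` before the log so an exact zero never produces -inf.
    """
    t = np.asarray(true_onehot, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    return float(-(t * np.log(np.maximum(p, eps))).sum(axis=-1).mean())


class RNTNet(nn.Module):
    """Backbone + mixed-attention encoder + classification head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, arm: str = "full"):
        super().__init__()
        if arm not in ("full", "backbone", "encoder"):
            raise ValueError(f"unknown ablation arm {arm!r}")
        self.cfg = cfg
        self.arm = arm
        d = cfg.attention.embed_dim
        grid = -(-cfg.image_size // 32)  # total stride 32, ceil mode
        if arm == "encoder":
            self.backbone: Optional[Backbone] = None
            patch_px = max(cfg.image_size // grid, 1)
            self.patch_embed: Optional[PatchEmbedding] = PatchEmbedding(
                3, cfg.image_size, cfg.image_size, patch_cells=patch_px,
                embed_dim=d, positional=cfg.attention.positional_embedding,
                rng=rng)
            self.patch_px = patch_px
            self.encoder: Optional[Encoder] = Encoder(cfg.attention, rng)
            head_dim = d
        elif arm == "backbone":
            self.backbone = Backbone(cfg.backbone, rng)
            self.patch_embed = None
            self.encoder = None
            head_dim = self.backbone.out_channels
        else:
            self.backbone = Backbone(cfg.backbone, rng)
            self.patch_embed = PatchEmbedding(
                self.backbone.out_channels, grid, grid,
                patch_cells=cfg.attention.patch_cells, embed_dim=d,
                positional=cfg.attention.positional_embedding, rng=rng)
            self.encoder = Encoder(cfg.attention, rng)
            head_dim = d
        self.head = ClassificationHead(head_dim, cfg.head, rng)

    def forward(self, x, retain_feature_grad: bool = False) -> Tensor:
        """(N, 3, H, W) standardized images -> (N, n_classes) logits."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, np.float32))
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) images, got {x.shape}")
        if self.arm == "encoder":
            tokens = self.patch_embed(x).tokens
            tokens = self.encoder(tokens)
        elif self.arm == "backbone":
            fm = self.backbone(x, retain_feature_grad=retain_feature_grad)
            tokens = fm.transpose(0, 2, 3, 1)
        else:
            fm = self.backbone(x, retain_feature_grad=retain_feature_grad)
            tokens = self.patch_embed(fm).tokens
            tokens = self.encoder(tokens)
        return self.head(tokens)

    def predict_proba(self, x, batch_size: int = 32) -> np.ndarray:
        """Eval-mode class probabilities, batched; rows sum to 1."""
        self.eval()
        x = np.asarray(x, np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size])
            out.append(logits.softmax(axis=-1).numpy())
        return np.concatenate(out, axis=0)


def assemble_rntnet(cfg: Optional[ModelConfig] = None, seed: int = 0,
                    arm: str = "full") -> RNTNet:
    """Build a seeded model; identical seeds give bit-identical weights."""
    cfg = cfg or default_model_config()
    return RNTNet(cfg, np.random.default_rng(seed), arm=arm)


# ---------------------------------------------------------------------------
# checkpointing: one .npz archive with weights + resolved config + classes
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: RNTNet, class_names: Sequence[str],
                    extra: Optional[dict] = None) -> None:
    meta = {
        "config": dataclasses.asdict(model.cfg),
        "arm": model.arm,
        "classes": list(class_names),
        "numpy_version": np.__version__,
    }
    if extra:
        meta["extra"] = extra
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Returns ``(model, class_names, meta)`` rebuilt from the archive."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    m = meta["config"]
    cfg = ModelConfig(
        backbone=BackboneConfig(**m["backbone"]),
        attention=AttentionConfig(**m["attention"]),
        head=HeadConfig(**m["head"]),
        image_size=m["image_size"],
    )
    model = assemble_rntnet(cfg, seed=0, arm=meta.get("arm", "full"))
    model.load_state_dict(state)
    model.eval()
    return model, meta["classes"], meta
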