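"""Configuration dataclasses for every stage of the model and pipeline.

All hyper-parameters live here so a run is fully described by one YAML file.
The default values follow the published training protocol (Adam, initial
learning rate 1e-4, 180 epochs, batch size 64, 300x300 inputs) and the
architecture description (four residual stages of 128/256/512/1024 filters
with 3/4/6/3 blocks); where the architecture description is silent the
defaults are the package's own documented choices (see docs/methods.md).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import yaml

__all__ = [
    "BlockConfig", "BackboneConfig", "AttentionConfig", "HeadConfig",
    "ModelConfig", "TrainConfig", "SplitSpec", "default_model_config",
    "reduced_model_config", "load_yaml", "save_yaml",
]

# Per-channel normalization applied after scaling pixels to [0, 1].
# Neutral 0.5/0.25 values: no dataset-specific statistics are assumed.
NORM_MEAN: Tuple[float, float, float] = (0.5, 0.5, 0.5)
NORM_STD: Tuple[float, float, float] = (0.25, 0.25, 0.25)

IMAGE_SIZE = 300  # input side length after resizing


@dataclass
class BlockConfig:
    """One grouped-convolution residual (ResNeXt-style) bottleneck block."""
    in_channels: int
    bottleneck_width: int
    out_channels: int
    cardinality: int = 32
    stride: int = 1

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.bottleneck_width % self.cardinality:
            raise ValueError(
                f"cardinality {self.cardinality} must divide bottleneck width "
                f"{self.bottleneck_width}")


@dataclass
class BackboneConfig:
    """Four-stage grouped-convolution residual feature extractor.

    ``stage_widths`` are output channels per stage; the bottleneck width of
    each block is ``stage_width // 2``. The stem is a 7x7 stride-2
    convolution of ``stem_width`` filters followed by a 3x3 stride-2
    max-pool, giving a total stride of 32 with the stride-2 first blocks of
    stages 2-4.
    """
    stage_widths: List[int] = field(default_factory=lambda: [128, 256, 512, 1024])
    stage_blocks: List[int] = field(default_factory=lambda: [3, 4, 6, 3])
    cardinality: int = 32
    stem_width: int = 64

    def __post_init__(self):
        if len(self.stage_widths) != 4 or len(self.stage_blocks) != 4:
            raise ValueError("backbone must have exactly 4 stages")
        for w in self.stage_widths:
            if (w // 2) % self.cardinality:
                raise ValueError(
                    f"cardinality {self.cardinality} must divide bottleneck width {w // 2}")

    @property
    def total_stride(self) -> int:
        return 32


@dataclass
class AttentionConfig:
    """Mixed-attention encoder: overlapping-block + grid + dense branches.

    ``variant`` selects the ablation arm: ``"oba+ga"`` (default, all three
    branches), ``"oba"``, ``"ga"`` (one local/global branch plus the dense
    transformer branch), or ``"mhsa"`` (dense branch only).
    """
    embed_dim: int = 768
    depth: int = 1
    patch_cells: int = 2
    block_size: int = 4          # B, in token-grid cells
    block_stride: int = 2        # s
    weight_scheme: str = "uniform"   # overlap aggregation: uniform | gaussian
    grid_count: int = 2          # G interleaved groups per axis
    grid_downsample: int = 2     # fixed stride-2 pooling before grid attention
    ffn_hidden: int = 2679
    softmax_attention: bool = True
    variant: str = "oba+ga"
    positional_embedding: bool = True
    local_conv_channels: int = 64  # 3x3 conv + GAP local-context path inside OBA

    def __post_init__(self):
        if self.variant not in ("mhsa", "oba", "ga", "oba+ga"):
            raise ValueError(f"unknown attention variant {self.variant!r}")
        if self.weight_scheme not in ("uniform", "gaussian"):
            raise ValueError(f"unknown weight scheme {self.weight_scheme!r}")
        if not 1 <= self.block_stride <= self.block_size:
            raise ValueError("require 1 <= stride <= block size")


@dataclass
class HeadConfig:
    """Dense classification head: 256-unit ReLU layer, 20% dropout, softmax."""
    hidden_units: int = 256
    dropout_rate: float = 0.20
    n_classes: int = 8

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


@dataclass
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    image_size: int = IMAGE_SIZE


@dataclass
class TrainConfig:
    """Published training protocol defaults."""
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 180
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class SplitSpec:
    """Hold-out split: 80% train / 20% validation, stratified by class."""
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def default_model_config(n_classes: int = 8) -> ModelConfig:
    """The calibrated full-size configuration (the complexity-report anchor)."""
    return ModelConfig(head=HeadConfig(n_classes=n_classes))


def reduced_model_config(n_classes: int = 8) -> ModelConfig:
    """Desk-scale model: all widths / 4, one encoder layer.

    Used for CPU-scale training jobs on the synthetic fixture; cardinality
    is reduced to 8 so it still divides the narrowed bottlenecks.
    """
    full = default_model_config(n_classes)
    bb = BackboneConfig(
        stage_widths=[w // 4 for w in full.backbone.stage_widths],
        stage_blocks=list(full.backbone.stage_blocks),
        cardinality=8,
        stem_width=full.backbone.stem_width // 4,
    )
    att = dataclasses.replace(
        full.attention,
        embed_dim=full.attention.embed_dim // 4,
        ffn_hidden=full.attention.ffn_hidden // 4,
        depth=1,
        local_conv_channels=full.attention.local_conv_channels // 4,
    )
    return ModelConfig(backbone=bb, attention=att, head=HeadConfig(n_classes=n_classes))


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    return obj


def save_yaml(cfg: ModelConfig, path, train: Optional[TrainConfig] = None) -> None:
    doc = {"model": _to_dict(cfg)}
    if train is not None:
        doc["train"] = _to_dict(train)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_yaml(path) -> ModelConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    m = doc["model"] if "model" in doc else doc
    return ModelConfig(
        backbone=BackboneConfig(**m.get("backbone", {})),
        attention=AttentionConfig(**m.get("attention", {})),
        head=HeadConfig(**m.get("head", {})),
        image_size=m.get("image_size", IMAGE_SIZE),
    )
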