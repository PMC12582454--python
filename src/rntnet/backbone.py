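"""Grouped-convolution residual backbone and feature-map tokenization.

The feature extractor is a ResNeXt-style network: a stem (7x7 stride-2
convolution + 3x3 stride-2 max-pool) followed by four stages of bottleneck
blocks with grouped 3x3 convolutions and skip connections.  Each block is

    X1 = Conv1x1(X);  X2 = GroupedConv3x3(X1);  X3 = Conv1x1(X2)
    X' = ReLU(X3 + Skp(X))

where the skip path ``Skp`` is the identity when shapes match and a 1x1
projection convolution (with the block's stride) otherwise.  The first block
of stages 2-4 uses stride 2, so together with the stem the total stride is
32 and a 300x300 input yields a 10x10 feature map under ceil-mode spatial
arithmetic (300 -> 150 -> 75 -> 75 -> 38 -> 19 -> 10).

``tokens_from_feature_map`` turns the final feature map into a spatial grid
of patch tokens (flatten + reshape into N patches of P_H x P_W x C cells,
optionally linearly embedded), the input of the mixed-attention encoder.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from .config import BackboneConfig, BlockConfig
from .nn import Tensor

__all__ = [
    "ResNeXtBlock",
    "Backbone",
    "build_backbone",
    "TokenGrid",
    "tokens_from_feature_map",
    "PatchEmbedding",
]


class ResNeXtBlock(nn.Module):
    """One bottleneck residual block with grouped spatial convolution."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.reduce = nn.Conv2d(cfg.in_channels, cfg.bottleneck_width, 1,
                                rng=rng, name="reduce1x1")
        self.grouped = nn.Conv2d(cfg.bottleneck_width, cfg.bottleneck_width, 3,
                                 stride=cfg.stride, groups=cfg.cardinality,
                                 rng=rng, name="grouped3x3")
        self.expand = nn.Conv2d(cfg.bottleneck_width, cfg.out_channels, 1,
                                rng=rng, name="expand1x1")
        # start each block near the identity (residual branch ~ 0): without
        # batch normalization this keeps the 16-block stack trainable
        self.expand.weight.data *= 1e-2
        if cfg.in_channels != cfg.out_channels or cfg.stride != 1:
            self.skip: Optional[nn.Conv2d] = nn.Conv2d(
                cfg.in_channels, cfg.out_channels, 1, stride=cfg.stride,
                rng=rng, name="skip1x1")
        else:
            self.skip = None  # identity skip

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"block expects {self.cfg.in_channels} channels, got {x.shape[1]}")
        h = self.reduce(x).relu()
        h = self.grouped(h).relu()
        h = self.expand(h)
        s = x if self.skip is None else self.skip(x)
        return (h + s).relu()


class Backbone(nn.Module):
    """Stem + four residual stages; maps (N, 3, H, W) to (N, C4, H/32, W/32).

    The activation of the final stage is kept on ``last_feature_map`` after
    each forward pass (the Grad-CAM source layer).
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.stem_conv = nn.Conv2d(3, cfg.stem_width, 7, stride=2, rng=rng, name="stem7x7")
        self.stem_pool = nn.MaxPool2d(3, 2, ceil_mode=True)
        self.stages = []
        in_ch = cfg.stem_width
        for si, (width, n_blocks) in enumerate(zip(cfg.stage_widths, cfg.stage_blocks)):
            blocks = []
            for bi in range(n_blocks):
                stride = 2 if (si > 0 and bi == 0) else 1
                blocks.append(ResNeXtBlock(BlockConfig(
                    in_channels=in_ch, bottleneck_width=width // 2,
                    out_channels=width, cardinality=cfg.cardinality,
                    stride=stride), rng))
                in_ch = width
            self.stages.append(nn.Sequential(*blocks))
        self.out_channels = in_ch
        self.last_feature_map: Optional[Tensor] = None

    @property
    def n_blocks(self) -> int:
        return sum(len(s.layers) for s in self.stages)

    def forward(self, x: Tensor, retain_feature_grad: bool = False) -> Tensor:
        with nn.scope("stem"):
            h = self.stem_conv(x).relu()
            h = self.stem_pool(h)
        for i, stage in enumerate(self.stages):
            with nn.scope(f"stage{i + 1}"):
                h = stage(h)
        if retain_feature_grad:
            h.retain_grad = True
        self.last_feature_map = h
        return h


def build_backbone(cfg: Optional[BackboneConfig] = None, seed: int = 0) -> Backbone:
    """Construct a seeded backbone; identical seeds give identical weights."""
    cfg = cfg or BackboneConfig()
    return Backbone(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------


@dataclass
class TokenGrid:
    """Spatially indexed patch tokens: ``tokens`` has shape (N, gh, gw, D)."""
    tokens: Tensor
    patch_h: int
    patch_w: int
    patch_channels: int

    @property
    def grid_h(self) -> int:
        return self.tokens.shape[1]

    @property
    def grid_w(self) -> int:
        return self.tokens.shape[2]

    @property
    def n_tokens(self) -> int:
        return self.grid_h * self.grid_w

    @property
    def token_dim(self) -> int:
        return self.tokens.shape[3]


def _patchify(x: Tensor, patch_cells: int, pad: bool) -> Tensor:
    """(N, C, H, W) -> (N, gh, gw, p*p*C) raw flattened patches."""
    n, c, h, w = x.shape
    p = patch_cells
    if h % p or w % p:
        if not pad:
            raise ValueError(
                f"patch size {p} does not divide feature map {h}x{w}; enable "
                "pad=True (zero-padding up to the next multiple of the patch size)")
        ph, pw = (-h) % p, (-w) % p
        x = x.pad(((0, 0), (0, 0), (0, ph), (0, pw)))
        n, c, h, w = x.shape
    # (N,C,H,W) -> (N, gh, p, gw, p, C) -> (N, gh, gw, p, p, C) -> flatten
    t = x.transpose(0, 2, 3, 1)                     # N,H,W,C
    t = t.reshape(n, h // p, p, w // p, p, c)
    t = t.transpose(0, 1, 3, 2, 4, 5)
    return t.reshape(n, h // p, w // p, p * p * c)


def tokens_from_feature_map(x: Tensor, patch_cells: int = 1,
                            embed: Optional[nn.Linear] = None,
                            pad: bool = False) -> TokenGrid:
    """Flatten the feature map into patch tokens (the Flatten/Reshape step).

    With ``patch_cells=1`` and no embedding this is a bijection on
    feature-map cells: reshaping the result back recovers the map exactly.
    """
    if not isinstance(x, Tensor):
        x = Tensor(x)
    c = x.shape[1]
    raw = _patchify(x, patch_cells, pad)
    tokens = embed(raw) if embed is not None else raw
    return TokenGrid(tokens=tokens, patch_h=patch_cells, patch_w=patch_cells,
                     patch_channels=c)


class PatchEmbedding(nn.Module):
    """Patch tokenization + linear embedding + learned positional embedding."""

    def __init__(self, in_channels: int, grid_h: int, grid_w: int, *,
                 patch_cells: int = 1, embed_dim: int, positional: bool = True,
                 rng: np.random.Generator):
        super().__init__()
        self.patch_cells = patch_cells
        gh = -(-grid_h // patch_cells)
        gw = -(-grid_w // patch_cells)
        self.proj = nn.Linear(patch_cells * patch_cells * in_channels, embed_dim,
                              rng=rng, name="patch_embed")
        if positional:
            pos = rng.normal(0.0, 0.02, (1, gh, gw, embed_dim)).astype(np.float32)
            self.pos = Tensor(pos, requires_grad=True)
        else:
            self.pos = None

    def forward(self, feature_map: Tensor) -> TokenGrid:
        with nn.scope("tokenize"):
            grid = tokens_from_feature_map(feature_map, self.patch_cells,
                                           embed=self.proj, pad=True)
            if self.pos is not None:
                grid.tokens = grid.tokens + self.pos
        return grid
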