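"""Analytic parameter and floating-point-operation accounting.

Parameters are summed over every trainable tensor.  FLOPs are recorded by
the op-level audit in :mod:`rntnet.nn` while a single forward pass runs:
dense/convolution/attention products cost 2 FLOPs per multiply-accumulate,
normalizations and activations 1 FLOP per element.  Both the 2xMAC total
and the plain MAC total are reported, since published complexity tables
rarely state their convention.

The audit tags attention score and value products separately, which lets
``mixed_attention_flops`` measure how the mixed block's attention cost
scales with the token count M at fixed block/grid settings — the
O(M^2 D^2) regime — and contrast it with a dense all-pairs-per-block-pair
count whose growth is of O(M^4 D) type in the feature-map side.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .attention import MixedAttentionBlock, count_overlapping_blocks
from .config import AttentionConfig, ModelConfig, default_model_config
from .model import RNTNet, assemble_rntnet

__all__ = [
    "ComplexityReport", "count_parameters", "count_flops", "complexity_report",
    "mixed_attention_flops", "pairwise_block_flops", "fit_flop_exponent",
    "ATTENTION_CATEGORIES",
]

# categories the audit may emit; anything else indicates an unregistered op
_KNOWN_CATEGORIES = {"conv", "linear", "matmul", "attn_score", "attn_value",
                     "softmax", "norm", "act", "add", "mul", "pool"}
_MAC_CATEGORIES = {"conv", "linear", "matmul", "attn_score", "attn_value"}
ATTENTION_CATEGORIES = ("attn_score", "attn_value", "softmax")


@dataclass
class ComplexityReport:
    parameters: int
    flops: int                      # 2 FLOPs per MAC convention
    macs: int
    per_layer: Dict[str, int] = field(default_factory=dict)
    per_category: Dict[str, int] = field(default_factory=dict)
    token_count: Optional[int] = None
    embed_dim: Optional[int] = None

    @property
    def parameters_millions(self) -> float:
        return self.parameters / 1e6

    @property
    def gflops(self) -> float:
        return self.flops / 1e9

    @property
    def gmacs(self) -> float:
        return self.macs / 1e9

    def as_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "parameters_millions": self.parameters_millions,
            "gflops_2xmac": self.gflops,
            "gmacs": self.gmacs,
            "token_count": self.token_count,
            "embed_dim": self.embed_dim,
            "per_category": self.per_category,
            "per_layer": self.per_layer,
        }


def count_parameters(model: nn.Module) -> int:
    """Total element count over all trainable tensors."""
    return model.n_parameters()


def _audit_forward(run) -> Tuple[int, int, Dict[str, int], Dict[str, int]]:
    with nn.flop_audit() as entries:
        run()
    per_layer: Dict[str, int] = {}
    per_cat: Dict[str, int] = {}
    for scope_name, category, flops in entries:
        if category not in _KNOWN_CATEGORIES:
            raise ValueError(f"unregistered op category {category!r} in {scope_name}")
        per_layer[scope_name] = per_layer.get(scope_name, 0) + flops
        per_cat[category] = per_cat.get(category, 0) + flops
    total = sum(per_cat.values())
    macs = sum(per_cat.get(c, 0) for c in _MAC_CATEGORIES) // 2
    return total, macs, per_layer, per_cat


def count_flops(model: RNTNet, image_size: Optional[int] = None) -> ComplexityReport:
    """Audit one eval-mode forward pass on a single input image."""
    size = image_size or model.cfg.image_size
    model.eval()
    x = np.zeros((1, 3, size, size), np.float32)
    total, macs, per_layer, per_cat = _audit_forward(lambda: model.forward(x))
    grid = -(-size // 32)
    cells = model.cfg.attention.patch_cells
    return ComplexityReport(
        parameters=count_parameters(model), flops=total, macs=macs,
        per_layer=per_layer, per_category=per_cat,
        token_count=(-(-grid // cells)) ** 2,
        embed_dim=model.cfg.attention.embed_dim)


def complexity_report(cfg: Optional[ModelConfig] = None, seed: int = 0,
                      arm: str = "full") -> ComplexityReport:
    """Build the (default calibrated) configuration and account for it."""
    cfg = cfg or default_model_config()
    return count_flops(assemble_rntnet(cfg, seed=seed, arm=arm))


# ---------------------------------------------------------------------------
# scaling probes
# ---------------------------------------------------------------------------


def mixed_attention_flops(grid_side: int, cfg: Optional[AttentionConfig] = None,
                          attention_only: bool = True, seed: int = 0) -> int:
    """FLOPs of one mixed block on a ``grid_side**2``-token grid.

    With ``attention_only`` (the scaling probe) only the attention
    computation proper — score products, value aggregation and the row
    softmax across all branches — is summed, isolating the M-dependence of
    the mechanism from projections and FFN, which are linear in M for any
    variant.
    """
    cfg = cfg or AttentionConfig(embed_dim=16, ffn_hidden=32, local_conv_channels=8)
    block = MixedAttentionBlock(cfg, np.random.default_rng(seed))
    block.eval()
    x = np.zeros((1, grid_side, grid_side, cfg.embed_dim), np.float32)
    total, _, _, per_cat = _audit_forward(lambda: block.forward(nn.Tensor(x)))
    if attention_only:
        return sum(per_cat.get(c, 0) for c in ATTENTION_CATEGORIES)
    return total


def pairwise_block_flops(grid_side: int, block_size: int = 4, stride: int = 2,
                         d: int = 16) -> int:
    """Dense all-pairs count: attention across every token pair per block pair.

    With n blocks of B*B tokens this costs ``4 n^2 B^4 d`` FLOPs (score and
    value products at 2 FLOPs/MAC) — O(M^4 D)-type growth in the
    feature-map side M that the mixed block avoids.
    """
    pad = (-(grid_side - block_size)) % stride if grid_side >= block_size else block_size - grid_side
    side = grid_side + pad
    n = count_overlapping_blocks(side, side, block_size, stride)
    return 4 * n * n * block_size ** 4 * d


def fit_flop_exponent(sizes: Sequence[int], flops: Sequence[int]) -> float:
    """Least-squares slope of log(flops) against log(size)."""
    lx = np.log(np.asarray(sizes, np.float64))
    ly = np.log(np.asarray(flops, np.float64))
    slope = np.polyfit(lx, ly, 1)[0]
    return float(slope)
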