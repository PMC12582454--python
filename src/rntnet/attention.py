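"""Mixed-attention encoder: overlapping block attention, grid attention and
a dense transformer branch, fused per token.

Three branches read the same token grid in parallel:

* **Dense transformer branch** — classic scaled-dot self-attention over all
  tokens plus a feed-forward sub-layer, combined residually and layer
  normalised: ``X_out = Norm(X + Atten(Q, K, V) + FFN(X))``.
* **Overlapping block attention (OBA)** — the grid is covered by B x B
  blocks placed at stride s (s < B gives overlap; the number of blocks is
  ``((H-B)/s + 1) * ((W-B)/s + 1)``).  Self-attention runs inside each
  block and overlapping contributions are merged by a weighted average with
  per-position weights that sum to one.  A parallel local-context path
  (3x3 convolution + ReLU + global average pooling + FFN) is added to each
  block's output before the merge.
* **Grid attention (GA)** — the grid is average-pooled with stride 2, then
  partitioned into G x G interleaved (dilated) groups: token (i, j) joins
  group (i mod G, j mod G).  Self-attention runs within each group, outputs
  are scattered back to their positions and upsampled to the input grid.

The fused output is a channel-axis concatenation of the branch outputs
followed by a learned linear projection back to the embedding dimension.

Attention weights are passed through a row-wise softmax in every branch by
default, making each output token a convex combination of value rows; the
unnormalised raw-score variant is available via ``softmax=False``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import nn
from .config import AttentionConfig
from .nn import Tensor, concatenate, matmul

__all__ = [
    "OBAConfig", "GridConfig", "AttentionProjection", "scaled_dot_attention",
    "TransformerBlock", "count_overlapping_blocks", "overlapping_block_attention",
    "grid_attention", "fuse_branches", "MixedAttentionBlock", "Encoder",
    "BranchOutputs",
]


@dataclass
class OBAConfig:
    block_size: int = 4
    stride: int = 2
    weight_scheme: str = "uniform"  # uniform | gaussian

    def __post_init__(self):
        if not 1 <= self.stride <= self.block_size:
            raise ValueError("require 1 <= stride <= block_size")
        if self.weight_scheme not in ("uniform", "gaussian"):
            raise ValueError(f"unknown weight scheme {self.weight_scheme!r}")


@dataclass
class GridConfig:
    grid_count: int = 2
    downsample_stride: int = 2


@dataclass
class BranchOutputs:
    """The three branch outputs on a common token grid and their fusion."""
    z_o: Optional[Tensor]
    z_g: Optional[Tensor]
    x_out: Tensor
    z_f: Optional[Tensor] = None


class AttentionProjection(nn.Module):
    """Learnable query/key/value maps W_Q, W_K, W_V (shared input/output dims)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 name: str = "proj"):
        super().__init__()
        self.w_q = nn.Linear(in_dim, out_dim, bias=False, rng=rng, name=f"{name}.w_q")
        self.w_k = nn.Linear(in_dim, out_dim, bias=False, rng=rng, name=f"{name}.w_k")
        self.w_v = nn.Linear(in_dim, out_dim, bias=False, rng=rng, name=f"{name}.w_v")
        self.d_k = out_dim

    def forward(self, x: Tensor) -> Tuple[Tensor, Tensor, Tensor]:
        return self.w_q(x), self.w_k(x), self.w_v(x)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         d_k: Optional[int] = None, softmax: bool = True) -> Tensor:
    """``softmax(Q K^T / sqrt(d_k)) V`` over the last two axes (batched).

    With ``softmax=True`` every output row is a convex combination of the
    rows of ``v``.
    """
    if not isinstance(q, Tensor):
        q, k, v = Tensor(q), Tensor(k), Tensor(v)
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(f"q/k feature dims differ: {q.shape[-1]} vs {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError(f"k/v row counts differ: {k.shape[-2]} vs {v.shape[-2]}")
    d_k = d_k if d_k is not None else q.shape[-1]
    scores = matmul(q, k.swapaxes(-1, -2), category="attn_score") * (1.0 / np.sqrt(d_k))
    if softmax:
        scores = scores.softmax(axis=-1)
    return matmul(scores, v, category="attn_value")


class TransformerBlock(nn.Module):
    """Dense branch: ``X_out = Norm(X + Atten(Q,K,V) + FFN(X))``."""

    def __init__(self, dim: int, ffn_hidden: int, rng: np.random.Generator,
                 softmax: bool = True):
        super().__init__()
        self.proj = AttentionProjection(dim, dim, rng, name="mhsa")
        self.ffn1 = nn.Linear(dim, ffn_hidden, rng=rng, name="ffn1")
        self.ffn2 = nn.Linear(ffn_hidden, dim, rng=rng, name="ffn2")
        self.norm = nn.LayerNorm(dim)
        self.softmax = softmax

    def forward(self, x: Tensor) -> Tensor:
        """``x``: (N, H, W, D) token grid; shape is preserved."""
        with nn.scope("transformer"):
            n, h, w, d = x.shape
            flat = x.reshape(n, h * w, d)
            q, k, v = self.proj(flat)
            att = scaled_dot_attention(q, k, v, self.proj.d_k, self.softmax)
            ffn = self.ffn2(self.ffn1(flat).relu())
            out = self.norm(flat + att + ffn)
            return out.reshape(n, h, w, d)


# ---------------------------------------------------------------------------
# overlapping block attention
# ---------------------------------------------------------------------------


def count_overlapping_blocks(h: int, w: int, block_size: int, stride: int) -> int:
    """Number of B x B blocks at stride s: ``((h-B)/s + 1) ((w-B)/s + 1)``.

    Requires ``(h - B)`` and ``(w - B)`` divisible by ``s`` (callers pad the
    grid beforehand; see :func:`overlapping_block_attention`).
    """
    if block_size > h or block_size > w:
        raise ValueError(f"block size {block_size} exceeds grid {h}x{w}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if (h - block_size) % stride or (w - block_size) % stride:
        raise ValueError(
            f"(grid - block) must be divisible by stride; pad {h}x{w} up to the "
            f"next size with (size - {block_size}) % {stride} == 0")
    return ((h - block_size) // stride + 1) * ((w - block_size) // stride + 1)


def _oba_pad(size: int, b: int, s: int) -> int:
    """Extra cells so that (size + pad - b) is a non-negative multiple of s."""
    if size < b:
        return b - size
    return (-(size - b)) % s


def _block_weights(b: int, scheme: str) -> np.ndarray:
    if scheme == "gaussian":
        # taper centred in the block, sigma = b/2
        r = np.arange(b) - (b - 1) / 2.0
        g = np.exp(-(r ** 2) / (2 * (b / 2.0) ** 2))
        return np.outer(g, g).astype(np.float32)
    return np.ones((b, b), np.float32)


def overlapping_block_attention(x: Tensor, cfg: OBAConfig,
                                proj: AttentionProjection,
                                softmax: bool = True,
                                local_context: Optional[Tensor] = None) -> Tensor:
    """Block-wise self-attention with weighted overlap-average reassembly.

    ``x``: (N, H, W, D) token grid. ``local_context``, when given, is a
    (N, D) vector (the conv + GAP path output) added to every block's
    attention output before the overlap average.  Output grid size equals
    the input grid size.
    """
    n, h, w, d = x.shape
    b, s = cfg.block_size, cfg.stride
    ph, pw = _oba_pad(h, b, s), _oba_pad(w, b, s)
    if ph or pw:
        x = x.pad(((0, 0), (0, ph), (0, pw), (0, 0)))
    hp, wp = h + ph, w + pw
    count_overlapping_blocks(hp, wp, b, s)  # validates geometry
    q, k, v = proj(x)

    origins = [(i, j) for i in range(0, hp - b + 1, s) for j in range(0, wp - b + 1, s)]
    blocks_q = concatenate(
        [q[:, i:i + b, j:j + b, :].reshape(n, 1, b * b, d) for i, j in origins], axis=1)
    blocks_k = concatenate(
        [k[:, i:i + b, j:j + b, :].reshape(n, 1, b * b, d) for i, j in origins], axis=1)
    blocks_v = concatenate(
        [v[:, i:i + b, j:j + b, :].reshape(n, 1, b * b, d) for i, j in origins], axis=1)

    z = scaled_dot_attention(blocks_q, blocks_k, blocks_v, proj.d_k, softmax)
    if local_context is not None:
        z = z + local_context.reshape(n, 1, 1, d)

    # weighted overlap-average: out(i,j) = sum_b W_b(i,j) Z_b(i,j) / sum_b W_b(i,j)
    wmap = _block_weights(b, cfg.weight_scheme)
    acc: Optional[Tensor] = None
    wsum = np.zeros((hp, wp), np.float32)
    for bi, (i, j) in enumerate(origins):
        zb = z[:, bi, :, :].reshape(n, b, b, d) * Tensor(wmap[None, :, :, None])
        padded = zb.pad(((0, 0), (i, hp - b - i), (j, wp - b - j), (0, 0)))
        acc = padded if acc is None else acc + padded
        wsum[i:i + b, j:j + b] += wmap
    out = acc * Tensor((1.0 / wsum)[None, :, :, None])
    return out[:, :h, :w, :]


# ---------------------------------------------------------------------------
# grid attention
# ---------------------------------------------------------------------------


def _avg_pool_tokens(x: Tensor, stride: int) -> Tensor:
    """Stride-``stride`` average pooling on the (H, W) axes of (N,H,W,D)."""
    n, h, w, d = x.shape
    ph, pw = (-h) % stride, (-w) % stride
    if ph or pw:
        x = x.pad(((0, 0), (0, ph), (0, pw), (0, 0)))
        n, h, w, d = x.shape
    t = x.reshape(n, h // stride, stride, w // stride, stride, d)
    return t.mean(axis=(2, 4))


def _upsample_nearest_tokens(x: Tensor, factor: int) -> Tensor:
    n, h, w, d = x.shape
    t = x.reshape(n, h, 1, w, 1, d).broadcast_to((n, h, factor, w, factor, d))
    return t.reshape(n, h * factor, w * factor, d)


def grid_attention(x: Tensor, cfg: GridConfig, proj: AttentionProjection,
                   softmax: bool = True) -> Tensor:
    """Interleaved (dilated) group attention after stride-2 downsampling.

    Tokens of the pooled grid are partitioned into G x G groups by their
    coordinates modulo G (a bijection on token indices); self-attention runs
    within each group; outputs are scattered back and nearest-neighbour
    upsampled to the input grid for fusion.
    """
    n, h, w, d = x.shape
    g = cfg.grid_count
    if g < 1:
        raise ValueError("grid_count must be >= 1")
    ds = cfg.downsample_stride
    t = _avg_pool_tokens(x, ds) if ds > 1 else x
    _, hd, wd, _ = t.shape
    ph, pw = (-hd) % g, (-wd) % g
    if ph or pw:  # pad with zero tokens so G divides the side
        t = t.pad(((0, 0), (0, ph), (0, pw), (0, 0)))
    _, hp, wp, _ = t.shape

    q, k, v = proj(t)

    def partition(u: Tensor) -> Tensor:
        # (N, Hp, Wp, D) -> (N, G*G, P, D), token (i, j) -> group (i%G, j%G)
        u = u.reshape(n, hp // g, g, wp // g, g, d)
        u = u.transpose(0, 2, 4, 1, 3, 5)
        return u.reshape(n, g * g, (hp // g) * (wp // g), d)

    z = scaled_dot_attention(partition(q), partition(k), partition(v),
                             proj.d_k, softmax)
    # inverse of partition: scatter every token back to its position
    z = z.reshape(n, g, g, hp // g, wp // g, d)
    z = z.transpose(0, 3, 1, 4, 2, 5)
    z = z.reshape(n, hp, wp, d)
    z = z[:, :hd, :wd, :]
    if ds > 1:
        z = _upsample_nearest_tokens(z, ds)
    return z[:, :h, :w, :]


def fuse_branches(branches: List[Tensor], fusion: nn.Linear,
                  mode: str = "concat") -> Tensor:
    """Fuse aligned branch outputs: channel concatenation + linear projection
    back to D (default), or summation (config variant)."""
    shapes = {b.shape[:3] for b in branches}
    if len(shapes) != 1:
        raise ValueError(f"branch token grids are misaligned: {sorted(shapes)}")
    if mode == "sum":
        out = branches[0]
        for b in branches[1:]:
            out = out + b
        return fusion(out)
    return fusion(concatenate(branches, axis=-1))


# ---------------------------------------------------------------------------
# the mixed block and encoder stack
# ---------------------------------------------------------------------------


class MixedAttentionBlock(nn.Module):
    """One encoder layer combining the OBA, GA and dense branches."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.embed_dim
        self.transformer = TransformerBlock(d, cfg.ffn_hidden, rng,
                                            softmax=cfg.softmax_attention)
        self.use_oba = cfg.variant in ("oba", "oba+ga")
        self.use_ga = cfg.variant in ("ga", "oba+ga")
        n_branches = 1 + self.use_oba + self.use_ga
        if self.use_oba:
            self.oba_cfg = OBAConfig(cfg.block_size, cfg.block_stride, cfg.weight_scheme)
            self.oba_proj = AttentionProjection(d, d, rng, name="oba")
            lc = cfg.local_conv_channels
            self.local_conv = nn.Conv2d(d, lc, 3, rng=rng, name="oba_local3x3")
            self.local_ffn1 = nn.Linear(lc, lc, rng=rng, name="oba_local_ffn1")
            self.local_ffn2 = nn.Linear(lc, d, rng=rng, name="oba_local_ffn2")
        if self.use_ga:
            self.ga_cfg = GridConfig(cfg.grid_count, cfg.grid_downsample)
            self.ga_proj = AttentionProjection(d, d, rng, name="ga")
        if n_branches > 1:
            self.fusion = nn.Linear(n_branches * d, d, rng=rng, name="fuse")
        else:
            self.fusion = None
        self.norm = nn.LayerNorm(d)

    def _local_context(self, x: Tensor) -> Tensor:
        # (N,H,W,D) -> conv over the grid -> ReLU -> GAP -> FFN -> (N,D)
        with nn.scope("oba_local"):
            u = x.transpose(0, 3, 1, 2)  # NCHW
            u = self.local_conv(u).relu()
            u = nn.global_avg_pool2d(u)
            return self.local_ffn2(self.local_ffn1(u).relu())

    def branch_outputs(self, x: Tensor) -> BranchOutputs:
        x_out = self.transformer(x)
        z_o = z_g = None
        if self.use_oba:
            with nn.scope("oba"):
                z_o = overlapping_block_attention(
                    x, self.oba_cfg, self.oba_proj,
                    softmax=self.cfg.softmax_attention,
                    local_context=self._local_context(x))
        if self.use_ga:
            with nn.scope("ga"):
                z_g = grid_attention(x, self.ga_cfg, self.ga_proj,
                                     softmax=self.cfg.softmax_attention)
        return BranchOutputs(z_o=z_o, z_g=z_g, x_out=x_out)

    def forward(self, x: Tensor) -> Tensor:
        b = self.branch_outputs(x)
        if self.fusion is None:
            b.z_f = b.x_out
        else:
            parts = [t for t in (b.z_o, b.z_g, b.x_out) if t is not None]
            with nn.scope("fusion"):
                b.z_f = self.norm(fuse_branches(parts, self.fusion))
        return b.z_f


class Encoder(nn.Module):
    """A stack of ``depth`` mixed-attention blocks."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.blocks = [MixedAttentionBlock(cfg, rng) for _ in range(cfg.depth)]

    def forward(self, x: Tensor) -> Tensor:
        with nn.scope("encoder"):
            for i, block in enumerate(self.blocks):
                with nn.scope(f"layer{i}"):
                    x = block(x)
        return x
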