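"""Mixed-attention branches checked against dense brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from rntnet.attention import (AttentionProjection, GridConfig,
                              MixedAttentionBlock, OBAConfig, TransformerBlock,
                              count_overlapping_blocks, fuse_branches,
                              grid_attention, overlapping_block_attention,
                              scaled_dot_attention)
from rntnet.config import AttentionConfig
from rntnet.nn import Linear, Tensor


def dense_softmax_attention(q, k, v, d_k):
    """Independent dense oracle: softmax(q k^T / sqrt(d_k)) v in plain numpy."""
    s = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    e = np.exp(s - s.max(axis=-1, keepdims=True))
    p = e / e.sum(axis=-1, keepdims=True)
    return p @ v


def dense_branch_oracle(x, proj):
    n, h, w, d = x.shape
    flat = x.reshape(n, h * w, d)
    q = flat @ proj.w_q.weight.data
    k = flat @ proj.w_k.weight.data
    v = flat @ proj.w_v.weight.data
    return dense_softmax_attention(q, k, v, proj.d_k).reshape(n, h, w, d)


# -- scaled dot attention ---------------------------------------------------


def test_single_token_attention_returns_value(rng):
    q = rng.normal(size=(1, 4)).astype(np.float32)
    v = rng.normal(size=(1, 4)).astype(np.float32)
    out = scaled_dot_attention(Tensor(q), Tensor(q), Tensor(v)).numpy()
    np.testing.assert_allclose(out, v, atol=1e-6)


def test_identical_keys_give_uniform_weights(rng):
    q = rng.normal(size=(3, 4)).astype(np.float32)
    k = np.tile(rng.normal(size=(1, 4)).astype(np.float32), (5, 1))
    v = rng.normal(size=(5, 4)).astype(np.float32)
    out = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v)).numpy()
    np.testing.assert_allclose(out, np.tile(v.mean(axis=0), (3, 1)), atol=1e-5)


def test_attention_matches_dense_oracle(rng):
    q, k, v = (rng.normal(size=(5, 3)).astype(np.float32) for _ in range(3))
    ours = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v), d_k=3).numpy()
    np.testing.assert_allclose(ours, dense_softmax_attention(q, k, v, 3), atol=1e-6)


def test_attention_dimension_mismatch_raises(rng):
    q = Tensor(rng.normal(size=(2, 3)).astype(np.float32))
    k = Tensor(rng.normal(size=(2, 4)).astype(np.float32))
    with pytest.raises(ValueError):
        scaled_dot_attention(q, k, k)


def test_attention_rows_are_convex_combinations(rng):
    q, k = (rng.normal(size=(6, 4)).astype(np.float32) for _ in range(2))
    v = np.ones((6, 2), np.float32)
    out = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v)).numpy()
    np.testing.assert_allclose(out, 1.0, atol=1e-6)  # weights sum to 1


# -- transformer block ------------------------------------------------------


def test_transformer_block_preserves_shape_and_normalizes(rng):
    blk = TransformerBlock(8, 16, rng)
    x = Tensor(rng.normal(size=(2, 3, 4, 8)).astype(np.float32))
    out = blk(x)
    assert out.shape == x.shape
    # pre-affine layer norm: gamma=1, beta=0 at init, so each token has
    # zero mean / unit variance across the feature axis
    o = out.numpy()
    np.testing.assert_allclose(o.mean(axis=-1), 0.0, atol=1e-5)
    np.testing.assert_allclose(o.var(axis=-1), 1.0, atol=1e-3)


def test_transformer_block_degenerates_to_norm_when_sublayers_zeroed(rng):
    blk = TransformerBlock(8, 16, rng)
    for lin in (blk.proj.w_q, blk.proj.w_k, blk.proj.w_v, blk.ffn1, blk.ffn2):
        lin.weight.data[:] = 0
        if lin.bias is not None:
            lin.bias.data[:] = 0
    # w_v = 0 makes the attention output zero; FFN zeroed; residual remains
    x = rng.normal(size=(1, 2, 2, 8)).astype(np.float32)
    out = blk(Tensor(x)).numpy().reshape(4, 8)
    mu = x.reshape(4, 8).mean(-1, keepdims=True)
    sd = np.sqrt(x.reshape(4, 8).var(-1, keepdims=True) + 1e-5)
    np.testing.assert_allclose(out, (x.reshape(4, 8) - mu) / sd, atol=1e-5)


# -- overlapping block attention -------------------------------------------


@pytest.mark.parametrize("h,w,b,s,expected", [
    (6, 6, 4, 2, 4),
    (5, 5, 5, 3, 1),   # h = w = B: single block
    (8, 8, 4, 4, 4),   # exact non-overlapping tiling
])
def test_block_count_examples(h, w, b, s, expected):
    assert count_overlapping_blocks(h, w, b, s) == expected


def test_block_count_rejects_oversized_block():
    with pytest.raises(ValueError, match="exceeds"):
        count_overlapping_blocks(4, 4, 6, 1)


@given(h=st.integers(1, 12), w=st.integers(1, 12),
       b=st.integers(1, 12), s=st.integers(1, 4))
def test_block_count_matches_enumeration(h, w, b, s):
    if b > h or b > w or (h - b) % s or (w - b) % s:
        return
    brute = sum(1 for _ in (
        (i, j) for i in range(0, h - b + 1, s) for j in range(0, w - b + 1, s)))
    assert count_overlapping_blocks(h, w, b, s) == brute


def test_oba_full_grid_equals_dense_attention(rng):
    d = 8
    proj = AttentionProjection(d, d, np.random.default_rng(1))
    x = rng.normal(size=(2, 6, 6, d)).astype(np.float32)
    out = overlapping_block_attention(
        Tensor(x), OBAConfig(block_size=6, stride=1), proj).numpy()
    np.testing.assert_allclose(out, dense_branch_oracle(x, proj), atol=1e-5)


def test_oba_without_overlap_is_identity_aggregation(rng):
    d = 4
    proj = AttentionProjection(d, d, np.random.default_rng(2))
    x = rng.normal(size=(1, 8, 8, d)).astype(np.float32)
    merged = overlapping_block_attention(
        Tensor(x), OBAConfig(block_size=4, stride=4), proj).numpy()
    # hand assembly: each non-overlapping block's attention placed in its tile
    q = x.reshape(1, 64, d) @ proj.w_q.weight.data
    k = x.reshape(1, 64, d) @ proj.w_k.weight.data
    v = x.reshape(1, 64, d) @ proj.w_v.weight.data
    q, k, v = (t.reshape(8, 8, d) for t in (q[0], k[0], v[0]))
    expected = np.zeros_like(merged[0])
    for i in (0, 4):
        for j in (0, 4):
            qb = q[i:i + 4, j:j + 4].reshape(16, d)
            kb = k[i:i + 4, j:j + 4].reshape(16, d)
            vb = v[i:i + 4, j:j + 4].reshape(16, d)
            expected[i:i + 4, j:j + 4] = dense_softmax_attention(
                qb, kb, vb, d).reshape(4, 4, d)
    np.testing.assert_allclose(merged[0], expected, atol=1e-5)


def test_oba_row_overlap_average_matches_hand_assembly(rng):
    # 1 x 6 token row, B = 4, s = 2: two blocks; columns 2-3 (0-based)
    # belong to both and must be the mean of the two block outputs there.
    d = 4
    proj = AttentionProjection(d, d, np.random.default_rng(3))
    x = rng.normal(size=(1, 4, 6, d)).astype(np.float32)
    out = overlapping_block_attention(
        Tensor(x), OBAConfig(block_size=4, stride=2), proj).numpy()[0]
    flat = x.reshape(1, 24, d)
    q = (flat @ proj.w_q.weight.data)[0].reshape(4, 6, d)
    k = (flat @ proj.w_k.weight.data)[0].reshape(4, 6, d)
    v = (flat @ proj.w_v.weight.data)[0].reshape(4, 6, d)
    zs = []
    for j0 in (0, 2):
        qb = q[:, j0:j0 + 4].reshape(16, d)
        kb = k[:, j0:j0 + 4].reshape(16, d)
        vb = v[:, j0:j0 + 4].reshape(16, d)
        zs.append(dense_softmax_attention(qb, kb, vb, d).reshape(4, 4, d))
    np.testing.assert_allclose(out[:, :2], zs[0][:, :2], atol=1e-5)
    np.testing.assert_allclose(out[:, 4:], zs[1][:, 2:], atol=1e-5)
    np.testing.assert_allclose(out[:, 2:4], (zs[0][:, 2:] + zs[1][:, :2]) / 2,
                               atol=1e-5)


def test_oba_aggregation_weights_conserve_mass(rng):
    # constant value field: any convex overlap-average must return it exactly
    d = 4
    proj = AttentionProjection(d, d, np.random.default_rng(4))
    proj.w_v.weight.data = np.eye(d, dtype=np.float32)
    x = np.ones((1, 6, 6, d), np.float32)
    for scheme in ("uniform", "gaussian"):
        out = overlapping_block_attention(
            Tensor(x), OBAConfig(4, 2, weight_scheme=scheme), proj).numpy()
        np.testing.assert_allclose(out, 1.0, atol=1e-5)


def test_oba_local_context_shifts_all_positions(rng):
    d = 4
    proj = AttentionProjection(d, d, np.random.default_rng(5))
    x = rng.normal(size=(2, 6, 6, d)).astype(np.float32)
    base = overlapping_block_attention(Tensor(x), OBAConfig(4, 2), proj).numpy()
    shift = rng.normal(size=(2, d)).astype(np.float32)
    out = overlapping_block_attention(Tensor(x), OBAConfig(4, 2), proj,
                                      local_context=Tensor(shift)).numpy()
    np.testing.assert_allclose(out, base + shift[:, None, None, :], atol=1e-5)


# -- grid attention ---------------------------------------------------------


def test_ga_single_group_equals_dense_attention(rng):
    d = 8
    proj = AttentionProjection(d, d, np.random.default_rng(6))
    x = rng.normal(size=(2, 5, 5, d)).astype(np.float32)
    out = grid_attention(Tensor(x), GridConfig(grid_count=1, downsample_stride=1),
                         proj).numpy()
    np.testing.assert_allclose(out, dense_branch_oracle(x, proj), atol=1e-5)


def test_ga_partition_is_a_bijection():
    # 4x4 grid, G=2: four interleaved groups of four; every token exactly once
    idx = np.arange(16, dtype=np.float32).reshape(1, 4, 4, 1)
    d = 1
    proj = AttentionProjection(d, d, np.random.default_rng(7))
    proj.w_v.weight.data = np.eye(1, dtype=np.float32)
    # identity attention: q=k=0 -> uniform weights within each group
    proj.w_q.weight.data[:] = 0
    proj.w_k.weight.data[:] = 0
    out = grid_attention(Tensor(idx), GridConfig(grid_count=2, downsample_stride=1),
                         proj).numpy()[0, :, :, 0]
    # each output token = mean of its dilated group {i%2, j%2}
    for i in range(4):
        for j in range(4):
            group = idx[0, i % 2::2, j % 2::2, 0]
            assert abs(out[i, j] - group.mean()) < 1e-5


def test_ga_attention_rows_sum_to_one(rng):
    d = 4
    proj = AttentionProjection(d, d, np.random.default_rng(8))
    proj.w_v.weight.data = np.eye(d, dtype=np.float32)
    x = np.ones((1, 4, 4, d), np.float32)
    out = grid_attention(Tensor(x), GridConfig(2, 1), proj).numpy()
    np.testing.assert_allclose(out, 1.0, atol=1e-5)  # convex combinations of 1s


def test_ga_downsample_and_upsample_restore_grid_size(rng):
    d = 4
    proj = AttentionProjection(d, d, np.random.default_rng(9))
    x = Tensor(rng.normal(size=(1, 5, 5, d)).astype(np.float32))
    out = grid_attention(x, GridConfig(grid_count=2, downsample_stride=2), proj)
    assert out.shape == (1, 5, 5, d)


# -- fusion and the mixed block ---------------------------------------------


def test_fusion_zero_branches_zero_projection_gives_zero(rng):
    fusion = Linear(12, 4, rng=np.random.default_rng(0))
    fusion.bias.data[:] = 0
    zeros = [Tensor(np.zeros((1, 2, 2, 4), np.float32)) for _ in range(3)]
    out = fuse_branches(zeros, fusion).numpy()
    np.testing.assert_array_equal(out, 0.0)


def test_fusion_rejects_misaligned_grids(rng):
    fusion = Linear(8, 4, rng=np.random.default_rng(0))
    a = Tensor(np.zeros((1, 2, 2, 4), np.float32))
    b = Tensor(np.zeros((1, 3, 3, 4), np.float32))
    with pytest.raises(ValueError, match="misaligned"):
        fuse_branches([a, b], fusion)


def test_fusion_is_token_permutation_equivariant(rng):
    fusion = Linear(12, 4, rng=np.random.default_rng(1))
    branches = [rng.normal(size=(1, 2, 3, 4)).astype(np.float32)
                for _ in range(3)]
    out = fuse_branches([Tensor(b) for b in branches], fusion).numpy()
    perm = np.random.default_rng(2).permutation(6)
    permuted = [b.reshape(1, 6, 4)[:, perm].reshape(1, 2, 3, 4)
                for b in branches]
    out_p = fuse_branches([Tensor(b) for b in permuted], fusion).numpy()
    np.testing.assert_allclose(out_p.reshape(1, 6, 4),
                               out.reshape(1, 6, 4)[:, perm], atol=1e-6)


@pytest.mark.parametrize("variant,n_branches", [
    ("mhsa", 1), ("oba", 2), ("ga", 2), ("oba+ga", 3)])
def test_mixed_block_variants_preserve_shape(rng, variant, n_branches):
    cfg = AttentionConfig(embed_dim=8, ffn_hidden=16, variant=variant,
                          local_conv_channels=4)
    blk = MixedAttentionBlock(cfg, np.random.default_rng(0))
    x = Tensor(rng.normal(size=(2, 5, 5, 8)).astype(np.float32))
    b = blk.branch_outputs(x)
    present = [t for t in (b.z_o, b.z_g, b.x_out) if t is not None]
    assert len(present) == n_branches
    assert blk(x).shape == x.shape


def test_oba_ga_match_dense_oracle_over_many_random_grids():
    """OBA with B = grid and GA with G = 1 coincide with dense attention
    on 50 random token grids (<= 1e-5)."""
    d = 6
    for trial in range(50):
        r = np.random.default_rng(100 + trial)
        proj = AttentionProjection(d, d, np.random.default_rng(200 + trial))
        side = int(r.integers(2, 7))
        x = r.normal(size=(1, side, side, d)).astype(np.float32)
        oracle = dense_branch_oracle(x, proj)
        oba = overlapping_block_attention(
            Tensor(x), OBAConfig(block_size=side, stride=1), proj).numpy()
        ga = grid_attention(Tensor(x), GridConfig(1, 1), proj).numpy()
        assert np.abs(oba - oracle).max() <= 1e-5
        assert np.abs(ga - oracle).max() <= 1e-5
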