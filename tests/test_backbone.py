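"""Backbone: residual block contracts, stride schedule, tokenization."""
import numpy as np
import pytest

from rntnet.backbone import (Backbone, ResNeXtBlock, build_backbone,
                             tokens_from_feature_map)
from rntnet.config import BackboneConfig, BlockConfig
from rntnet.nn import Tensor
from rntnet.nn.tensor import softmax_cross_entropy


def test_block_is_identity_when_conv_branch_zeroed(rng):
    cfg = BlockConfig(in_channels=8, bottleneck_width=8, out_channels=8,
                      cardinality=4, stride=1)
    block = ResNeXtBlock(cfg, rng)
    assert block.skip is None  # identity skip when shapes match
    for conv in (block.reduce, block.grouped, block.expand):
        conv.weight.data[:] = 0
        conv.bias.data[:] = 0
    x = np.abs(rng.normal(size=(2, 8, 6, 6))).astype(np.float32)
    out = block(Tensor(x)).numpy()
    np.testing.assert_allclose(out, x, atol=1e-7)


@pytest.mark.parametrize("stride,expected_hw", [(1, 16), (2, 8)])
def test_block_shape_contract(rng, stride, expected_hw):
    cfg = BlockConfig(in_channels=64, bottleneck_width=64, out_channels=128,
                      cardinality=32, stride=stride)
    block = ResNeXtBlock(cfg, rng)
    out = block(Tensor(rng.normal(size=(1, 64, 16, 16)).astype(np.float32)))
    assert out.shape == (1, 128, expected_hw, expected_hw)
    assert out.numpy().min() >= 0  # ReLU output


def test_block_rejects_channel_mismatch(rng):
    cfg = BlockConfig(in_channels=8, bottleneck_width=8, out_channels=8,
                      cardinality=4)
    block = ResNeXtBlock(cfg, rng)
    with pytest.raises(ValueError, match="channels"):
        block(Tensor(np.zeros((1, 4, 6, 6), np.float32)))


def test_block_config_rejects_bad_cardinality():
    with pytest.raises(ValueError, match="cardinality"):
        BlockConfig(in_channels=8, bottleneck_width=6, out_channels=8,
                    cardinality=4)


def test_default_backbone_has_16_blocks():
    bb = build_backbone(seed=0)
    assert bb.n_blocks == 3 + 4 + 6 + 3 == 16


def test_backbone_stride_schedule_on_300_input():
    # 300 -> 150 -> 75 -> 75 -> 38 -> 19 -> 10 under ceil-mode arithmetic
    cfg = BackboneConfig(stage_widths=[16, 32, 64, 128], cardinality=8,
                         stem_width=8)
    bb = Backbone(cfg, np.random.default_rng(0))
    out = bb(Tensor(np.zeros((1, 3, 300, 300), np.float32)))
    assert out.shape == (1, 128, 10, 10)


@pytest.mark.parametrize("size", [64, 150, 224, 300])
def test_backbone_output_follows_total_stride(size):
    cfg = BackboneConfig(stage_widths=[16, 32, 64, 128], cardinality=8,
                         stem_width=8)
    bb = Backbone(cfg, np.random.default_rng(0))
    out = bb(Tensor(np.zeros((1, 3, size, size), np.float32)))
    expect = size
    for _ in range(5):  # five stride-2 stages: stem conv, pool, stages 2-4
        expect = -(-expect // 2)
    assert out.shape[2] == out.shape[3] == expect


def test_same_seed_gives_bit_identical_weights():
    a, b = build_backbone(seed=11), build_backbone(seed=11)
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb
        np.testing.assert_array_equal(pa.data, pb.data)


def test_gradient_reaches_every_backbone_parameter(rng):
    cfg = BackboneConfig(stage_widths=[8, 16, 32, 64], stage_blocks=[1, 1, 1, 1],
                         cardinality=4, stem_width=8)
    bb = Backbone(cfg, rng)
    x = rng.normal(size=(2, 3, 64, 64)).astype(np.float32)
    out = bb(Tensor(x)).mean(axis=(2, 3))  # (2, 64)
    loss = softmax_cross_entropy(out, np.eye(64, dtype=np.float32)[[0, 1]])
    loss.backward()
    for name, p in bb.named_parameters():
        assert p.grad is not None and np.isfinite(p.grad).all(), name


# -- tokenization -----------------------------------------------------------


def test_patch_counting(rng):
    x = Tensor(rng.normal(size=(1, 5, 4, 4)).astype(np.float32))
    grid = tokens_from_feature_map(x, patch_cells=2)
    assert grid.n_tokens == 4 and grid.token_dim == 2 * 2 * 5

    x10 = Tensor(rng.normal(size=(1, 7, 10, 10)).astype(np.float32))
    assert tokens_from_feature_map(x10, patch_cells=1).n_tokens == 100


def test_tokenization_roundtrip_is_lossless_at_patch_one(rng):
    x = rng.normal(size=(2, 6, 5, 5)).astype(np.float32)
    grid = tokens_from_feature_map(Tensor(x), patch_cells=1)
    # tokens (N, gh, gw, C) permuted back must equal the map exactly
    back = grid.tokens.numpy().transpose(0, 3, 1, 2)
    np.testing.assert_array_equal(back, x)


def test_non_divisible_patch_raises_naming_padding_rule(rng):
    x = Tensor(rng.normal(size=(1, 3, 5, 5)).astype(np.float32))
    with pytest.raises(ValueError, match="zero-padding"):
        tokens_from_feature_map(x, patch_cells=2, pad=False)
    grid = tokens_from_feature_map(x, patch_cells=2, pad=True)
    assert (grid.grid_h, grid.grid_w) == (3, 3)
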