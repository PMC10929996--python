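"""Encoder building blocks: Conv-IN-ReLU, residual blocks, backbones, Ms-FPN."""

import numpy as np
import pytest

from coretr import autodiff as ad
from coretr.autodiff import Tensor
from coretr.config import BackboneConfig, ModelConfig
from coretr.encoder import (Backbone, ConvINReLU, CoReTrEncoder, FeatureMap,
                            FeaturePyramid, MsFPN, ResidualBlock, Stem)

RNG = np.random.default_rng(0)


def _x(c, n=8):
    return Tensor(RNG.normal(size=(c, n, n, n)).astype(np.float32))


class TestConvINReLU:
    def test_output_nonnegative(self):
        blk = ConvINReLU(2, 3, 3, rng=np.random.default_rng(1))
        assert blk(_x(2)).data.min() >= 0.0

    def test_stride_two_halves_dims(self):
        blk = ConvINReLU(2, 4, 3, stride=2, rng=np.random.default_rng(1))
        assert blk(_x(2, 8)).data.shape == (4, 4, 4, 4)

    def test_instance_norm_standardizes_prerelu(self):
        # per-channel mean ~ 0 and sd ~ 1 after IN (gamma=1, beta=0), before ReLU
        from coretr.nn import InstanceNorm
        x = _x(3, 6)
        y = InstanceNorm(3)(x).data
        np.testing.assert_allclose(y.mean(axis=(1, 2, 3)), 0.0, atol=1e-4)
        np.testing.assert_allclose(y.std(axis=(1, 2, 3)), 1.0, atol=1e-2)


class TestResidualBlock:
    def test_zeroed_transform_equals_shortcut(self):
        blk = ResidualBlock(3, 3, kernel=3, stride=1, rng=np.random.default_rng(2))
        blk.conv2.weight.data[:] = 0.0
        blk.conv2.bias.data[:] = 0.0
        blk.norm2.beta.data[:] = 0.0
        x = _x(3)
        out = blk(x).data
        np.testing.assert_allclose(out, np.maximum(x.data, 0.0), atol=1e-6)

    def test_shape_preserved_without_downsampling(self):
        blk = ResidualBlock(3, 3, kernel=5, stride=1, rng=np.random.default_rng(2))
        assert blk(_x(3)).data.shape == (3, 8, 8, 8)

    def test_projection_shortcut_on_channel_change(self):
        blk = ResidualBlock(2, 6, kernel=3, stride=2, rng=np.random.default_rng(2))
        assert blk(_x(2, 8)).data.shape == (6, 4, 4, 4)
        assert blk.shortcut is not None

    def test_skip_path_carries_gradient(self):
        """With the transform branch zeroed the block is ReLU(identity), so
        input gradient passes straight through on positive inputs."""
        blk = ResidualBlock(2, 2, kernel=3, stride=1, rng=np.random.default_rng(3))
        blk.conv2.weight.data[:] = 0.0
        blk.norm2.beta.data[:] = 0.0
        x = Tensor(np.abs(RNG.normal(size=(2, 6, 6, 6))).astype(np.float32) + 0.1,
                   requires_grad=True)
        ad.tsum(blk(x)).backward()
        np.testing.assert_allclose(x.grad, 1.0, atol=1e-6)


class TestStem:
    def test_channel_raise_and_stride_one(self):
        stem = Stem(base_channels=6, n_blocks=3, rng=np.random.default_rng(4))
        out = stem(_x(1, 8))
        assert out.data.shape == (6, 8, 8, 8)

    def test_finite_on_zero_input(self):
        stem = Stem(base_channels=4, n_blocks=5, rng=np.random.default_rng(4))
        out = stem(Tensor(np.zeros((1, 8, 8, 8), np.float32)))
        assert np.all(np.isfinite(out.data))

    def test_kernel_pattern_one_then_three(self):
        stem = Stem(base_channels=4, n_blocks=5, rng=np.random.default_rng(4))
        kernels = [b.conv.weight.data.shape[-1] for b in stem.blocks]
        assert kernels == [3, 1, 3, 3, 3]


class TestBackbones:
    def test_shallow_stride_ladder_full_depth(self):
        # six stages with strides doubling from 1 to 32 relative to the input
        cfg = BackboneConfig(base_channels=2, channel_cap=8, shallow_conv_blocks=3,
                             res_kernel=3)
        bb = Backbone(cfg, level=0, rng=np.random.default_rng(5))
        maps = bb(Tensor(RNG.normal(size=(1, 64, 64, 64)).astype(np.float32)), 0.5)
        assert len(maps) == 6
        assert [m.dims[0] for m in maps] == [64, 32, 16, 8, 4, 2]
        assert [m.stride for m in maps] == [0.5, 1.0, 2.0, 4.0, 8.0, 16.0]

    def test_deep_coarsest_extent_and_grouping(self):
        cfg = BackboneConfig(base_channels=2, channel_cap=8, shallow_conv_blocks=3,
                             res_kernel=3)
        assert cfg.deep_blocks_per_scale() == [2, 2, 2, 1, 1, 1]
        bb = Backbone(cfg, level=1, rng=np.random.default_rng(5))
        maps = bb(Tensor(RNG.normal(size=(1, 48, 48, 48)).astype(np.float32)), 2.0)
        assert len(maps) == 6
        assert min(maps[-1].dims) >= 3  # coarsest map keeps a usable extent
        assert np.all(np.isfinite(maps[-1].tensor.data))

    def test_deep_has_more_parameters_than_shallow(self):
        cfg = BackboneConfig(base_channels=4, channel_cap=16, shallow_conv_blocks=3,
                             res_kernel=3)
        n_sh = sum(p.size for p in Backbone(cfg, 0, rng=np.random.default_rng(6)).parameters())
        n_dp = sum(p.size for p in Backbone(cfg, 1, rng=np.random.default_rng(6)).parameters())
        assert n_dp > n_sh

    def test_deterministic_forward(self):
        cfg = BackboneConfig(base_channels=2, channel_cap=4, shallow_conv_blocks=3,
                             shallow_res_stages=4, deep_res_stages=6, res_kernel=3)
        bb = Backbone(cfg, level=0, rng=np.random.default_rng(7))
        x = Tensor(RNG.normal(size=(1, 16, 16, 16)).astype(np.float32))
        a = bb(x, 1.0)[-1].tensor.data
        b = bb(x, 1.0)[-1].tensor.data
        np.testing.assert_array_equal(a, b)


class TestMsFPN:
    def test_single_map_reduces_to_projection(self):
        rng = np.random.default_rng(8)
        fpn = MsFPN([3], [], fpn_channels=5, rng=rng)
        fm = FeatureMap(tensor=_x(3, 4), level=0, scale=0, stride=1.0)
        out = fpn([fm], [])
        assert out.fused
        lat = fpn.lateral[0][0]
        np.testing.assert_allclose(out.maps[0].tensor.data,
                                   lat(fm.tensor).data, atol=1e-6)

    def test_fused_dims_match_inputs_and_channels_uniform(self, tiny_cfg):
        enc = CoReTrEncoder(tiny_cfg, rng=np.random.default_rng(9))
        x = Tensor(RNG.random((1, 16, 16, 16)).astype(np.float32))
        pyr = enc(x)
        assert pyr.fused
        assert len({m.channels for m in pyr.maps}) == 1
        shallow = pyr.level_maps(0)
        assert [m.dims[0] for m in shallow] == [32, 16, 8, 4]

    def test_identity_projection_with_zero_neighbors(self):
        """With the lateral projection forced to identity and no neighbor
        terms, fusion passes the map through unchanged."""
        rng = np.random.default_rng(10)
        fpn = MsFPN([4], [], fpn_channels=4, rng=rng)
        conv = fpn.lateral[0][0]
        conv.weight.data[:] = 0.0
        for c in range(4):
            conv.weight.data[c, c, 0, 0, 0] = 1.0
        conv.bias.data[:] = 0.0
        fm = FeatureMap(tensor=_x(4, 4), level=0, scale=0, stride=1.0)
        out = fpn([fm], [])
        np.testing.assert_allclose(out.maps[0].tensor.data, fm.tensor.data, atol=1e-6)

    def test_duplicate_scale_rejected(self):
        fm = FeatureMap(tensor=_x(2, 4), level=0, scale=0, stride=1.0)
        with pytest.raises(ValueError, match="duplicate"):
            FeaturePyramid(maps=[fm, fm])

    def test_empty_pyramid_rejected(self):
        rng = np.random.default_rng(11)
        fpn = MsFPN([], [], fpn_channels=4, rng=rng)
        with pytest.raises(ValueError, match="empty"):
            fpn([], [])


def test_multi_resolution_switch_changes_input_resolution(tiny_cfg):
    import dataclasses
    cfg_native = dataclasses.replace(tiny_cfg, multi_resolution_input=False)
    enc = CoReTrEncoder(cfg_native, rng=np.random.default_rng(12))
    x = Tensor(RNG.random((1, 16, 16, 16)).astype(np.float32))
    pyr = enc(x)
    shallow = pyr.level_maps(0)
    assert [m.dims[0] for m in shallow] == [16, 8, 4, 2]
    assert shallow[0].stride == 1.0
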