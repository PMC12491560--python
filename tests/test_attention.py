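"""Spatial-channel attention against brute-force oracles."""

import numpy as np
import pytest

import lmsaunet.autograd as ag
from lmsaunet.attention import (ChannelAttentionConfig, SpatialAttentionConfig,
                                SpatialChannelAttention, channel_attention,
                                channel_pool_spatial, eca_kernel_size,
                                fuse_attention, global_avg_pool, spatial_attention)
from lmsaunet.errors import ConfigurationError, DimensionError
from lmsaunet.nn_core import count_parameters

RNG = np.random.default_rng(5)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestChannelPool:
    def test_constant_input(self):
        out = channel_pool_spatial(np.full((5, 3, 3), 2.0))
        assert out.shape == (2, 3, 3)
        np.testing.assert_allclose(out, 2.0)

    def test_single_hot_channel(self):
        x = np.zeros((4, 2, 2))
        x[1] = 3.0
        out = channel_pool_spatial(x)
        np.testing.assert_allclose(out[0], 3.0)       # max
        np.testing.assert_allclose(out[1], 3.0 / 4)   # mean

    def test_matches_nested_loop_oracle(self):
        x = RNG.standard_normal((3, 4, 4))
        out = channel_pool_spatial(x)
        for h in range(4):
            for w in range(4):
                assert out[0, h, w] == max(x[c, h, w] for c in range(3))
                assert out[1, h, w] == pytest.approx(
                    sum(x[c, h, w] for c in range(3)) / 3)


class TestSpatialAttention:
    def test_zero_weights_give_half_everywhere(self):
        out = spatial_attention(RNG.random((4, 6, 6)), np.zeros((1, 2, 7, 7)))
        np.testing.assert_allclose(out, 0.5)

    def test_output_strictly_in_unit_interval(self):
        out = spatial_attention(RNG.standard_normal((4, 8, 8)),
                                RNG.standard_normal((1, 2, 7, 7)) * 0.2)
        assert np.all(out > 0) and np.all(out < 1)

    def test_matches_composed_brute_force(self):
        x = RNG.standard_normal((4, 8, 8))
        cfg = SpatialAttentionConfig(kernel_size=3)
        w = RNG.standard_normal((1, 2, 3, 3))
        out = spatial_attention(x, w, cfg)
        pooled = np.pad(channel_pool_spatial(x), ((0, 0), (1, 1), (1, 1)))
        expected = np.zeros((8, 8))
        for h in range(8):
            for wd in range(8):
                acc = 0.0
                for c in range(2):
                    for i in range(3):
                        for j in range(3):
                            acc += w[0, c, i, j] * pooled[c, h + i, wd + j]
                expected[h, wd] = _sigmoid(acc)
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            SpatialAttentionConfig(kernel_size=4)


class TestGlobalAvgPool:
    def test_constant_channel(self):
        assert global_avg_pool(np.full((1, 3, 3), 4.0))[0] == 4.0

    def test_half_ones(self):
        x = np.zeros((1, 2, 4))
        x[0, 0] = 1.0
        assert global_avg_pool(x)[0] == 0.5

    def test_matches_mean_oracle(self):
        x = RNG.standard_normal((5, 3, 3))
        np.testing.assert_allclose(global_avg_pool(x),
                                   [x[c].mean() for c in range(5)])


class TestEcaKernel:
    @pytest.mark.parametrize("c,expected", [(2, 1), (64, 3), (512, 5), (8, 1),
                                            (128, 3), (256, 5)])
    def test_adaptive_size(self, c, expected):
        assert eca_kernel_size(c) == expected

    def test_result_is_odd_and_positive(self):
        for c in range(1, 600, 7):
            k = eca_kernel_size(c)
            assert k >= 1 and k % 2 == 1


class TestChannelAttention:
    def test_zero_kernel_gives_half(self):
        x = RNG.random((64, 4, 4))
        np.testing.assert_allclose(channel_attention(x, np.zeros(3)), 0.5)

    def test_strictly_in_unit_interval(self):
        out = channel_attention(RNG.standard_normal((64, 4, 4)) * 9,
                                RNG.standard_normal(3))
        assert np.all(out > 0) and np.all(out < 1)

    def test_matches_sliding_window_oracle(self):
        # gamma=1, b=0 makes the adaptive size 3 for an 8-channel map
        cfg = ChannelAttentionConfig(gamma=1.0, b=0.0)
        x = RNG.standard_normal((8, 3, 3))
        kern = RNG.standard_normal(3)
        out = channel_attention(x, kern, cfg)
        s = np.pad(global_avg_pool(x), 1)
        expected = [_sigmoid(sum(kern[i] * s[c + i] for i in range(3)))
                    for c in range(8)]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_kernel_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError, match="adaptive"):
            channel_attention(RNG.random((64, 2, 2)), np.zeros(5))


class TestFusion:
    def test_identity_when_channel_only_ones(self):
        x = RNG.random((3, 4, 4))
        out = fuse_attention(x, np.ones(3), RNG.random((4, 4)), alpha=1.0, beta=0.0)
        np.testing.assert_allclose(out, x)

    def test_zero_weights_zero_output(self):
        x = RNG.random((3, 4, 4))
        assert np.all(fuse_attention(x, np.ones(3), np.ones((4, 4)), 0.0, 0.0) == 0)

    def test_hand_broadcast_example(self):
        x = RNG.random((2, 2, 2))
        out = fuse_attention(x, np.array([0.5, 1.0]), np.full((2, 2), 0.5), 0.5, 0.5)
        for c, cw in enumerate([0.5, 1.0]):
            np.testing.assert_allclose(out[c], x[c] * (0.5 * cw + 0.25))

    def test_linear_in_input(self):
        x = RNG.standard_normal((3, 4, 4))
        ch, sp = RNG.random(3), RNG.random((4, 4))
        np.testing.assert_allclose(fuse_attention(3 * x, ch, sp, 0.3, 0.7),
                                   3 * fuse_attention(x, ch, sp, 0.3, 0.7))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            fuse_attention(RNG.random((3, 4, 4)), np.ones(2), np.ones((4, 4)), 1, 1)


class TestSCAModule:
    def test_translation_invariance_on_constants(self):
        sca = SpatialChannelAttention(8, rng=np.random.default_rng(3))
        x = np.full((1, 8, 16, 16), 1.7, dtype=np.float32)
        out = sca(ag.Tensor(x)).data
        # constant input -> constant gates away from the zero-padded border
        interior = out[0, :, 3:-3, 3:-3]
        for c in range(8):
            np.testing.assert_allclose(interior[c], interior[c, 0, 0], atol=1e-6)

    def test_parameter_cost_bound_for_512_channels(self):
        sca = SpatialChannelAttention(512)
        total = count_parameters(sca).total
        ks = sca.spatial_cfg.kernel_size
        assert total <= ks * ks * 2 + eca_kernel_size(512) + 2
        assert total == 105  # 98 + 5 + 2 with the default configuration

    def test_gate_module_matches_functional_pipeline(self):
        sca = SpatialChannelAttention(6, rng=np.random.default_rng(1))
        x = RNG.standard_normal((1, 6, 5, 5)).astype(np.float32)
        out = sca(ag.Tensor(x)).data[0]
        sp = spatial_attention(x[0], sca.spatial_weight.data,
                               sca.spatial_cfg)
        ch = channel_attention(x[0], sca.channel_kernel.data, sca.channel_cfg)
        expected = fuse_attention(x[0], ch, sp, float(sca.alpha.data),
                                  float(sca.beta.data))
        np.testing.assert_allclose(out, expected, rtol=2e-5, atol=1e-6)
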