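"""Elementary ops against brute-force oracles, and the parameter auditor."""

import numpy as np
import pytest

from lmsaunet import nn_core
from lmsaunet.errors import ConfigurationError, DimensionError
from lmsaunet.nn_core import (BatchNorm2d, DepthwiseConv, Module, PointwiseConv,
                              bicubic_matrix, bicubic_upsample_x2, conv_param_count,
                              count_parameters, depthwise_conv, downsample_2x2,
                              pointwise_conv)

RNG = np.random.default_rng(99)


# -- pointwise convolution -------------------------------------------------

class TestPointwise:
    def test_zero_weights_give_zero_output(self):
        x = RNG.random((3, 4, 4))
        out = pointwise_conv(x, np.zeros((5, 3)))
        assert out.shape == (5, 4, 4)
        assert np.all(out == 0)

    def test_identity_weights_reproduce_input(self):
        x = RNG.random((4, 5, 5))
        np.testing.assert_allclose(pointwise_conv(x, np.eye(4)), x)

    def test_hand_example(self):
        # per-pixel channel vector (1,2); weight rows (1,1) and (0,1) -> (3,2)
        x = np.stack([np.ones((2, 2)), 2 * np.ones((2, 2))])
        out = pointwise_conv(x, np.array([[1.0, 1.0], [0.0, 1.0]]))
        np.testing.assert_allclose(out[0], 3.0)
        np.testing.assert_allclose(out[1], 2.0)

    def test_matches_per_pixel_matvec_oracle(self):
        x = RNG.standard_normal((6, 4, 4))
        w = RNG.standard_normal((3, 6))
        out = pointwise_conv(x, w)
        expected = np.empty((3, 4, 4))
        for h in range(4):
            for wd in range(4):
                expected[:, h, wd] = w @ x[:, h, wd]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_channel_mismatch_names_both_counts(self):
        with pytest.raises(ConfigurationError, match="3.*5|5.*3"):
            pointwise_conv(RNG.random((5, 2, 2)), np.zeros((4, 3)))


# -- depthwise convolution -------------------------------------------------

def _correlate2d_oracle(channel, kernel):
    """Zero-padded same-size 2-D correlation by explicit loops."""
    k = kernel.shape[0]
    p = k // 2
    h, w = channel.shape
    padded = np.pad(channel, p)
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            for i in range(k):
                for j in range(k):
                    out[y, x] += kernel[i, j] * padded[y + i, x + j]
    return out


class TestDepthwise:
    def test_box_kernel_center_sums_window(self):
        x = np.ones((1, 5, 5))
        out = depthwise_conv(x, np.ones((1, 3, 3)))
        assert out[0, 2, 2] == 9.0

    def test_zero_kernel_gives_zero(self):
        assert np.all(depthwise_conv(RNG.random((2, 5, 5)), np.zeros((2, 3, 3))) == 0)

    def test_impulse_reproduces_kernel(self):
        x = np.zeros((1, 5, 5))
        x[0, 2, 2] = 1.0
        kern = RNG.standard_normal((1, 3, 3))
        out = depthwise_conv(x, kern)
        # correlation convention: the kernel appears index-flipped around the impulse
        np.testing.assert_allclose(out[0, 1:4, 1:4], kern[0, ::-1, ::-1], atol=1e-12)

    def test_matches_per_channel_oracle(self):
        x = RNG.standard_normal((3, 5, 5))
        kern = RNG.standard_normal((3, 3, 3))
        out = depthwise_conv(x, kern)
        for c in range(3):
            np.testing.assert_allclose(out[c], _correlate2d_oracle(x[c], kern[c]),
                                       atol=1e-12)

    def test_no_cross_channel_mixing(self):
        x = np.zeros((2, 5, 5))
        x[0] = RNG.random((5, 5))
        out = depthwise_conv(x, RNG.standard_normal((2, 3, 3)))
        assert np.all(out[1] == 0)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(DimensionError):
            depthwise_conv(np.ones((1, 2, 2)), np.ones((1, 7, 7)), padding=1)


# -- parameter counting ----------------------------------------------------

class TestParamCount:
    @pytest.mark.parametrize("args,expected", [
        ((1024, 1024, 3), 9_437_184),
        ((64, 2, 1), 128),
        ((3, 64, 3), 1_728),
    ])
    def test_closed_form(self, args, expected):
        assert conv_param_count(*args) == expected

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            conv_param_count(0, 4, 3)

    @pytest.mark.parametrize("c", [16, 32, 64, 256])
    @pytest.mark.parametrize("k", [3, 5, 7])
    def test_separable_pair_saves_parameters(self, c, k):
        # depthwise C*K^2 + pointwise C*C < dense C*C*K^2 whenever C > K^2/(K^2-1)
        dense = conv_param_count(c, c, k)
        separable = c * k * k + conv_param_count(c, c, 1)
        assert separable < dense

    def test_count_parameters_additive_and_size_independent(self):
        class Pair(Module):
            def __init__(self):
                self.a = PointwiseConv(64, 128)
                self.b = DepthwiseConv(32, 3)

        report = count_parameters(Pair())
        assert dict(report.per_component)["a.weight"] == 8192
        assert report.total == 8192 + 32 * 9
        assert report.total_millions == report.total / 1e6

    def test_flops_are_twice_macs(self):
        model = PointwiseConv(64, 128)

        class Wrap(Module):
            def __init__(self, inner):
                self.inner = inner

            def audit_macs(self, h, w):
                return self.inner.macs(h, w)

        report = nn_core.estimate_macs(Wrap(model), 16, 16)
        assert report.mac_count == 64 * 128 * 256 == 2_097_152
        assert report.flop_count == 2 * report.mac_count

    def test_estimate_macs_requires_divisible_by_16(self):
        class Zero(Module):
            def audit_macs(self, h, w):
                return 0

        with pytest.raises(DimensionError):
            nn_core.estimate_macs(Zero(), 50, 50)
        assert nn_core.estimate_macs(Zero(), 16, 16).mac_count == 0


# -- pooling ---------------------------------------------------------------

class TestPooling:
    @pytest.mark.parametrize("mode", ["max", "average"])
    def test_constant_preserved(self, mode):
        x = np.full((2, 4, 4), 3.5)
        out = downsample_2x2(x, mode)
        assert out.shape == (2, 2, 2)
        np.testing.assert_allclose(out, 3.5)

    def test_max_pool_peak(self):
        x = np.zeros((1, 4, 4))
        x[0, 1, 2] = 5.0
        out = downsample_2x2(x, "max")
        assert out[0, 0, 1] == 5.0 and out.sum() == 5.0

    def test_average_matches_window_mean_oracle(self):
        x = RNG.random((2, 6, 6))
        out = downsample_2x2(x, "average")
        for c in range(2):
            for i in range(3):
                for j in range(3):
                    assert out[c, i, j] == pytest.approx(
                        x[c, 2 * i:2 * i + 2, 2 * j:2 * j + 2].mean())

    def test_odd_size_rejected(self):
        with pytest.raises(DimensionError, match="even"):
            downsample_2x2(np.ones((1, 5, 4)))


# -- bicubic up-sampling ---------------------------------------------------

def _keys_weight(t, a=-0.5):
    t = abs(t)
    if t <= 1:
        return (a + 2) * t ** 3 - (a + 3) * t ** 2 + 1
    if t < 2:
        return a * t ** 3 - 5 * a * t ** 2 + 8 * a * t - 4 * a
    return 0.0


def _bicubic_oracle(x):
    """Direct per-pixel 4x4-tap evaluation, half-pixel centers, clamped borders."""
    c, h, w = x.shape
    out = np.zeros((c, 2 * h, 2 * w))
    for oy in range(2 * h):
        cy = (oy + 0.5) / 2 - 0.5
        by = int(np.floor(cy))
        for ox in range(2 * w):
            cx = (ox + 0.5) / 2 - 0.5
            bx = int(np.floor(cx))
            wy = np.array([_keys_weight(cy - (by + d)) for d in (-1, 0, 1, 2)])
            wx = np.array([_keys_weight(cx - (bx + d)) for d in (-1, 0, 1, 2)])
            wy, wx = wy / wy.sum(), wx / wx.sum()
            acc = 0.0
            for dy in range(4):
                for dx in range(4):
                    iy = min(max(by - 1 + dy, 0), h - 1)
                    ix = min(max(bx - 1 + dx, 0), w - 1)
                    acc += wy[dy] * wx[dx] * x[:, iy, ix]
            out[:, oy, ox] = acc
    return out


class TestBicubic:
    def test_constants_reproduced(self):
        out = bicubic_upsample_x2(np.full((3, 4, 6), 2.25))
        assert out.shape == (3, 8, 12)
        np.testing.assert_allclose(out, 2.25, atol=1e-12)

    def test_shape_contract(self):
        assert bicubic_upsample_x2(np.zeros((1, 64, 64))).shape == (1, 128, 128)

    def test_ramp_matches_reference_resampler(self):
        yy, xx = np.mgrid[0:6, 0:8].astype(float)
        ramp = (0.3 + 0.5 * xx + 0.2 * yy)[None]
        np.testing.assert_allclose(bicubic_upsample_x2(ramp), _bicubic_oracle(ramp),
                                   atol=1e-5)

    def test_random_map_matches_reference(self):
        x = RNG.standard_normal((2, 5, 7))
        np.testing.assert_allclose(bicubic_upsample_x2(x), _bicubic_oracle(x),
                                   atol=1e-10)

    def test_interior_of_ramp_is_exact(self):
        # cubic interpolation reproduces affine functions away from clamped borders
        yy, xx = np.mgrid[0:8, 0:8].astype(float)
        ramp = (1.0 + 2.0 * xx - 0.5 * yy)[None]
        out = bicubic_upsample_x2(ramp)
        oy, ox = np.mgrid[0:16, 0:16]
        expected = 1.0 + 2.0 * ((ox + 0.5) / 2 - 0.5) - 0.5 * ((oy + 0.5) / 2 - 0.5)
        np.testing.assert_allclose(out[0, 3:-3, 3:-3], expected[3:-3, 3:-3], atol=1e-9)

    def test_rows_are_a_partition_of_unity(self):
        np.testing.assert_allclose(bicubic_matrix(9).sum(axis=1), 1.0, atol=1e-12)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(DimensionError):
            bicubic_upsample_x2(np.ones((1, 1, 8)))


# -- batch norm ------------------------------------------------------------

def test_batchnorm_normalizes_then_tracks_running_stats():
    import lmsaunet.autograd as ag

    bn = BatchNorm2d(3, momentum=0.5)
    x = RNG.standard_normal((4, 3, 5, 5)) * 3 + 1
    out = bn(ag.Tensor(x.astype(np.float32)))
    np.testing.assert_allclose(out.data.mean(axis=(0, 2, 3)), 0, atol=1e-5)
    np.testing.assert_allclose(out.data.std(axis=(0, 2, 3)), 1, atol=1e-3)
    bn.eval()
    out_eval = bn(ag.Tensor(x.astype(np.float32)))
    assert out_eval.data.shape == x.shape
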