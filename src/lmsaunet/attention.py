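"""Parallel spatial-channel attention (SCA).

Two multiplicative gates computed independently and fused with learnable
scalars: a spatial gate from per-pixel channel max/mean pooling followed by
a KxK convolution and sigmoid, and a channel gate in the efficient-channel-
attention style — global average pooling followed by an adaptively sized
1-D convolution across the channel axis and sigmoid.  The fused weight
field alpha*channel + beta*spatial multiplies the input feature map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .errors import ConfigurationError, DimensionError
from .nn_core import Module, _chw


@dataclass
class SpatialAttentionConfig:
    """KxK conv over the 2-channel pooled map; kernel_size must be odd >= 3."""

    kernel_size: int = 7

    def __post_init__(self):
        if self.kernel_size % 2 == 0 or self.kernel_size < 3:
            raise ConfigurationError(
                f"spatial attention kernel must be odd and >= 3, got {self.kernel_size}")


@dataclass
class ChannelAttentionConfig:
    """Hyperparameters of the adaptive 1-D channel-attention kernel.

    k = largest odd integer <= log2(C)/gamma + b, clamped below at 1.
    Defaults gamma=2, b=1 are the standard efficient-channel-attention values.
    """

    gamma: float = 2.0
    b: float = 1.0


def eca_kernel_size(c: int, cfg: ChannelAttentionConfig | None = None) -> int:
    """Adaptive odd 1-D kernel size for a C-channel map."""
    cfg = cfg or ChannelAttentionConfig()
    if c < 1:
        raise ValueError(f"channel count must be positive, got {c}")
    val = np.log2(c) / cfg.gamma + cfg.b
    k = int(np.floor(val))
    if k % 2 == 0:
        k -= 1
    return max(k, 1)


# -- functional pieces (plain CHW arrays; used directly by tests/oracles) --

def channel_pool_spatial(x: np.ndarray) -> np.ndarray:
    """Stack per-pixel channel max and channel mean into a 2xHxW map."""
    x = _chw(x)
    return np.stack([x.max(axis=0), x.mean(axis=0)])


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean: a length-C statistics vector."""
    x = _chw(x)
    return x.mean(axis=(1, 2))


def spatial_attention(x: np.ndarray, weights: np.ndarray,
                      cfg: SpatialAttentionConfig | None = None) -> np.ndarray:
    """Sigmoid of the same-padded KxK conv of the pooled map: 1xHxW in (0,1)."""
    cfg = cfg or SpatialAttentionConfig()
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (1, 2, cfg.kernel_size, cfg.kernel_size):
        raise ConfigurationError(
            f"spatial attention weights must be (1,2,{cfg.kernel_size},{cfg.kernel_size}), "
            f"got {weights.shape}")
    pooled = channel_pool_spatial(x)
    g = ag.dense_conv2d(ag.Tensor(pooled[None]), ag.Tensor(weights))
    return ag.sigmoid(g).data[0]


def channel_attention(x: np.ndarray, kernel: np.ndarray,
                      cfg: ChannelAttentionConfig | None = None) -> np.ndarray:
    """Sigmoid of the zero-padded 1-D conv of the pooled channel vector."""
    cfg = cfg or ChannelAttentionConfig()
    x = _chw(x)
    kernel = np.asarray(kernel, dtype=np.float64).reshape(-1)
    k = eca_kernel_size(x.shape[0], cfg)
    if kernel.shape[0] != k:
        raise ConfigurationError(
            f"channel attention kernel length {kernel.shape[0]} != adaptive size {k} "
            f"for C={x.shape[0]}")
    s = global_avg_pool(x)
    out = ag.conv1d_same(ag.Tensor(s[None]), ag.Tensor(kernel))
    return ag.sigmoid(out).data[0]


def fuse_attention(x: np.ndarray, ch_w: np.ndarray, sp_w: np.ndarray,
                   alpha: float, beta: float) -> np.ndarray:
    """X' = X * (alpha * channel_weight + beta * spatial_weight), broadcast."""
    x = _chw(x)
    ch_w = np.asarray(ch_w, dtype=np.float64).reshape(-1)
    sp_w = np.asarray(sp_w, dtype=np.float64)
    if sp_w.ndim == 3:
        sp_w = sp_w[0]
    if ch_w.shape[0] != x.shape[0]:
        raise DimensionError(
            f"channel weights length {ch_w.shape[0]} != {x.shape[0]} channels")
    if sp_w.shape != x.shape[1:]:
        raise DimensionError(
            f"spatial weights {sp_w.shape} != spatial size {x.shape[1:]}")
    return x * (alpha * ch_w[:, None, None] + beta * sp_w[None])


# -- trainable module ------------------------------------------------------


class SpatialChannelAttention(Module):
    """The full SCA unit as a trainable layer on batched NCHW tensors.

    Parameter cost: 2*k_s^2 (spatial conv) + k (channel conv) + 2 (alpha, beta).
    """

    def __init__(self, channels: int,
                 spatial_cfg: SpatialAttentionConfig | None = None,
                 channel_cfg: ChannelAttentionConfig | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.spatial_cfg = spatial_cfg or SpatialAttentionConfig()
        self.channel_cfg = channel_cfg or ChannelAttentionConfig()
        ks = self.spatial_cfg.kernel_size
        self.spatial_weight = ag.Tensor(
            (rng.standard_normal((1, 2, ks, ks)) * np.sqrt(2.0 / (2 * ks * ks))
             ).astype(np.float32), requires_grad=True)
        k = eca_kernel_size(channels, self.channel_cfg)
        self.channel_kernel = ag.Tensor(
            (rng.standard_normal(k) * np.sqrt(2.0 / k)).astype(np.float32),
            requires_grad=True)
        # symmetric start: learning chooses the spatial/channel balance
        self.alpha = ag.Tensor(np.float32(0.5), requires_grad=True)
        self.beta = ag.Tensor(np.float32(0.5), requires_grad=True)

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        b, c, h, w = x.shape
        if c != self.channels:
            raise ConfigurationError(f"SCA built for {self.channels} channels, got {c}")
        pooled = ag.concat_channels([ag.channel_max(x), ag.tmean(x, axis=1, keepdims=True)])
        sp = ag.sigmoid(ag.dense_conv2d(pooled, self.spatial_weight))      # (B,1,H,W)
        s = ag.tmean(x, axis=(2, 3))                                       # (B,C)
        ch = ag.sigmoid(ag.conv1d_same(s, self.channel_kernel))            # (B,C)
        ch = ag.reshape(ch, (b, c, 1, 1))
        gate = ag.add(ag.mul(ch, self.alpha), ag.mul(sp, self.beta))
        return ag.mul(x, gate)

    def macs(self, h: int, w: int) -> int:
        c = self.channels
        k = self.channel_kernel.data.size
        ks = self.spatial_cfg.kernel_size
        pool = 2 * c * h * w                  # channel max + mean per pixel
        spconv = 2 * ks * ks * h * w          # 2-channel KxK conv to 1 map
        gap = c * h * w
        eca = c * k
        apply = 2 * c * h * w                 # gate sum + multiply
        return pool + spconv + gap + eca + apply
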