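"""The ECDF feature-extraction block.

One ECDF unit replaces the two dense 3x3 convolutions of a classical U-Net
stage.  It exploits channel redundancy: a pointwise convolution compresses
the input to C_out/N channels (N a power of two), the compressed map is
split into two halves of C_out/(2N) channels, each half passes through a
sequential cascade of (N-2)/2 depthwise convolutions whose every
intermediate is saved, and the compressed map plus all (N-2) saved maps are
concatenated — by construction exactly

    C_out/N + (N-2) * C_out/(2N) = C_out/2

channels of mixed receptive-field content.  Parallel spatial-channel
attention gates the concatenated map, and a final pointwise convolution
fuses it up to C_out channels.

Normalization/activation placement (batch norm + ReLU after the compression
and after each depthwise convolution, nothing after the fusion) and the
grouped-vs-dense fusion knob are deliberate free choices exposed in
``ECDFConfig``; the auditor reports their cost separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .attention import (ChannelAttentionConfig, SpatialAttentionConfig,
                        SpatialChannelAttention, eca_kernel_size)
from .errors import ConfigurationError
from .nn_core import BatchNorm2d, DepthwiseConv, Module, PointwiseConv


@dataclass
class ECDFConfig:
    in_channels: int
    out_channels: int
    compression_factor: int = 8
    dw_kernel: int = 3
    attention_enabled: bool = True
    fusion_groups: int = 2
    norm: str = "batch"          # "batch" | "none"
    activation: str = "relu"     # "relu" | "none"

    def __post_init__(self):
        n = self.compression_factor
        if n < 2 or (n & (n - 1)) != 0:
            raise ConfigurationError(f"compression factor must be a power of two >= 2, got {n}")
        if self.out_channels % (2 * n):
            raise ConfigurationError(
                f"out_channels={self.out_channels} must be divisible by 2N={2 * n}")
        if self.dw_kernel % 2 == 0:
            raise ConfigurationError(f"depthwise kernel must be odd, got {self.dw_kernel}")
        if self.fusion_groups not in (1, 2):
            raise ConfigurationError(f"fusion_groups must be 1 or 2, got {self.fusion_groups}")
        if self.norm not in ("batch", "none"):
            raise ConfigurationError(f"norm must be 'batch' or 'none', got {self.norm!r}")
        if self.activation not in ("relu", "none"):
            raise ConfigurationError(f"activation must be 'relu' or 'none'")

    @property
    def mid_channels(self) -> int:
        """Width of the compressed map, C_out / N."""
        return self.out_channels // self.compression_factor

    @property
    def branch_channels(self) -> int:
        """Width of each cascade half, C_out / (2N)."""
        return self.out_channels // (2 * self.compression_factor)

    @property
    def cascade_depth(self) -> int:
        """Depthwise convolutions per branch, (N-2)/2."""
        return (self.compression_factor - 2) // 2

    @property
    def concat_channels(self) -> int:
        """Assembled width: compressed map plus both cascades = C_out/2."""
        return self.mid_channels + 2 * self.cascade_depth * self.branch_channels


# -- functional pieces on plain CHW arrays ---------------------------------

def split_halves(x: np.ndarray):
    """Split channels [0, C/2) and [C/2, C), order preserved."""
    x = np.asarray(x)
    c = x.shape[0]
    if c % 2:
        raise ConfigurationError(f"cannot split odd channel count {c}")
    return x[: c // 2], x[c // 2:]


def branch_cascade(half: np.ndarray, kernels, norm=None, activation=None):
    """Sequential depthwise cascade; returns every intermediate, in order.

    ``kernels`` is an ordered list of (C,K,K) arrays, one per cascade step.
    Optional ``norm``/``activation`` callables are applied after each step.
    """
    from .nn_core import depthwise_conv

    outputs = []
    current = np.asarray(half, dtype=np.float64)
    for kern in kernels:
        kern = np.asarray(kern)
        if kern.shape[0] != current.shape[0]:
            raise ConfigurationError(
                f"cascade kernel has {kern.shape[0]} channels for a "
                f"{current.shape[0]}-channel half (check N)")
        current = depthwise_conv(current, kern)
        if norm is not None:
            current = norm(current)
        if activation is not None:
            current = activation(current)
        outputs.append(current)
    return outputs


def assemble_concat(xp: np.ndarray, branch1, branch2) -> np.ndarray:
    """Channel-stack [compressed map, cascade 1 outputs, cascade 2 outputs]."""
    maps = [np.asarray(xp)] + [np.asarray(m) for m in branch1] + \
           [np.asarray(m) for m in branch2]
    spatial = maps[0].shape[1:]
    for m in maps:
        if m.shape[1:] != spatial:
            raise ConfigurationError(f"spatial mismatch in concat: {m.shape[1:]} vs {spatial}")
    return np.concatenate(maps, axis=0)


def ecdf_param_count(cfg: ECDFConfig) -> int:
    """Closed-form trainable-scalar count of one ECDF block."""
    k2 = cfg.dw_kernel ** 2
    n = cfg.compression_factor
    compress = cfg.in_channels * cfg.mid_channels
    dw = (n - 2) * k2 * cfg.branch_channels
    fuse = cfg.concat_channels * cfg.out_channels // cfg.fusion_groups
    sca = 0
    if cfg.attention_enabled:
        ks = SpatialAttentionConfig().kernel_size
        sca = 2 * ks * ks + eca_kernel_size(cfg.concat_channels) + 2
    norm = 0
    if cfg.norm == "batch":
        norm = 2 * cfg.mid_channels + (n - 2) * 2 * cfg.branch_channels
    return compress + dw + fuse + sca + norm


# -- trainable block -------------------------------------------------------


class ECDFBlock(Module):
    """Backbone-agnostic ECDF unit: constructor takes (C_in, C_out, N, switches)."""

    def __init__(self, in_channels: int, out_channels: int,
                 compression_factor: int = 8, *, dw_kernel: int = 3,
                 attention_enabled: bool = True, fusion_groups: int = 2,
                 norm: str = "batch", activation: str = "relu",
                 spatial_cfg: SpatialAttentionConfig | None = None,
                 channel_cfg: ChannelAttentionConfig | None = None,
                 rng: np.random.Generator | None = None):
        cfg = ECDFConfig(in_channels, out_channels, compression_factor,
                         dw_kernel, attention_enabled, fusion_groups,
                         norm, activation)
        rng = rng or np.random.default_rng(0)
        self.config = cfg
        self.pw_compress = PointwiseConv(in_channels, cfg.mid_channels, rng=rng)
        self.compress_norm = BatchNorm2d(cfg.mid_channels) if cfg.norm == "batch" else None
        self.branch1 = [DepthwiseConv(cfg.branch_channels, dw_kernel, rng=rng)
                        for _ in range(cfg.cascade_depth)]
        self.branch2 = [DepthwiseConv(cfg.branch_channels, dw_kernel, rng=rng)
                        for _ in range(cfg.cascade_depth)]
        if cfg.norm == "batch":
            self.branch1_norms = [BatchNorm2d(cfg.branch_channels)
                                  for _ in range(cfg.cascade_depth)]
            self.branch2_norms = [BatchNorm2d(cfg.branch_channels)
                                  for _ in range(cfg.cascade_depth)]
        else:
            self.branch1_norms = self.branch2_norms = None
        self.sca = (SpatialChannelAttention(cfg.concat_channels, spatial_cfg,
                                            channel_cfg, rng=rng)
                    if attention_enabled else None)
        self.pw_fuse = PointwiseConv(cfg.concat_channels, out_channels,
                                     groups=fusion_groups, rng=rng)

    # internal: act/norm helper
    def _post(self, x, norm_layer):
        if norm_layer is not None:
            x = norm_layer(x)
        if self.config.activation == "relu":
            x = ag.relu(x)
        return x

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        cfg = self.config
        if x.shape[1] != cfg.in_channels:
            raise ConfigurationError(
                f"ECDF block expects {cfg.in_channels} channels, input has {x.shape[1]}")
        xp = self._post(self.pw_compress(x), self.compress_norm)
        bc = cfg.branch_channels
        half1 = ag.narrow_channels(xp, 0, bc)
        half2 = ag.narrow_channels(xp, bc, bc)
        saved = [xp]
        for branch, norms, cur in ((self.branch1, self.branch1_norms, half1),
                                   (self.branch2, self.branch2_norms, half2)):
            for i, dw in enumerate(branch):
                cur = self._post(dw(cur), norms[i] if norms else None)
                saved.append(cur)
        cat = saved[0] if len(saved) == 1 else ag.concat_channels(saved)
        if self.sca is not None:
            cat = self.sca(cat)
        return self.pw_fuse(cat)

    def macs(self, h: int, w: int) -> int:
        total = self.pw_compress.macs(h, w)
        if self.compress_norm is not None:
            total += self.compress_norm.macs(h, w)
        for dw in self.branch1 + self.branch2:
            total += dw.macs(h, w)
        if self.branch1_norms:
            for bn in self.branch1_norms + self.branch2_norms:
                total += bn.macs(h, w)
        if self.sca is not None:
            total += self.sca.macs(h, w)
        total += self.pw_fuse.macs(h, w)
        return total
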