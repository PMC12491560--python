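"""Assembly of the full encoder-decoder segmentation network.

Four encoder stages (ECDF block + 2x2 downsampling), a mirrored decoder
(parameter-free bicubic 2x up-sampling, channel concatenation with the
matching encoder skip, ECDF block), and a final pointwise two-channel
classifier head.  Under the default channel plan (64, 128, 256, 512) the
decoder concatenation widths are 1024, 768, 384 and 192.

Input spatial size must be divisible by 16 (four halvings).  The decoder
concatenation order is [up-sampled map, skip connection].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autograd as ag
from .ecdf import ECDFBlock
from .errors import ConfigurationError, DimensionError
from .nn_core import (BicubicUpsample2x, Downsample2x2, Module, ParamReport,
                      PointwiseConv, count_parameters)

PAPER_STAGE_CHANNELS = (64, 128, 256, 512)
SMALL_STAGE_CHANNELS = (16, 32, 64, 128)


@dataclass
class NetworkConfig:
    """Global architecture switches.

    ``stage_channels`` is the encoder output-width plan; decoder concat
    widths are derived from it, never stored.  ``small()`` gives a
    quarter-width preset for desk-scale CPU experiments.
    """

    stage_channels: tuple[int, ...] = PAPER_STAGE_CHANNELS
    num_classes: int = 2
    compression_factor: int = 8
    pooling: str = "max"
    attention_enabled: bool = True
    attention_gamma: float = 2.0
    attention_b: float = 1.0
    spatial_kernel: int = 7
    fusion_groups: int = 2
    norm: str = "batch"
    seed: int = 0

    def __post_init__(self):
        self.stage_channels = tuple(int(c) for c in self.stage_channels)
        if len(self.stage_channels) != 4:
            raise ConfigurationError("exactly four encoder stages are supported")
        if any(a >= b for a, b in zip(self.stage_channels, self.stage_channels[1:])):
            raise ConfigurationError(
                f"stage channels must be strictly increasing, got {self.stage_channels}")

    @classmethod
    def small(cls, **overrides) -> "NetworkConfig":
        return cls(stage_channels=SMALL_STAGE_CHANNELS, **overrides)

    def to_dict(self) -> dict:
        return {
            "stage_channels": list(self.stage_channels),
            "num_classes": self.num_classes,
            "compression_factor": self.compression_factor,
            "pooling": self.pooling,
            "attention_enabled": self.attention_enabled,
            "attention_gamma": self.attention_gamma,
            "attention_b": self.attention_b,
            "spatial_kernel": self.spatial_kernel,
            "fusion_groups": self.fusion_groups,
            "norm": self.norm,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["stage_channels"] = tuple(d.get("stage_channels", PAPER_STAGE_CHANNELS))
        return cls(**d)


class LMSAUnet(Module):
    """The assembled segmentation network."""

    def __init__(self, config: NetworkConfig | None = None):
        cfg = config or NetworkConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        s1, s2, s3, s4 = cfg.stage_channels
        from .attention import ChannelAttentionConfig, SpatialAttentionConfig

        kw = dict(compression_factor=cfg.compression_factor,
                  attention_enabled=cfg.attention_enabled,
                  fusion_groups=cfg.fusion_groups, norm=cfg.norm,
                  spatial_cfg=SpatialAttentionConfig(cfg.spatial_kernel),
                  channel_cfg=ChannelAttentionConfig(cfg.attention_gamma,
                                                     cfg.attention_b))
        enc_plan = [(3, s1), (s1, s2), (s2, s3), (s3, s4)]
        dec_plan = [(2 * s4, s4), (s4 + s3, s3), (s3 + s2, s2), (s2 + s1, s1)]
        try:
            self.encoder = [ECDFBlock(ci, co, rng=rng, **kw) for ci, co in enc_plan]
            self.decoder = [ECDFBlock(ci, co, rng=rng, **kw) for ci, co in dec_plan]
        except ConfigurationError as exc:
            raise ConfigurationError(f"invalid channel plan {cfg.stage_channels}: {exc}")
        self.down = Downsample2x2(cfg.pooling)
        self.up = BicubicUpsample2x()
        self.head = PointwiseConv(s1, cfg.num_classes, rng=rng)

    # -- forward -----------------------------------------------------------

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        """Map a (B,3,H,W) image batch to (B,num_classes,H,W) logits."""
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise DimensionError(
                f"input spatial size {h}x{w} must be divisible by 16")
        skips = []
        cur = x
        for block in self.encoder:
            cur = block(cur)
            skips.append(cur)
            cur = self.down(cur)
        for block, skip in zip(self.decoder, reversed(skips)):
            cur = self.up(cur)
            cur = ag.concat_channels([cur, skip])
            cur = block(cur)
        return self.head(cur)

    def forward_numpy(self, image: np.ndarray) -> np.ndarray:
        """Inference on a single 3xHxW image; returns num_classes x H x W logits."""
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 3 or image.shape[0] != 3:
            raise DimensionError(f"expected a 3xHxW image, got shape {image.shape}")
        was_training = self.training
        self.eval()
        try:
            with ag.no_grad():
                out = self(ag.Tensor(image[None])).data[0]
        finally:
            self.train(was_training)
        return out

    # -- auditing ----------------------------------------------------------

    def audit_macs(self, h: int, w: int) -> int:
        total = 0
        sizes = [(h, w), (h // 2, w // 2), (h // 4, w // 4), (h // 8, w // 8)]
        for block, (bh, bw) in zip(self.encoder, sizes):
            total += block.macs(bh, bw)
            total += block.config.out_channels * self.down.macs(bh, bw)
        for i, block in enumerate(self.decoder):
            sh, sw = sizes[3 - i]
            up_in = self.config.stage_channels[3] if i == 0 else \
                self.decoder[i - 1].config.out_channels
            total += up_in * self.up.macs(sh // 2, sw // 2)
            total += block.macs(sh, sw)
        total += self.head.macs(h, w)
        return total

    def stage_table(self, input_size: int = 256) -> list[dict]:
        """Per-block (name, output size, C_in, C_out) rows, mirroring the plan."""
        if input_size % 16:
            raise DimensionError(f"input size {input_size} must be divisible by 16")
        rows = []
        s = input_size
        for i, block in enumerate(self.encoder, 1):
            rows.append({"block": f"ECDF BLOCK {i}", "size": f"{s}x{s}",
                         "in": block.config.in_channels, "out": block.config.out_channels})
            c = block.config.out_channels
            s //= 2
            rows.append({"block": f"DOWNSAMPLING {i}", "size": f"{s}x{s}", "in": c, "out": c})
        for i, block in enumerate(self.decoder, 1):
            c_up = self.config.stage_channels[3] if i == 1 else \
                self.decoder[i - 2].config.out_channels
            s *= 2
            rows.append({"block": f"UPSAMPLING {i}", "size": f"{s}x{s}",
                         "in": c_up, "out": c_up})
            rows.append({"block": f"ECDF BLOCK {4 + i}", "size": f"{s}x{s}",
                         "in": block.config.in_channels, "out": block.config.out_channels})
        rows.append({"block": "PWCONV", "size": f"{s}x{s}",
                     "in": self.head.in_channels, "out": self.head.out_channels})
        return rows

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path):
        """Write parameters (.npz) plus a JSON sidecar with the config."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(path, **{k.replace(".", "/"): v for k, v in self.state_dict().items()})
        path.with_suffix(".json").write_text(
            json.dumps({"network_config": self.config.to_dict()}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LMSAUnet":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        cfg = NetworkConfig.from_dict(
            json.loads(path.with_suffix(".json").read_text())["network_config"])
        net = cls(cfg)
        with np.load(path) as data:
            net.load_state_dict({k.replace("/", "."): data[k] for k in data.files})
        return net


def build_network(cfg: NetworkConfig | None = None) -> LMSAUnet:
    return LMSAUnet(cfg)


def predict_mask(logits: np.ndarray) -> np.ndarray:
    """Binary mask from 2xHxW logits: softmax foreground probability > 0.5.

    Ties (equal logits) go to background — the threshold is strict.
    """
    logits = np.asarray(logits)
    if logits.ndim != 3 or logits.shape[0] != 2:
        raise DimensionError(f"expected 2xHxW logits, got shape {logits.shape}")
    prob_fg = 1.0 / (1.0 + np.exp(-(logits[1] - logits[0])))
    return (prob_fg > 0.5).astype(np.uint8)


def summarize(network: LMSAUnet, input_size: int = 256) -> tuple[ParamReport, list[dict]]:
    """ParamReport (with MACs at ``input_size``) plus the per-stage shape table."""
    from .nn_core import estimate_macs

    report = estimate_macs(network, input_size, input_size)
    report.notes["fusion_groups"] = network.config.fusion_groups
    report.notes["norm"] = network.config.norm
    report.notes["attention_enabled"] = network.config.attention_enabled
    report.notes["compression_factor"] = network.config.compression_factor
    return report, network.stage_table(input_size)
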