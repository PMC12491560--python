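"""Elementary network operations and the parameter/MAC auditor.

The building blocks every other module composes: bias-free pointwise
(1x1) and depthwise convolutions, 2x2 pooling, parameter-free bicubic
2x up-sampling, batch normalization, and accounting utilities that report
trainable-parameter and multiply-accumulate counts per component.

Convolutions follow the correlation convention (no kernel flip) and carry
no bias terms, so the auditor's closed-form counts C_in*C_out*K*K hold
exactly.  All layers operate on batched NCHW tensors from `autograd`;
thin functional wrappers accept plain CHW NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .errors import ConfigurationError, DataError, DimensionError

# --------------------------------------------------------------------------
# parameter accounting


@dataclass
class ParamReport:
    """Per-component trainable-scalar tally, optionally with MAC/FLOP counts.

    flop_count follows the 1 MAC = 2 FLOPs convention.
    """

    per_component: list[tuple[str, int]] = field(default_factory=list)
    mac_count: int = 0
    notes: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(n for _, n in self.per_component))

    @property
    def total_millions(self) -> float:
        return self.total / 1e6

    @property
    def flop_count(self) -> int:
        return 2 * self.mac_count

    def to_dict(self) -> dict:
        return {
            "per_component": [[name, int(n)] for name, n in self.per_component],
            "total": self.total,
            "total_millions": self.total_millions,
            "mac_count": int(self.mac_count),
            "flop_count": int(self.flop_count),
            "notes": dict(self.notes),
        }

    def format(self) -> str:
        lines = [f"{name:<40s} {n:>12,d}" for name, n in self.per_component]
        lines.append("-" * 53)
        lines.append(f"{'total':<40s} {self.total:>12,d}  ({self.total_millions:.4f} M)")
        if self.mac_count:
            lines.append(f"{'MACs':<40s} {self.mac_count:>12,d}  "
                         f"({self.mac_count / 1e9:.4f} G; {self.flop_count / 1e9:.4f} GFLOPs)")
        return "\n".join(lines)


def conv_param_count(c_in: int, c_out: int, k: int) -> int:
    """Trainable scalars of one bias-free convolution: C_in * C_out * K * K."""
    if c_in < 1 or c_out < 1 or k < 1:
        raise ValueError(f"conv_param_count requires positive arguments, got "
                         f"({c_in}, {c_out}, {k})")
    return c_in * c_out * k * k


# --------------------------------------------------------------------------
# module base


class Module:
    """Composite of learnable tensors; enumerates them for optimizer and auditor."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, ag.Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, ag.Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def children(self):
        for val in vars(self).items():
            if isinstance(val[1], Module):
                yield val[1]

    def train(self, mode: bool = True):
        self.training = mode
        for name, val in vars(self).items():
            if isinstance(val, Module):
                val.train(mode)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    buffer_names: tuple[str, ...] = ()

    def named_buffers(self, prefix: str = ""):
        """Non-trainable persistent state (e.g. batch-norm running statistics)."""
        for name in self.buffer_names:
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            yield full, self, name
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Module):
                yield from val.named_buffers(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}")

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, owner, attr in self.named_buffers():
            state[name] = np.array(getattr(owner, attr), copy=True)
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = {name: (owner, attr) for name, owner, attr in self.named_buffers()}
        expected = set(params) | set(buffers)
        if expected != set(state):
            missing = expected ^ set(state)
            raise ConfigurationError(f"state dict key mismatch: {sorted(missing)}")
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()
        for name, (owner, attr) in buffers.items():
            setattr(owner, attr,
                    np.asarray(state[name], dtype=getattr(owner, attr).dtype).copy())

    training: bool = True


def count_parameters(model: Module) -> ParamReport:
    """ParamReport over every trainable scalar, additive over composition."""
    report = ParamReport()
    for name, p in model.named_parameters():
        report.per_component.append((name, int(p.data.size)))
    return report


# --------------------------------------------------------------------------
# layers


def _init_conv(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class PointwiseConv(Module):
    """Bias-free 1x1 convolution: per-pixel linear map across channels.

    With groups=2 the input channels are split into two halves, each mapped
    by its own dense matrix to half the outputs (used by the ECDF fusion knob).
    """

    def __init__(self, in_channels: int, out_channels: int, groups: int = 1,
                 rng: np.random.Generator | None = None):
        if in_channels % groups or out_channels % groups:
            raise ConfigurationError(
                f"groups={groups} must divide in={in_channels} and out={out_channels}")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.groups = groups
        self.weight = ag.Tensor(
            _init_conv(rng, (out_channels, in_channels // groups), in_channels // groups),
            requires_grad=True)

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        if x.shape[1] != self.in_channels:
            raise ConfigurationError(
                f"pointwise conv expects {self.in_channels} channels, input has {x.shape[1]}")
        return ag.pointwise_conv2d(x, self.weight, groups=self.groups)

    def macs(self, h: int, w: int) -> int:
        return self.weight.data.size * h * w


class DepthwiseConv(Module):
    """Bias-free per-channel KxK correlation with same padding (stride 1)."""

    def __init__(self, channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        if kernel_size % 2 == 0:
            raise ConfigurationError(f"depthwise kernel must be odd, got {kernel_size}")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.kernel_size = kernel_size
        self.weight = ag.Tensor(
            _init_conv(rng, (channels, kernel_size, kernel_size), kernel_size ** 2),
            requires_grad=True)

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"depthwise conv expects {self.channels} channels, input has {x.shape[1]}")
        if x.shape[2] + 2 * (self.kernel_size // 2) < self.kernel_size or \
           x.shape[3] + 2 * (self.kernel_size // 2) < self.kernel_size:
            raise DimensionError(
                f"kernel {self.kernel_size} larger than padded input {x.shape[2:]}")
        return ag.depthwise_conv2d(x, self.weight)

    def macs(self, h: int, w: int) -> int:
        return self.weight.data.size * h * w


class BatchNorm2d(Module):
    """Per-channel batch normalization with learnable scale and shift.

    Uses batch statistics in training mode and exponential running statistics
    in eval mode (momentum 0.1).
    """

    buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = ag.Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = ag.Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.training = True

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        shape = (1, self.channels, 1, 1)
        if self.training:
            out, mu, var = ag.batchnorm2d_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(shape)
        xhat = ag.mul(x - self.running_mean.reshape(shape), inv)
        return ag.add(ag.mul(xhat, ag.reshape(self.gamma, shape)),
                      ag.reshape(self.beta, shape))

    def macs(self, h: int, w: int) -> int:
        return 2 * self.channels * h * w


class Downsample2x2(Module):
    """Non-overlapping 2x2 max or average pooling (stride 2), no parameters."""

    def __init__(self, mode: str = "max"):
        if mode not in ("max", "average"):
            raise ConfigurationError(f"pooling mode must be max or average, got {mode!r}")
        self.mode = mode

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 2 or w % 2:
            raise DimensionError(
                f"2x2 downsampling needs even spatial size; got {h}x{w} "
                "(constrain network inputs to multiples of 16)")
        return ag.pool2x2(x, self.mode)

    def macs(self, h: int, w: int) -> int:
        # one op per input pixel per channel; channel count applied by caller
        return h * w


# bicubic resampling -------------------------------------------------------

def _cubic_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel (a = -0.5)."""
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t <= 1
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    m2 = (t > 1) & (t < 2)
    out[m2] = a * t[m2] ** 3 - 5 * a * t[m2] ** 2 + 8 * a * t[m2] - 4 * a
    return out


def bicubic_matrix(n: int) -> np.ndarray:
    """(2n x n) linear operator for 2x bicubic up-sampling along one axis.

    Output sample centers are half-pixel aligned: output index i reads input
    coordinate (i + 0.5)/2 - 0.5.  Edge taps clamp to the border sample, so
    constants are reproduced exactly (rows sum to 1).
    """
    if n < 2:
        raise DimensionError(f"bicubic up-sampling needs axis length >= 2, got {n}")
    op = np.zeros((2 * n, n))
    for i in range(2 * n):
        c = (i + 0.5) / 2.0 - 0.5
        base = int(np.floor(c))
        t = c - base
        taps = np.arange(base - 1, base + 3)
        weights = _cubic_kernel(t - (taps - base))
        weights /= weights.sum()
        for tap, wgt in zip(taps, weights):
            op[i, min(max(tap, 0), n - 1)] += wgt
    return op


class BicubicUpsample2x(Module):
    """Parameter-free 2x spatial up-sampling by separable bicubic interpolation."""

    _cache: dict[int, np.ndarray] = {}

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        h, w = x.shape[2], x.shape[3]
        if h < 2 or w < 2:
            raise DimensionError(f"cannot bicubic-upsample degenerate size {h}x{w}")
        row = self._operator(h).astype(x.data.dtype)
        col = self._operator(w).astype(x.data.dtype)
        return ag.linear_resample(x, row, col)

    @classmethod
    def _operator(cls, n: int) -> np.ndarray:
        if n not in cls._cache:
            cls._cache[n] = bicubic_matrix(n)
        return cls._cache[n]

    def macs(self, h: int, w: int) -> int:
        # separable 4-tap filter: 4 MACs per intermediate + 4 per output pixel
        return 4 * (2 * h) * w + 4 * (2 * h) * (2 * w)


class ReLU(Module):
    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        return ag.relu(x)

    def macs(self, h: int, w: int) -> int:
        return 0


# --------------------------------------------------------------------------
# functional wrappers on plain CHW arrays


def _chw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise DimensionError(f"expected a CHW feature map, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise DataError("feature map contains non-finite values")
    return x


def pointwise_conv(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Y(c_out, h, w) = sum_c_in W(c_out, c_in) * X(c_in, h, w)."""
    x = _chw(x)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape[1] != x.shape[0]:
        raise ConfigurationError(
            f"weight expects {weights.shape[1]} input channels, feature map has {x.shape[0]}")
    out = ag.pointwise_conv2d(ag.Tensor(x[None]), ag.Tensor(weights))
    return out.data[0]


def depthwise_conv(x: np.ndarray, kernels: np.ndarray,
                   padding: int | None = None) -> np.ndarray:
    """Per-channel correlation; kernels shaped (C, K, K); padding defaults to K//2."""
    x = _chw(x)
    kernels = np.asarray(kernels, dtype=np.float64)
    if kernels.shape[0] != x.shape[0]:
        raise ConfigurationError(
            f"{kernels.shape[0]} kernels for {x.shape[0]} channels")
    k = kernels.shape[1]
    p = k // 2 if padding is None else int(padding)
    if x.shape[1] + 2 * p < k or x.shape[2] + 2 * p < k:
        raise DimensionError(f"kernel {k} larger than padded input {x.shape[1:]}")
    return ag.depthwise_conv2d(ag.Tensor(x[None]), ag.Tensor(kernels), p).data[0]


def downsample_2x2(x: np.ndarray, mode: str = "max") -> np.ndarray:
    x = _chw(x)
    if x.shape[1] % 2 or x.shape[2] % 2:
        raise DimensionError(
            f"2x2 downsampling needs even spatial size; got {x.shape[1]}x{x.shape[2]}")
    return ag.pool2x2(ag.Tensor(x[None]), mode).data[0]


def bicubic_upsample_x2(x: np.ndarray) -> np.ndarray:
    x = _chw(x)
    if x.shape[1] < 2 or x.shape[2] < 2:
        raise DimensionError(f"cannot bicubic-upsample degenerate size {x.shape[1:]}")
    row = bicubic_matrix(x.shape[1])
    col = bicubic_matrix(x.shape[2])
    return ag.linear_resample(ag.Tensor(x[None]), row, col).data[0]


# --------------------------------------------------------------------------
# MAC estimation


def estimate_macs(model, input_height: int, input_width: int) -> ParamReport:
    """ParamReport with mac_count for a model exposing ``audit_macs(h, w)``.

    Input spatial size must be divisible by 16 (the network's own constraint).
    """
    if input_height % 16 or input_width % 16:
        raise DimensionError(
            f"input size {input_height}x{input_width} must be divisible by 16")
    report = count_parameters(model)
    report.mac_count = int(model.audit_macs(input_height, input_width))
    return report
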