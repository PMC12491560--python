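"""Joint training objective: weighted binary cross-entropy + soft-IoU.

    L_total = alpha * L_BCE + beta * L_IoU,     alpha = 0.25, beta = 0.75

L_BCE is the pixel-mean cross-entropy of the foreground probability
(probabilities clamped to [delta, 1-delta] inside the logs); L_IoU is one
minus the soft intersection-over-union with a small epsilon guarding the
divisor.  The two-channel classifier head bridges to the single sigmoid
probability via  p_fg = sigmoid(logit_fg - logit_bg), which is exactly the
two-class softmax foreground entry.

Every function has a NumPy form (for evaluation and tests) and a Tensor
form (suffix ``_t``) used inside the training graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .errors import DimensionError


@dataclass
class LossConfig:
    alpha_loss: float = 0.25
    beta_loss: float = 0.75
    epsilon: float = 1e-6
    clamp_delta: float = 1e-7

    def __post_init__(self):
        if self.alpha_loss < 0 or self.beta_loss < 0:
            raise ValueError("loss weights must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def foreground_probability(logits: np.ndarray) -> np.ndarray:
    """sigmoid(logit_fg - logit_bg) == two-class softmax foreground entry."""
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim != 3 or logits.shape[0] != 2:
        raise DimensionError(f"expected 2xHxW logits, got {logits.shape}")
    return 1.0 / (1.0 + np.exp(-(logits[1] - logits[0])))


def bce_loss(y_hat: np.ndarray, y: np.ndarray, delta: float = 1e-7) -> float:
    """Mean over pixels of -[y log(p) + (1-y) log(1-p)], p clamped to [delta, 1-delta]."""
    y_hat, y = np.asarray(y_hat, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape:
        raise DimensionError(f"shape mismatch {y_hat.shape} vs {y.shape}")
    p = np.clip(y_hat, delta, 1.0 - delta)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def iou_loss(y_hat: np.ndarray, y: np.ndarray, eps: float = 1e-6) -> float:
    """1 - sum(p*y) / (sum(p + y - p*y) + eps), sums over all pixels."""
    y_hat, y = np.asarray(y_hat, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape:
        raise DimensionError(f"shape mismatch {y_hat.shape} vs {y.shape}")
    inter = (y_hat * y).sum()
    union = (y_hat + y - y_hat * y).sum()
    return float(1.0 - inter / (union + eps))


def total_loss(y_hat: np.ndarray, y: np.ndarray, cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    return (cfg.alpha_loss * bce_loss(y_hat, y, cfg.clamp_delta)
            + cfg.beta_loss * iou_loss(y_hat, y, cfg.epsilon))


# -- Tensor (autodiff) forms ----------------------------------------------


def foreground_probability_t(logits: ag.Tensor) -> ag.Tensor:
    """Batched: (B,2,H,W) logits -> (B,1,H,W) foreground probability."""
    fg = ag.narrow_channels(logits, 1, 1)
    bg = ag.narrow_channels(logits, 0, 1)
    return ag.sigmoid(fg - bg)


def total_loss_t(y_hat: ag.Tensor, y: np.ndarray,
                 cfg: LossConfig | None = None) -> ag.Tensor:
    """Differentiable joint loss; `y` is a constant (B,1,H,W) binary array."""
    cfg = cfg or LossConfig()
    y = np.asarray(y, dtype=y_hat.data.dtype)
    if y.shape != y_hat.shape:
        raise DimensionError(f"shape mismatch {y_hat.shape} vs {y.shape}")
    d = cfg.clamp_delta
    p = ag.clip(y_hat, d, 1.0 - d)
    bce = ag.tmean(-(ag.mul(ag.log(p), y) + ag.mul(ag.log(1.0 - p), 1.0 - y)))
    inter = ag.tsum(ag.mul(y_hat, y))
    union = ag.tsum(y_hat + y - ag.mul(y_hat, y))
    iou = 1.0 - inter / (union + cfg.epsilon)
    return ag.mul(bce, cfg.alpha_loss) + ag.mul(iou, cfg.beta_loss)
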