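"""Dataset I/O, training loop, model selection, evaluation, visualization.

The training protocol: AdamW (decoupled weight decay 1e-5), cosine-annealed
learning rate, batch size 8, inputs resized to a square divisible by 16,
at most 200 epochs with early stopping after 20 epochs without validation
improvement, and the joint BCE + soft-IoU loss.  The printed default
initial learning rate of 1e-6 is kept for protocol fidelity; desk-scale
runs should override it (1e-3 is what the package's own sanity tests use).

Evaluation pools confusion counts over the whole set (micro-aggregation)
before computing metrics.
"""

from __future__ import annotations

import copy
import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from . import autograd as ag
from .errors import ConfigurationError, DataError, DimensionError
from .losses import LossConfig, foreground_probability_t, total_loss_t
from .metrics import ConfusionCounts, confusion, metric_report
from .model import LMSAUnet, predict_mask


@dataclass
class TrainConfig:
    lr_initial: float = 1e-6
    lr_min: float = 0.0
    weight_decay: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    warm_restarts: bool = False
    restart_period: int = 64
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 8
    input_size: int = 256
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ConfigurationError("patience must be smaller than max_epochs")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.input_size % 16:
            raise ConfigurationError("input_size must be divisible by 16")


@dataclass
class RunHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    val_metrics: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def to_rows(self):
        rows = []
        for i in range(len(self.train_loss)):
            m = self.val_metrics[i]
            rows.append({"epoch": i, "train_loss": self.train_loss[i],
                         "val_loss": self.val_loss[i], "lr": self.lr[i], **m})
        return rows

    def save(self, out_dir: str | Path):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = self.to_rows()
        if rows:
            with open(out_dir / "history.csv", "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
                writer.writeheader()
                writer.writerows(rows)
        (out_dir / "history.json").write_text(json.dumps(
            {"rows": rows, "best_epoch": self.best_epoch,
             "stopped_early": self.stopped_early}, indent=2))


# -- data loading ----------------------------------------------------------

def load_pairs(image_dir: str | Path, mask_dir: str | Path | None = None,
               input_size: int = 256):
    """Load (image, mask) pairs following the `<stem>_segmentation.png` convention.

    Images are resized bilinearly to input_size x input_size and scaled to
    [0,1]; masks are resized nearest-neighbor and mapped 255 -> 1.  Ordering
    is deterministic (sorted by filename).
    """
    image_dir = Path(image_dir)
    mask_dir = Path(mask_dir) if mask_dir is not None else image_dir
    images = sorted(p for p in image_dir.iterdir()
                    if p.suffix.lower() in (".png", ".jpg", ".jpeg")
                    and not p.stem.endswith("_segmentation"))
    if not images:
        raise DataError(f"no images found in {image_dir}")
    pairs = []
    for img_path in images:
        mask_path = mask_dir / f"{img_path.stem}_segmentation.png"
        if not mask_path.exists():
            raise DataError(f"missing mask partner for stem {img_path.stem!r}")
        img = Image.open(img_path).convert("RGB").resize(
            (input_size, input_size), Image.BILINEAR)
        arr = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
        mask_img = Image.open(mask_path).convert("L").resize(
            (input_size, input_size), Image.NEAREST)
        mask = np.asarray(mask_img)
        vals = np.unique(mask)
        if not np.isin(vals, (0, 255)).all():
            raise DataError(f"mask {mask_path.name} is not binary {{0,255}}: {vals[:8]}")
        pairs.append((arr, (mask > 0).astype(np.uint8)))
    return pairs


# -- schedule and optimizer ------------------------------------------------

def lr_at_epoch(t: int, cfg: TrainConfig) -> float:
    """Cosine annealing: eta_min + (eta0-eta_min)(1+cos(pi t'/T0))/2."""
    if not 0 <= t < cfg.max_epochs:
        raise ValueError(f"epoch {t} outside [0, {cfg.max_epochs})")
    if cfg.warm_restarts:
        t0 = cfg.restart_period
        tp = t % t0
    else:
        t0 = cfg.max_epochs
        tp = t
    return cfg.lr_min + 0.5 * (cfg.lr_initial - cfg.lr_min) * (
        1.0 + math.cos(math.pi * tp / t0))


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float, weight_decay: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)


# -- training --------------------------------------------------------------

def _batch_loss(network: LMSAUnet, images: np.ndarray, masks: np.ndarray,
                loss_cfg: LossConfig) -> ag.Tensor:
    logits = network(ag.Tensor(images))
    prob = foreground_probability_t(logits)
    return total_loss_t(prob, masks[:, None].astype(np.float32), loss_cfg)


def _epoch_val_loss(network: LMSAUnet, pairs, loss_cfg: LossConfig,
                    batch_size: int) -> float:
    """Mean per-batch validation loss in eval mode."""
    network.eval()
    losses = []
    with ag.no_grad():
        for lo in range(0, len(pairs), batch_size):
            chunk = pairs[lo:lo + batch_size]
            images = np.stack([p[0] for p in chunk]).astype(np.float32)
            masks = np.stack([p[1] for p in chunk])
            losses.append(float(_batch_loss(network, images, masks, loss_cfg).data))
    network.train()
    return float(np.mean(losses))


def train(network: LMSAUnet, train_pairs, val_pairs,
          cfg: TrainConfig | None = None, verbose: bool = False):
    """Optimize the joint loss; returns (best network, RunHistory).

    Early stopping: training ends once the validation loss has not improved
    for ``cfg.patience`` consecutive epochs; the parameters of the best
    validation epoch are restored.
    """
    cfg = cfg or TrainConfig()
    if not train_pairs or not val_pairs:
        raise DataError("training and validation splits must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(network.parameters(), lr=cfg.lr_initial,
                weight_decay=cfg.weight_decay, beta1=cfg.beta1,
                beta2=cfg.beta2, eps=cfg.adam_eps)
    history = RunHistory()
    best_loss, best_state, since_best = np.inf, None, 0
    n = len(train_pairs)
    for epoch in range(cfg.max_epochs):
        lr = lr_at_epoch(epoch, cfg)
        opt.lr = lr
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            images = np.stack([train_pairs[i][0] for i in idx]).astype(np.float32)
            masks = np.stack([train_pairs[i][1] for i in idx])
            loss = _batch_loss(network, images, masks, cfg.loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {lo // cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = _epoch_val_loss(network, val_pairs, cfg.loss, cfg.batch_size)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.lr.append(lr)
        history.val_metrics.append(evaluate(network, val_pairs))
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.2e}  train {history.train_loss[-1]:.4f}  "
                  f"val {val_loss:.4f}  dice {history.val_metrics[-1]['dice']:.4f}")
        if val_loss < best_loss:
            best_loss = val_loss
            history.best_epoch = epoch
            best_state = copy.deepcopy(network.state_dict())
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                history.stopped_early = True
                break
    if best_state is not None:
        network.load_state_dict(best_state)
    return network, history


def select_best(history: RunHistory, checkpoints: dict):
    """Parameters minimizing validation loss; ties break to the earliest epoch."""
    if not history.val_loss:
        raise DataError("empty run history")
    best = int(np.argmin(history.val_loss))   # argmin returns the first minimum
    return checkpoints[best]


# -- evaluation ------------------------------------------------------------

def evaluate(network: LMSAUnet, pairs) -> dict:
    """Micro-aggregated metrics: confusion counts pooled over the whole set."""
    if not pairs:
        raise DataError("cannot evaluate on an empty set")
    total = ConfusionCounts()
    was_training = network.training
    network.eval()
    try:
        with ag.no_grad():
            for img, mask in pairs:
                logits = network(ag.Tensor(np.asarray(img, dtype=np.float32)[None])).data[0]
                pred = predict_mask(logits)
                total = total + confusion(pred, mask)
    finally:
        network.train(was_training)
    return metric_report(total)


# -- visualization ---------------------------------------------------------

def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 4-adjacent to background."""
    m = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(
        m, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0)
    return m & ~eroded


def overlay_contours(image: np.ndarray, truth_mask: np.ndarray,
                     pred_mask: np.ndarray) -> np.ndarray:
    """Truth boundary in red, prediction boundary in blue, on a 3xHxW image."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape[1:] != np.asarray(truth_mask).shape or \
       image.shape[1:] != np.asarray(pred_mask).shape:
        raise DimensionError("image and masks must share spatial size")
    out = image.copy()
    tb = mask_boundary(truth_mask)
    pb = mask_boundary(pred_mask)
    out[:, tb] = np.array([1.0, 0.0, 0.0])[:, None]
    out[:, pb] = np.array([0.0, 0.0, 1.0])[:, None]
    return out
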