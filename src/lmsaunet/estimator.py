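"""scikit-learn-compatible estimator wrapping the segmentation pipeline.

`LesionSegmenter` follows the sklearn estimator contract — constructor
stores hyperparameters untouched, `fit` learns and sets trailing-underscore
attributes, `predict` maps images to binary masks, `score` returns the Dice
coefficient — so it composes with `sklearn.model_selection` utilities and
`clone`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DimensionError
from .losses import LossConfig
from .model import LMSAUnet, NetworkConfig, predict_mask
from .pipeline import TrainConfig, evaluate, train


class LesionSegmenter(BaseEstimator):
    """Lightweight attention U-Net for binary lesion segmentation.

    Parameters
    ----------
    preset : {"small", "paper"}
        Channel plan: "paper" is the full 64/128/256/512 plan, "small" a
        quarter-width desk-scale variant.
    compression_factor : int
        Power-of-two channel compression N inside each ECDF block.
    attention : bool
        Enable the spatial-channel attention gates.
    pooling : {"max", "average"}
    lr : float
        Initial learning rate of the cosine schedule.
    max_epochs, patience, batch_size : int
        Training protocol knobs.
    validation_fraction : float
        Tail fraction of the training set held out for early stopping.
    seed : int
        Seeds weight init, shuffling, and the split.

    Attributes
    ----------
    network_ : LMSAUnet
        The trained network (best validation-loss parameters).
    history_ : RunHistory
        Per-epoch losses, learning rates and validation metrics.
    n_features_in_ : int
        Number of channels of the training images (always 3).
    """

    def __init__(self, preset: str = "small", compression_factor: int = 8,
                 attention: bool = True, pooling: str = "max", lr: float = 1e-3,
                 max_epochs: int = 30, patience: int = 10, batch_size: int = 8,
                 validation_fraction: float = 0.2, seed: int = 0):
        self.preset = preset
        self.compression_factor = compression_factor
        self.attention = attention
        self.pooling = pooling
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _network_config(self) -> NetworkConfig:
        kwargs = dict(compression_factor=self.compression_factor,
                      attention_enabled=self.attention, pooling=self.pooling,
                      seed=self.seed)
        if self.preset == "paper":
            return NetworkConfig(**kwargs)
        if self.preset == "small":
            return NetworkConfig.small(**kwargs)
        raise ValueError(f"unknown preset {self.preset!r}")

    @staticmethod
    def _check_images(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1] != 3:
            raise DimensionError(f"X must be (n_samples, 3, H, W), got {X.shape}")
        if X.shape[2] % 16 or X.shape[3] % 16:
            raise DimensionError(f"spatial size {X.shape[2:]} must be divisible by 16")
        return X

    def fit(self, X, y):
        """Fit on images X (n,3,H,W) in [0,1] and binary masks y (n,H,W)."""
        X = self._check_images(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0],) + X.shape[2:]:
            raise DimensionError(f"y must be (n_samples, H, W) matching X, got {y.shape}")
        pairs = [(X[i], y[i].astype(np.uint8)) for i in range(len(X))]
        n_val = max(1, int(round(self.validation_fraction * len(pairs))))
        if len(pairs) == 1:
            train_pairs = val_pairs = pairs
        else:
            train_pairs, val_pairs = pairs[:-n_val], pairs[-n_val:]
        cfg = TrainConfig(lr_initial=self.lr, max_epochs=self.max_epochs,
                          patience=min(self.patience, self.max_epochs - 1),
                          batch_size=self.batch_size, input_size=X.shape[2],
                          loss=LossConfig(), seed=self.seed)
        self.network_ = LMSAUnet(self._network_config())
        self.network_, self.history_ = train(self.network_, train_pairs, val_pairs, cfg)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Binary masks (n, H, W) for images X."""
        if not hasattr(self, "network_"):
            raise RuntimeError("this LesionSegmenter instance is not fitted yet")
        X = self._check_images(X)
        return np.stack([predict_mask(self.network_.forward_numpy(x)) for x in X])

    def predict_proba(self, X) -> np.ndarray:
        """Foreground probability maps (n, H, W)."""
        from .losses import foreground_probability

        if not hasattr(self, "network_"):
            raise RuntimeError("this LesionSegmenter instance is not fitted yet")
        X = self._check_images(X)
        return np.stack([foreground_probability(self.network_.forward_numpy(x))
                         for x in X])

    def score(self, X, y) -> float:
        """Micro-aggregated Dice coefficient over (X, y)."""
        X = self._check_images(X)
        y = np.asarray(y)
        pairs = [(X[i], y[i].astype(np.uint8)) for i in range(len(X))]
        return evaluate(self.network_, pairs)["dice"]
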