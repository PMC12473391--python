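"""Scikit-learn estimators wrapping the parallel bimodal networks.

``PMMCTClassifier`` is the main model; ``ParallelCNNClassifier``,
``CNNLSTMClassifier`` and ``CNNLSTMAttentionClassifier`` are the baseline
architectures.  All accept ``X`` of shape ``(n, 2, win)`` — modality 1
(HEOG) first, modality 2 (HSUM or O2) second — or the flattened
``(n, 2*win)`` equivalent, and binary labels with SEM as the positive
class.  They compose with sklearn model selection and pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .architectures import ModelConfig, build_model
from .training import TrainConfig, fit

__all__ = [
    "PMMCTClassifier",
    "ParallelCNNClassifier",
    "CNNLSTMClassifier",
    "CNNLSTMAttentionClassifier",
]


class _ParallelNetClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for every architecture variant."""

    _variant = "pmmct"

    def __init__(
        self,
        kernel_sizes=(50, 50, 50, 50),
        d_model=64,
        n_heads=2,
        n_encoder_layers=2,
        d_ff=128,
        pool_sizes=(1, 4),
        lstm_units=100,
        fc_units=64,
        dropout=0.5,
        ablation=None,
        learning_rate=5e-4,
        batch_size=128,
        max_epochs=100,
        early_stop_patience=10,
        lr_patience=3,
        lr_reduce_factor=0.2,
        min_lr=1e-6,
        validation_fraction=0.1,
        random_state=0,
    ):
        self.kernel_sizes = kernel_sizes
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_encoder_layers = n_encoder_layers
        self.d_ff = d_ff
        self.pool_sizes = pool_sizes
        self.lstm_units = lstm_units
        self.fc_units = fc_units
        self.dropout = dropout
        self.ablation = ablation
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.lr_patience = lr_patience
        self.lr_reduce_factor = lr_reduce_factor
        self.min_lr = min_lr
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _coerce_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            if X.shape[1] % 2 != 0:
                raise ValueError(
                    "flattened input must have an even number of columns "
                    "(two stacked modalities)"
                )
            X = X.reshape(len(X), 2, X.shape[1] // 2)
        if X.ndim != 3 or X.shape[1] != 2:
            raise ValueError(f"X must have shape (n, 2, win), got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains NaN/Inf")
        return X

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            variant=self._variant,
            kernel_sizes=tuple(self.kernel_sizes),
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_encoder_layers=self.n_encoder_layers,
            d_ff=self.d_ff,
            pool_sizes=tuple(self.pool_sizes),
            lstm_units=self.lstm_units,
            fc_units=self.fc_units,
            dropout=self.dropout,
            ablation=self.ablation,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            initial_lr=self.learning_rate,
            lr_reduce_factor=self.lr_reduce_factor,
            lr_patience=self.lr_patience,
            min_lr=self.min_lr,
            batch_size=self.batch_size,
            early_stop_patience=self.early_stop_patience,
            max_epochs=self.max_epochs,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
        )

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y):
        X = self._coerce_X(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(f"expected a binary problem, got classes {self.classes_}")
        self.network_ = build_model(
            self.model_config(), np.random.default_rng(self.random_state)
        )
        self.history_ = fit(self.network_, X, y_idx, self.train_config())
        self.n_features_in_ = X.shape[1] * X.shape[2]
        self.window_len_ = X.shape[2]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = self._coerce_X(X)
        if X.shape[2] != self.window_len_:
            raise ValueError(
                f"window length {X.shape[2]} differs from fitted {self.window_len_}"
            )
        return self.network_.predict_proba(X[:, 0], X[:, 1])

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.three_d_array = True
        return tags


class PMMCTClassifier(_ParallelNetClassifier):
    """Parallel multimodal CNN-Transformer SEM detector.

    Per branch: conv-BN-ReLU x2 with max pooling, sinusoidal positional
    encoding, N post-norm Transformer encoder layers (h-head self
    attention + position-wise FFN with residual Add&Norm), and global
    average pooling; branch features are concatenated and classified by a
    dropout-regularized two-layer head trained with inverse-frequency
    weighted cross-entropy.  ``ablation`` removes one component
    ('no_transformer', 'no_cnn', 'no_residual', 'no_ffn').
    """

    _variant = "pmmct"


class ParallelCNNClassifier(_ParallelNetClassifier):
    """Baseline: conv module + global average pooling per branch."""

    _variant = "cnn"


class CNNLSTMClassifier(_ParallelNetClassifier):
    """Baseline: conv module + LSTM + global average pooling per branch."""

    _variant = "cnn_lstm"


class CNNLSTMAttentionClassifier(_ParallelNetClassifier):
    """Baseline: conv module + LSTM + additive attention pooling."""

    _variant = "cnn_lstm_attn"
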