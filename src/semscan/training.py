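"""Weighted loss, class-weight rule, optimization schedule, and grid search.

The schedule: Adam (beta1 0.9, beta2 0.999) at an initial learning rate of
5e-4, reduced by a factor of 0.2 when validation loss stagnates for 3
epochs (floored at 1e-6), minibatch 128, early stopping when validation
accuracy stagnates for 10 epochs, with best-validation-accuracy weights
restored.  Class imbalance is handled by inverse-frequency class weights
w_i = N / (c * N_i) computed on the training split only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architectures import ModelConfig, ParallelNet, build_model

__all__ = [
    "TrainConfig",
    "class_weights",
    "weighted_cross_entropy",
    "Adam",
    "fit",
    "enumerate_combinations",
    "grid_search",
]


def enumerate_combinations(variant, kernel_grid=(50, 150, 250), lstm_grid=(50, 100, 150)):
    """All hyperparameter combinations the grid search evaluates: kernel
    four-tuples, extended by the LSTM unit count for LSTM variants."""
    if not kernel_grid:
        raise ValueError("kernel grid must not be empty")
    has_lstm = variant in ("cnn_lstm", "cnn_lstm_attn")
    return sorted(
        tuple(k) + ((u,) if has_lstm else ())
        for k in itertools.product(kernel_grid, repeat=4)
        for u in (lstm_grid if has_lstm else (None,))
    )


@dataclass
class TrainConfig:
    """Optimization schedule parameters."""

    initial_lr: float = 5e-4
    beta1: float = 0.9
    beta2: float = 0.999
    lr_reduce_factor: float = 0.2
    lr_patience: int = 3
    min_lr: float = 1e-6
    batch_size: int = 128
    early_stop_patience: int = 10
    max_epochs: int = 100
    validation_fraction: float = 0.1
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_reduce_factor < 1):
            raise ValueError("lr_reduce_factor must be in (0, 1)")
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")


def class_weights(class_counts) -> np.ndarray:
    """Inverse-frequency weights w_i = N / (c * N_i).

    Balanced counts give unit weights, and the frequency-weighted mean of
    the weights is exactly 1 for any positive counts.
    """
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError(f"all class counts must be positive, got {class_counts}")
    return counts.sum() / (len(counts) * counts)


def weighted_cross_entropy(y_onehot, y_hat, weights) -> float:
    """Mean over the batch of ``-w_class * log(p_class)`` with the log
    argument clamped at 1e-12."""
    y_onehot = np.atleast_2d(np.asarray(y_onehot, dtype=float))
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    weights = np.asarray(weights, dtype=float)
    sums = y_hat.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-3):
        raise ValueError("predictions must be probability vectors (rows summing to 1)")
    p_true = np.clip((y_hat * y_onehot).sum(axis=1), 1e-12, None)
    w = y_onehot @ weights
    return float(np.mean(-w * np.log(p_true)))


class Adam:
    """Adam with per-tensor moment estimates."""

    def __init__(self, net: ParallelNet, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, _, p in net.parameters()]
        self.v = [np.zeros_like(p) for _, _, p in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for k, (layer, name, p) in enumerate(self.net.parameters()):
            g = layer.grads[name]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / corr1
            vhat = self.v[k] / corr2
            layer.params[name] = (
                p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(p.dtype)


def _softmax_rows(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _evaluate(net, x1, x2, y, weights, batch_size=256):
    probs = net.predict_proba(x1, x2, batch_size)
    onehot = np.eye(2)[y]
    loss = weighted_cross_entropy(onehot, probs, weights)
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def fit(
    net: ParallelNet,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> dict:
    """Train a network in place; returns the per-epoch history.

    ``X`` has shape (n, 2, win).  If no validation set is given, the last
    ``validation_fraction`` of the (chronologically ordered) training data
    is held out.  The training split must contain both classes.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if X_val is None:
        n_val = max(int(round(config.validation_fraction * len(X))), 1)
        X, X_val = X[:-n_val], X[-n_val:]
        y, y_val = y[:-n_val], y[-n_val:]
    counts = np.bincount(y, minlength=2)
    if np.any(counts == 0):
        raise ValueError("training split must contain both classes")
    weights = class_weights(counts)

    rng = np.random.default_rng(config.seed)
    opt = Adam(net, config.initial_lr, config.beta1, config.beta2)
    history = {k: [] for k in ("loss", "accuracy", "val_loss", "val_accuracy", "lr")}
    best_acc, best_weights, best_epoch = -np.inf, None, -1
    stale_acc, stale_loss, best_val_loss = 0, 0, np.inf

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X)) if config.shuffle else np.arange(len(X))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb1, xb2, yb = X[idx, 0], X[idx, 1], y[idx]
            logits = net.forward(xb1, xb2, training=True)
            probs = _softmax_rows(logits)
            onehot = np.eye(2, dtype=np.float32)[yb]
            w = weights[yb][:, None].astype(np.float32)
            batch_loss = float(
                np.mean(-w[:, 0] * np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)))
            )
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            dlogits = (w * (probs - onehot) / len(yb)).astype(np.float32)
            net.backward(dlogits)
            opt.step()
            ep_loss += batch_loss * len(yb)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())

        val_loss, val_acc = _evaluate(net, X_val[:, 0], X_val[:, 1], y_val, weights)
        history["loss"].append(ep_loss / len(X))
        history["accuracy"].append(ep_correct / len(X))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        history["lr"].append(opt.lr)

        if val_acc > best_acc:
            best_acc, best_weights, best_epoch = val_acc, net.get_weights(), epoch
            stale_acc = 0
        else:
            stale_acc += 1
        if val_loss < best_val_loss - 1e-12:
            best_val_loss, stale_loss = val_loss, 0
        else:
            stale_loss += 1
            if stale_loss >= config.lr_patience:
                opt.lr = max(opt.lr * config.lr_reduce_factor, config.min_lr)
                stale_loss = 0
        if stale_acc >= config.early_stop_patience:
            break

    if best_weights is not None:
        net.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_accuracy"] = best_acc
    return history


def grid_search(
    model_config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    folds,
    train_config: TrainConfig = TrainConfig(),
    kernel_grid=(50, 150, 250),
    lstm_grid=(50, 100, 150),
    seed: int = 0,
):
    """Exhaustive kernel-size (and LSTM-unit) search with k-fold CV.

    Every kernel four-tuple from ``kernel_grid`` (times every LSTM size
    for LSTM variants) is scored by mean validation accuracy over the
    folds: each contiguous fold serves once as the validation set, the
    remaining folds as training data.  Ties break toward the
    lexicographically smallest combination.  Returns ``(best_config,
    table)`` where the table lists mean and SD of accuracy per combination.
    """
    has_lstm = model_config.variant in ("cnn_lstm", "cnn_lstm_attn")
    combos = enumerate_combinations(model_config.variant, kernel_grid, lstm_grid)
    rows = []
    best = None
    for combo in combos:
        kernels = combo[:4]
        cfg = ModelConfig(
            **{
                **model_config.to_dict(),
                "kernel_sizes": kernels,
                **({"lstm_units": combo[4]} if has_lstm else {}),
            }
        )
        accs = []
        for i, val_fold in enumerate(folds):
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
            net = build_model(cfg, np.random.default_rng(seed))
            hist = fit(
                net,
                X[train_idx],
                y[train_idx],
                train_config,
                X_val=X[val_fold],
                y_val=y[val_fold],
            )
            accs.append(hist["best_val_accuracy"])
        mean, sd = float(np.mean(accs)), float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
        rows.append({"combination": combo, "mean_accuracy": mean, "sd_accuracy": sd})
        if best is None or mean > best[0]:
            best = (mean, combo, cfg)
    table = pd.DataFrame(rows)
    return best[2], table
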