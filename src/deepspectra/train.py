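"""Training loop: Adam on MSE with minimum-validation-loss weight selection.

The protocol: learning rate 0.005, batch size 16, exactly ``max_epochs``
epochs (default 100, no early stopping), Adam with conventional defaults,
and the weight snapshot kept is the one at the epoch where the
validation-set MSE was minimal (earliest epoch on ties).  Validation loss
is evaluated once per epoch in evaluation mode (batch-norm running
statistics) over the full validation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import DeepSpectraNet
from .exceptions import DataError, DivergenceError
from . import nn


@dataclass
class TrainConfig:
    learning_rate: float = 0.005
    batch_size: int = 16
    max_epochs: int = 100
    seed: int = 0
    shuffle: bool = True
    #: after restoring the best weights, re-estimate every batch-norm layer's
    #: running statistics with one full pass over the calibration set
    #: ("precise BN"): the mini-batch EMA tracks a moving training
    #: trajectory and is a noisy estimate of the population statistics the
    #: selected weights should be evaluated with
    recalibrate_batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise DataError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise DataError("max_epochs must be >= 1")


@dataclass
class TrainResult:
    """Per-epoch loss curves plus the best weight snapshot."""

    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int  # 1-based
    best_state: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def best_val_loss(self) -> float:
        return self.val_losses[self.best_epoch - 1]


def _batches(n: int, batch_size: int, order: np.ndarray):
    """Batch index lists; a trailing single-sample batch is merged with the
    previous one because batch normalization needs >= 2 samples per batch."""
    bounds = list(range(0, n, batch_size))
    slices = [order[b : b + batch_size] for b in bounds]
    if len(slices) > 1 and len(slices[-1]) == 1:
        slices[-2] = np.concatenate([slices[-2], slices[-1]])
        slices.pop()
    return slices


def _as_xy(X: np.ndarray, y: np.ndarray, input_length: int, dtype) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=dtype)
    y = np.asarray(y, dtype=dtype).reshape(-1, 1)
    if X.ndim != 2:
        raise DataError("spectra must be a 2-D (samples, wavelengths) array")
    if X.shape[1] != input_length:
        raise DataError(
            f"spectra length {X.shape[1]} does not match network input length {input_length}"
        )
    if X.shape[0] != y.shape[0]:
        raise DataError(f"{X.shape[0]} spectra vs {y.shape[0]} targets")
    return X, y


def mse(predicted: np.ndarray, actual: np.ndarray) -> float:
    return float(np.mean((np.asarray(predicted, float) - np.asarray(actual, float)) ** 2))


def train(
    model: DeepSpectraNet,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Run exactly ``max_epochs`` epochs and keep the min-validation-loss weights."""
    input_length = model.spec.input_length
    X_cal, y_cal = _as_xy(X_cal, y_cal, input_length, model.dtype)
    X_val, y_val = _as_xy(X_val, y_val, input_length, model.dtype)
    n = X_cal.shape[0]
    if n == 0:
        raise DataError("empty calibration set")

    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    train_losses: list[float] = []
    val_losses: list[float] = []
    best_epoch = 0
    best_val = np.inf
    best_state: dict[str, np.ndarray] = {}

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        sq_sum = 0.0
        for idx in _batches(n, config.batch_size, order):
            xb, yb = X_cal[idx], y_cal[idx]
            pred = model.forward(xb, training=True)
            resid = pred - yb
            loss = float(np.mean(resid.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            sq_sum += loss * len(idx)
            model.backward(2.0 * resid / len(idx))
            optimizer.step(model.gradients())
        train_losses.append(sq_sum / n)

        val_pred = model.forward(X_val, training=False)
        val_loss = mse(val_pred, y_val)
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        val_losses.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    if config.recalibrate_batchnorm:
        recalibrate_batchnorm(model, X_cal)
    return TrainResult(train_losses, val_losses, best_epoch, best_state)


def recalibrate_batchnorm(model: DeepSpectraNet, X: np.ndarray) -> None:
    """Set every batch-norm layer's running statistics to the population
    statistics of ``X`` (one full-batch forward pass, momentum 1)."""
    bn_layers = [
        layer
        for _, layer in model._stateful_layers()
        if isinstance(layer, nn.BatchNorm)
    ]
    saved = [layer.momentum for layer in bn_layers]
    for layer in bn_layers:
        layer.momentum = 1.0
    model.forward(np.asarray(X, dtype=model.dtype), training=True)
    for layer, m in zip(bn_layers, saved):
        layer.momentum = m


def predict(
    model: DeepSpectraNet,
    X: np.ndarray,
    batch_size: int | None = None,
) -> np.ndarray:
    """Evaluation-mode predictions; invariant to how the input is batched."""
    X = np.asarray(X, dtype=model.dtype)
    if X.size == 0:
        return np.empty(0)
    if X.ndim != 2 or X.shape[1] != model.spec.input_length:
        raise DataError(
            f"spectra shape {X.shape} does not match network input length "
            f"{model.spec.input_length}"
        )
    if batch_size is None:
        batch_size = X.shape[0]
    out = []
    for start in range(0, X.shape[0], batch_size):
        out.append(model.forward(X[start : start + batch_size], training=False)[:, 0])
    return np.concatenate(out).astype(float)
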