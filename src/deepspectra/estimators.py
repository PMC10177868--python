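"""Scikit-learn-style estimators for the spectral regression models.

`DeepSpectraRegressor` wraps the 1-D CNN and its training protocol;
`PLSRegressorBaseline` and `RBFSVRBaseline` are the conventional
chemometric comparison models with validation-set-driven model selection.
All three accept an explicit validation set through ``fit(X, y, X_val,
y_val)`` so model selection (epoch, latent variables, grid point) uses the
same held-out samples; when no validation set is given the calibration set
is reused.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVR
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .architecture import DEFAULT_MULTI_CHANNELS, NetworkSpec, build_network
from .exceptions import DataError
from .train import TrainConfig, predict as _net_predict, train as _net_train


def _validation_pair(X, y, X_val, y_val):
    if (X_val is None) != (y_val is None):
        raise DataError("provide both X_val and y_val, or neither")
    if X_val is None:
        return X, y
    X_val, y_val = check_X_y(X_val, y_val, dtype=float, y_numeric=True)
    return X_val, y_val


class DeepSpectraRegressor(RegressorMixin, BaseEstimator):
    """1-D CNN regressor for preprocessed spectra.

    Parameters
    ----------
    mode : {'multi', 'single'}
        Three parallel convolution channels fused by length-axis
        concatenation, or a single channel.
    channels : sequence of (k1, k2), optional
        Kernel sizes of the two convolution layers per channel.  Defaults
        to ((7,5), (7,3), (5,3)) in multi mode and ((5,3),) in single mode.
    kernels_per_conv : int, optional
        Kernels per convolution layer; defaults to 16 (multi) / 32 (single).
    learning_rate, batch_size, max_epochs, shuffle :
        Training protocol (Adam on MSE, min-validation-loss weight
        selection; no early stopping).
    input_scaling : {'global', 'per_wavelength', None}
        Standardization of the input spectra, fitted on the calibration
        set.  ``'global'`` (default) centers each wavelength and divides by
        one pooled standard deviation, preserving the relative magnitude of
        spectral features; ``'per_wavelength'`` is a full z-score; ``None``
        feeds raw values.  Derivative spectra are ~1e-3 in magnitude, which
        leaves batch-norm feature variances orders of magnitude below the
        optimizer's per-step parameter drift, so the evaluation-mode
        running statistics can never track training — scaling to O(1) is
        required for the network to evaluate at all.
    random_state : int
        Seeds both parameter initialization and batch shuffling.

    Attributes
    ----------
    network_ : DeepSpectraNet
        The trained network, holding the best-validation-loss weights.
    best_epoch_ : int
        1-based epoch whose validation loss was minimal.
    loss_curve_, validation_loss_curve_ : list of float
        Per-epoch calibration and validation MSE (µg/g squared).
    """

    def __init__(
        self,
        mode: str = "multi",
        channels=None,
        kernels_per_conv: int | None = None,
        fc_units: int = 16,
        learning_rate: float = 0.005,
        batch_size: int = 16,
        max_epochs: int = 100,
        shuffle: bool = True,
        input_scaling: str | None = "global",
        random_state: int = 0,
    ) -> None:
        self.mode = mode
        self.channels = channels
        self.kernels_per_conv = kernels_per_conv
        self.fc_units = fc_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.shuffle = shuffle
        self.input_scaling = input_scaling
        self.random_state = random_state

    def _fit_scaler(self, X: np.ndarray) -> None:
        if self.input_scaling is None:
            self.input_mean_ = np.zeros(X.shape[1])
            self.input_scale_ = 1.0
        elif self.input_scaling == "global":
            self.input_mean_ = X.mean(axis=0)
            sd = float((X - self.input_mean_).std())
            self.input_scale_ = sd if sd > 0 else 1.0
        elif self.input_scaling == "per_wavelength":
            self.input_mean_ = X.mean(axis=0)
            sd = (X - self.input_mean_).std(axis=0)
            self.input_scale_ = np.where(sd > 0, sd, 1.0)
        else:
            raise DataError(f"unknown input_scaling {self.input_scaling!r}")

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.input_mean_) / self.input_scale_

    def _spec(self, input_length: int) -> NetworkSpec:
        if self.channels is not None:
            channels = tuple(tuple(pair) for pair in self.channels)
        elif self.mode == "single":
            channels = ((5, 3),)
        else:
            channels = DEFAULT_MULTI_CHANNELS
        return NetworkSpec(
            mode=self.mode,
            channels=channels,
            kernels_per_conv=self.kernels_per_conv,
            fc_units=self.fc_units,
            input_length=input_length,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = check_X_y(X, y, dtype=float, y_numeric=True)
        X_val, y_val = _validation_pair(X, y, X_val, y_val)
        self.n_features_in_ = X.shape[1]
        self._fit_scaler(X)
        spec = self._spec(X.shape[1])
        self.network_ = build_network(spec, seed=self.random_state)
        config = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            seed=self.random_state,
            shuffle=self.shuffle,
        )
        result = _net_train(
            self.network_, self._scale(X), y, self._scale(X_val), y_val, config
        )
        self.train_result_ = result
        self.best_epoch_ = result.best_epoch
        self.loss_curve_ = result.train_losses
        self.validation_loss_curve_ = result.val_losses
        return self

    def predict(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[0] == 0:
            return np.empty(0)
        return _net_predict(self.network_, self._scale(X))


class PLSRegressorBaseline(RegressorMixin, BaseEstimator):
    """Partial least squares regression with latent-variable selection.

    Components are extracted on mean-centered data (no scaling, NIPALS-style
    sequential deflation); the number of latent variables is chosen to
    minimize the validation-set RMSE over ``1..max_lv``, earliest on ties.

    Attributes
    ----------
    selected_lv_ : int
        Chosen number of latent variables.
    val_rmse_curve_ : ndarray
        Validation RMSE for each candidate LV count.
    """

    def __init__(self, max_lv: int = 20) -> None:
        self.max_lv = max_lv

    def fit(self, X, y, X_val=None, y_val=None):
        if self.max_lv < 1:
            raise DataError("max_lv must be >= 1")
        X, y = check_X_y(X, y, dtype=float, y_numeric=True)
        X_val, y_val = _validation_pair(X, y, X_val, y_val)
        self.n_features_in_ = X.shape[1]
        limit = min(self.max_lv, X.shape[0] - 1, X.shape[1])
        if limit < self.max_lv:
            warnings.warn(
                f"max_lv={self.max_lv} exceeds the data rank bound; truncated to {limit}",
                stacklevel=2,
            )
        models = []
        val_rmse = []
        for k in range(1, limit + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # y-residual-constant chatter near full rank
                pls = PLSRegression(n_components=k, scale=False).fit(X, y)
            resid = pls.predict(X_val).ravel() - y_val
            models.append(pls)
            val_rmse.append(float(np.sqrt(np.mean(resid**2))))
        best = int(np.argmin(val_rmse))
        self.val_rmse_curve_ = np.array(val_rmse)
        self.selected_lv_ = best + 1
        self.model_ = models[best]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"spectra have {X.shape[1]} wavelengths, model expects {self.n_features_in_}"
            )
        return self.model_.predict(X).ravel()


class RBFSVRBaseline(RegressorMixin, BaseEstimator):
    """Epsilon-insensitive SVR with an RBF kernel and validation grid search.

    The penalty ``c`` and kernel width ``g`` are selected over log2-spaced
    grids (defaults 2^-8 … 2^8) by minimum validation RMSE; ties prefer the
    smaller ``c``, then the smaller ``g``.
    """

    def __init__(self, grid_c=None, grid_g=None, epsilon: float = 0.1) -> None:
        self.grid_c = grid_c
        self.grid_g = grid_g
        self.epsilon = epsilon

    @staticmethod
    def default_grid() -> np.ndarray:
        return 2.0 ** np.arange(-8, 9)

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = check_X_y(X, y, dtype=float, y_numeric=True)
        X_val, y_val = _validation_pair(X, y, X_val, y_val)
        grid_c = np.sort(np.asarray(self.grid_c if self.grid_c is not None else self.default_grid(), float))
        grid_g = np.sort(np.asarray(self.grid_g if self.grid_g is not None else self.default_grid(), float))
        if grid_c.size == 0 or grid_g.size == 0:
            raise DataError("empty hyperparameter grid")
        self.n_features_in_ = X.shape[1]
        best = None
        failures = 0
        for c in grid_c:
            for g in grid_g:
                try:
                    model = SVR(kernel="rbf", C=c, gamma=g, epsilon=self.epsilon).fit(X, y)
                except Exception as exc:  # solver failure at one grid point
                    warnings.warn(f"SVR failed at c={c}, g={g}: {exc}", stacklevel=2)
                    failures += 1
                    continue
                resid = model.predict(X_val) - y_val
                score = float(np.sqrt(np.mean(resid**2)))
                if best is None or score < best[0]:  # strict: earliest (c, g) wins ties
                    best = (score, c, g, model)
        if best is None:
            raise DataError(f"SVR failed at all {failures} grid points")
        self.val_rmse_, self.c_, self.g_, self.model_ = best
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"spectra have {X.shape[1]} wavelengths, model expects {self.n_features_in_}"
            )
        return self.model_.predict(X)
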