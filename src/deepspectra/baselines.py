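"""Functional wrappers over the conventional chemometric baseline estimators."""

from __future__ import annotations

import numpy as np

from .estimators import PLSRegressorBaseline, RBFSVRBaseline


def fit_plsr(cal, val, max_lv: int = 20) -> PLSRegressorBaseline:
    """Fit PLSR on the calibration pair, selecting LVs by validation RMSE.

    ``cal`` and ``val`` are (X, y) tuples of preprocessed spectra and
    contents.
    """
    (X, y), (Xv, yv) = cal, val
    return PLSRegressorBaseline(max_lv=max_lv).fit(X, y, Xv, yv)


def fit_svr(cal, val, grid_c=None, grid_g=None, epsilon: float = 0.1) -> RBFSVRBaseline:
    """Fit RBF-SVR with a validation-RMSE grid search over (c, g)."""
    (X, y), (Xv, yv) = cal, val
    return RBFSVRBaseline(grid_c=grid_c, grid_g=grid_g, epsilon=epsilon).fit(X, y, Xv, yv)


def predict_baseline(model, X) -> np.ndarray:
    """Predict contents with a fitted baseline model."""
    return model.predict(X)
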