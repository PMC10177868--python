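"""Figures of merit for spectral calibration models.

R² (coefficient of determination about the mean of the reference values),
RMSE, and the residual predictive deviation RPD = (1 − Rp²)^(−1/2) computed
from the prediction-set R².  RPD is read against the conventional bands:
below 1.5 no predictive value, 1.5–2.0 initiatory, 2.0–2.5 admissible,
2.5–3.0 suitable, above 3.0 sufficient for application (left-closed,
right-open intervals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import MetricUndefinedError

RPD_BANDS = ("below", "initiatory", "admissible", "suitable", "sufficient")


@dataclass
class PredictionPairs:
    """Aligned actual/predicted contents (µg/g) for one sample set."""

    actual: np.ndarray
    predicted: np.ndarray
    set_label: str = "prediction"

    def __post_init__(self) -> None:
        self.actual = np.asarray(self.actual, dtype=float).ravel()
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        if self.actual.size != self.predicted.size:
            raise MetricUndefinedError("actual and predicted lengths differ")
        if not (np.all(np.isfinite(self.actual)) and np.all(np.isfinite(self.predicted))):
            raise MetricUndefinedError("non-finite values in prediction pairs")


def r_squared(pairs: PredictionPairs) -> float:
    """1 − SSE/SST with SST about the mean of the reference values.

    Can be negative for a model worse than the mean predictor; undefined
    (raises) when all reference values are equal.
    """
    if pairs.actual.size < 2:
        raise MetricUndefinedError("R^2 needs at least two samples")
    sst = float(np.sum((pairs.actual - pairs.actual.mean()) ** 2))
    if sst == 0.0:
        raise MetricUndefinedError("R^2 undefined: reference values are all equal")
    sse = float(np.sum((pairs.actual - pairs.predicted) ** 2))
    return 1.0 - sse / sst


def rmse(pairs: PredictionPairs) -> float:
    """Root mean squared residual, in µg/g."""
    if pairs.actual.size == 0:
        raise MetricUndefinedError("RMSE needs at least one sample")
    return float(np.sqrt(np.mean((pairs.actual - pairs.predicted) ** 2)))


def rpd(rp2: float) -> float:
    """Residual predictive deviation from the prediction-set R²."""
    if rp2 >= 1.0:
        raise MetricUndefinedError(f"RPD undefined for Rp^2 = {rp2} (>= 1)")
    return (1.0 - rp2) ** -0.5


def classify_rpd(rpd_value: float) -> str:
    """Interpretation band of an RPD value (left-closed, right-open)."""
    if rpd_value < 0:
        raise MetricUndefinedError(f"negative RPD {rpd_value}")
    if rpd_value < 1.5:
        return "below"
    if rpd_value < 2.0:
        return "initiatory"
    if rpd_value < 2.5:
        return "admissible"
    if rpd_value < 3.0:
        return "suitable"
    return "sufficient"


@dataclass
class MetricsReport:
    """One row of the standard calibration/validation/prediction summary."""

    rc2: float
    rmsec: float
    rv2: float
    rmsev: float
    rp2: float
    rmsep: float
    rpd: float
    rpd_band: str

    def rounded(self, ndigits: int = 3) -> "MetricsReport":
        """Reporting convention: three decimals on every metric."""
        r = lambda v: round(v, ndigits) if math.isfinite(v) else v
        return MetricsReport(
            r(self.rc2), r(self.rmsec), r(self.rv2), r(self.rmsev),
            r(self.rp2), r(self.rmsep), r(self.rpd), self.rpd_band,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Rc2": self.rc2,
                    "RMSEC": self.rmsec,
                    "Rv2": self.rv2,
                    "RMSEV": self.rmsev,
                    "Rp2": self.rp2,
                    "RMSEP": self.rmsep,
                    "RPD": self.rpd,
                    "RPD_band": self.rpd_band,
                }
            ]
        )


def assemble_report(
    cal: PredictionPairs, val: PredictionPairs, pred: PredictionPairs
) -> MetricsReport:
    """Compute all seven metrics; a perfect prediction set (Rp² = 1) is
    flagged with an infinite RPD rather than an error."""
    rp2 = r_squared(pred)
    if rp2 >= 1.0:
        rpd_value = math.inf
    else:
        rpd_value = rpd(rp2)
    return MetricsReport(
        rc2=r_squared(cal),
        rmsec=rmse(cal),
        rv2=r_squared(val),
        rmsev=rmse(val),
        rp2=rp2,
        rmsep=rmse(pred),
        rpd=rpd_value,
        rpd_band=classify_rpd(rpd_value),
    )
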