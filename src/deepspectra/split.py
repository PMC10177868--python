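"""Interval-sampling dataset division and per-set reference statistics.

Samples are rank-ordered by reference content and divided block-wise: in
each consecutive block of ``cal + val + pred`` ranks, the lowest ``cal``
ranks go to calibration, the next ``val`` to validation and the last
``pred`` to prediction.  With the default 3:1:1 pattern on 100 samples this
yields the 60/20/20 division, every set spans the concentration range, and
the calibration set always contains the global minimum (rank 1).  The
global maximum is optionally swapped into calibration so its range covers
the other sets entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SplitError, StatsError
from .spectra import ReferenceTable

SET_NAMES = ("calibration", "validation", "prediction")


@dataclass
class SplitIndices:
    """Disjoint index lists into the original sample order."""

    calibration: list[int]
    validation: list[int]
    prediction: list[int]

    def as_dict(self) -> dict[str, list[int]]:
        return {
            "calibration": self.calibration,
            "validation": self.validation,
            "prediction": self.prediction,
        }

    def to_frame(self, sample_ids: list[str]) -> pd.DataFrame:
        records = []
        for name, idx in self.as_dict().items():
            records += [(sample_ids[i], name) for i in idx]
        return pd.DataFrame(records, columns=["sample_id", "set"]).sort_values(
            "sample_id", ignore_index=True
        )


def interval_split(
    refs: ReferenceTable,
    pattern: tuple[int, int, int] = (3, 1, 1),
    ensure_max_coverage: bool = True,
) -> SplitIndices:
    """Deterministic interval sampling by reference-content rank.

    Ties in content are broken by sample id, so the division is invariant
    to the input row order.  A trailing partial block goes to calibration.
    With ``ensure_max_coverage`` (default), the global-maximum sample is
    swapped into calibration if the block rule placed it elsewhere, which
    guarantees the calibration range covers the validation and prediction
    ranges.
    """
    cal_k, val_k, pred_k = pattern
    if min(cal_k, val_k, pred_k) < 0 or cal_k == 0:
        raise SplitError(f"invalid pattern {pattern}")
    block = cal_k + val_k + pred_k
    n = len(refs)
    if n < block:
        raise SplitError(f"need at least {block} samples, got {n}")

    order = sorted(range(n), key=lambda i: (refs.contents[i], refs.sample_ids[i]))
    sets: dict[str, list[int]] = {name: [] for name in SET_NAMES}
    n_full = (n // block) * block
    for rank, idx in enumerate(order[:n_full]):
        r = rank % block
        if r < cal_k:
            sets["calibration"].append(idx)
        elif r < cal_k + val_k:
            sets["validation"].append(idx)
        else:
            sets["prediction"].append(idx)
    sets["calibration"].extend(order[n_full:])  # trailing partial block

    if ensure_max_coverage:
        imax = order[-1]
        for name in ("validation", "prediction"):
            if imax in sets[name]:
                # swap with the highest-content calibration sample
                cal_top = max(
                    sets["calibration"],
                    key=lambda i: (refs.contents[i], refs.sample_ids[i]),
                )
                sets[name].remove(imax)
                sets[name].append(cal_top)
                sets["calibration"].remove(cal_top)
                sets["calibration"].append(imax)
    return SplitIndices(sets["calibration"], sets["validation"], sets["prediction"])


def compute_stats(refs: ReferenceTable, split: SplitIndices) -> pd.DataFrame:
    """Per-set n / max / min / mean / SD (n−1 denominator) of the contents."""
    rows = []
    for name, idx in split.as_dict().items():
        if not idx:
            raise StatsError(f"{name} set is empty")
        if len(idx) < 2:
            raise StatsError(f"{name} set has a single sample; SD undefined")
        x = refs.contents[np.asarray(idx)]
        rows.append(
            {
                "set": name,
                "n": len(idx),
                "max": x.max(),
                "min": x.min(),
                "mean": x.mean(),
                "sd": x.std(ddof=1),
            }
        )
    total = refs.contents
    rows.append(
        {
            "set": "total",
            "n": len(refs),
            "max": total.max(),
            "min": total.min(),
            "mean": total.mean(),
            "sd": total.std(ddof=1),
        }
    )
    return pd.DataFrame(rows)
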