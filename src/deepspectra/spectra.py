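"""In-memory containers for spectra and reference contents, plus CSV I/O.

The CSV dialect is shared by every pipeline stage:

* spectra: first column ``wavelength_nm``, one column per sample (or per
  replicate, named ``<sampleID>_r<k>`` before averaging);
* references: columns ``sample_id, content_ug_per_g``;
* white/dark references: columns ``wavelength_nm, value``.

A sidecar ``<name>.meta`` key-value text file records the processing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError

#: Processing stages a SpectraSet can be in, in pipeline order.
STAGES = ("raw", "calibrated", "averaged", "resampled", "derivative")


@dataclass
class SpectraSet:
    """A wavelength grid with one spectrum per sample.

    Parameters
    ----------
    wavelengths : ndarray, shape (n_wavelengths,)
        Strictly increasing grid in nm.
    values : ndarray, shape (n_samples, n_wavelengths)
        Reflectance (unitless), raw counts, or first derivative (per nm),
        depending on ``stage``.
    sample_ids : list of str
        Row labels; replicate columns are named ``<sampleID>_r<k>``.
    stage : str
        One of :data:`STAGES`.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: list[str]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = list(self.sample_ids)
        if self.stage not in STAGES:
            raise DataError(f"unknown stage {self.stage!r}")
        if self.wavelengths.ndim != 1 or np.any(np.diff(self.wavelengths) <= 0):
            raise DataError("wavelength grid must be 1-D and strictly increasing")
        if self.values.shape != (len(self.sample_ids), self.wavelengths.size):
            raise DataError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("spectra contain non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_values(self, values: np.ndarray, stage: str | None = None) -> "SpectraSet":
        """Copy with new values (same grid/ids), optionally advancing the stage."""
        return replace(self, values=values, stage=stage or self.stage)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wavelength_nm": self.wavelengths})
        for sid, row in zip(self.sample_ids, self.values):
            df[sid] = row
        return df

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        path.with_suffix(path.suffix + ".meta").write_text(f"stage: {self.stage}\n")

    @classmethod
    def from_csv(cls, path: str | Path, stage: str | None = None) -> "SpectraSet":
        path = Path(path)
        df = pd.read_csv(path)
        if stage is None:
            meta = path.with_suffix(path.suffix + ".meta")
            stage = "raw"
            if meta.exists():
                for line in meta.read_text().splitlines():
                    key, _, value = line.partition(":")
                    if key.strip() == "stage":
                        stage = value.strip()
        wavelengths = df["wavelength_nm"].to_numpy()
        ids = [c for c in df.columns if c != "wavelength_nm"]
        return cls(wavelengths, df[ids].to_numpy().T, ids, stage=stage)


@dataclass
class ReferenceTable:
    """Per-sample analyte content in µg/g — the regression target."""

    sample_ids: list[str]
    contents: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.contents = np.asarray(self.contents, dtype=float).ravel()
        if self.contents.size != len(self.sample_ids):
            raise DataError("one content per sample_id required")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def aligned_to(self, sample_ids: list[str]) -> np.ndarray:
        """Contents reordered to match ``sample_ids``; error on unknown ids."""
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        try:
            order = [index[s] for s in sample_ids]
        except KeyError as exc:  # pragma: no cover - message path
            raise DataError(f"sample id {exc.args[0]!r} missing from reference table")
        return self.contents[order]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": self.sample_ids, "content_ug_per_g": self.contents}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        df = pd.read_csv(path)
        return cls(df["sample_id"].astype(str).tolist(), df["content_ug_per_g"].to_numpy())


def write_reference_vector(path: str | Path, wavelengths: np.ndarray, values: np.ndarray) -> None:
    """Write a white/dark reference as ``wavelength_nm, value`` CSV."""
    pd.DataFrame({"wavelength_nm": wavelengths, "value": values}).to_csv(path, index=False)


def read_reference_vector(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["wavelength_nm"].to_numpy(), df["value"].to_numpy()
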