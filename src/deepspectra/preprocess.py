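"""Raw acquisition → network-ready spectra.

Pipeline order: white/dark reflectance calibration, replicate averaging,
resampling onto a uniform 1000-point grid, and a Savitzky–Golay first
derivative (window 5, polynomial order 2).  Resampling precedes the
derivative so the uniform-spacing precondition of the SG filter holds.
"""

from __future__ import annotations

import re

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import CalibrationError, GroupingError, ParameterError
from .spectra import SpectraSet

_REPLICATE_RE = re.compile(r"^(?P<sample>.+)_r(?P<k>\d+)$")


def calibrate_reflectance(
    raw: SpectraSet, white: np.ndarray, dark: np.ndarray
) -> SpectraSet:
    """Convert raw counts to reflectance: ``(raw − dark) / (white − dark)``.

    Raises
    ------
    CalibrationError
        If ``white ≤ dark`` at any wavelength (names the first offender).
    """
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if white.shape != raw.wavelengths.shape or dark.shape != raw.wavelengths.shape:
        raise CalibrationError("white/dark references must match the wavelength grid")
    bad = np.nonzero(white <= dark)[0]
    if bad.size:
        wl = raw.wavelengths[bad[0]]
        raise CalibrationError(
            f"white reference does not exceed dark at {wl:.2f} nm "
            f"({bad.size} wavelength(s) affected)"
        )
    values = (raw.values - dark) / (white - dark)
    return raw.with_values(values, stage="calibrated")


def replicate_grouping(sample_ids: list[str]) -> dict[str, list[str]]:
    """Infer the sample → replicate-column mapping from ``<id>_r<k>`` names."""
    groups: dict[str, list[str]] = {}
    for col in sample_ids:
        m = _REPLICATE_RE.match(col)
        sample = m.group("sample") if m else col
        groups.setdefault(sample, []).append(col)
    return groups


def average_replicates(
    spectra: SpectraSet, grouping: dict[str, list[str]] | None = None
) -> SpectraSet:
    """Average each sample's replicate spectra into one row per sample."""
    if grouping is None:
        grouping = replicate_grouping(spectra.sample_ids)
    col_index = {c: i for i, c in enumerate(spectra.sample_ids)}
    rows = []
    ids = []
    for sample, cols in grouping.items():
        if not cols:
            raise GroupingError(f"sample {sample!r} has no replicate columns")
        try:
            idx = [col_index[c] for c in cols]
        except KeyError as exc:
            raise GroupingError(
                f"replicate column {exc.args[0]!r} not present in spectra"
            ) from None
        rows.append(spectra.values[idx].mean(axis=0))
        ids.append(sample)
    return SpectraSet(spectra.wavelengths, np.array(rows), ids, stage="averaged")


def resample_to_length(spectra: SpectraSet, n_points: int = 1000) -> SpectraSet:
    """Linearly interpolate every spectrum onto a uniform ``n_points`` grid.

    The new grid spans the input's wavelength range end to end, so an input
    that is already uniform with ``n_points`` columns passes through
    unchanged.
    """
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    grid = np.linspace(spectra.wavelengths[0], spectra.wavelengths[-1], n_points)
    values = np.empty((spectra.n_samples, n_points))
    for i, row in enumerate(spectra.values):
        values[i] = np.interp(grid, spectra.wavelengths, row)
    return SpectraSet(grid, values, spectra.sample_ids, stage="resampled")


def savitzky_golay_first_derivative(
    spectra: SpectraSet, window: int = 5, polyorder: int = 2
) -> SpectraSet:
    """Savitzky–Golay first derivative, in reflectance per nm.

    The filter fits an order-``polyorder`` polynomial in each ``window``-point
    neighbourhood and reads off its slope; it is exact for polynomials up to
    that order.  The signal is mirror-padded so the output has the same
    length as the input; interior points are unaffected by the padding.
    Requires a uniform wavelength grid (run after :func:`resample_to_length`).
    """
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ParameterError(
            f"window ({window}) must exceed polynomial order ({polyorder})"
        )
    spacing = np.diff(spectra.wavelengths)
    if not np.allclose(spacing, spacing[0], rtol=1e-8):
        raise ParameterError("wavelength grid must be uniform; resample first")
    values = savgol_filter(
        spectra.values, window, polyorder, deriv=1, delta=spacing[0], axis=1, mode="mirror"
    )
    return spectra.with_values(values, stage="derivative")


def preprocess_pipeline(
    raw: SpectraSet,
    white: np.ndarray,
    dark: np.ndarray,
    n_points: int = 1000,
    window: int = 5,
    polyorder: int = 2,
) -> SpectraSet:
    """Full chain: calibrate → average replicates → resample → SG 1st derivative."""
    out = calibrate_reflectance(raw, white, dark)
    out = average_replicates(out)
    out = resample_to_length(out, n_points)
    return savitzky_golay_first_derivative(out, window, polyorder)
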