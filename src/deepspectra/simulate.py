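"""Synthetic Vis/NIR diffuse-reflectance acquisitions with a planted analyte band.

The generator emulates the statistical structure of melon-rind reflectance
spectra in the 380–1140 nm range: a smooth baseline rising toward the NIR,
chlorophyll absorption near 420 and 675 nm, a weak C–H third-overtone band
near 835 nm, a strong water band near 975 nm, per-sample multiplicative
scatter, additive noise, and a concentration-dependent depression of the
spectrum in a designated analyte band.  Raw instrument counts are produced
by inverting the standard white/dark reflectance calibration so that the
downstream calibration step recovers the simulated reflectance exactly.

The planted analyte band is a testing convention: it makes residue content
recoverable by construction so the whole calibration pipeline can be
exercised end to end; it is not a claim about where real pesticide signal
lives in the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .spectra import ReferenceTable, SpectraSet


@dataclass
class SimConfig:
    """Parameters of the synthetic acquisition.

    Defaults follow the instrument geometry (380–1140 nm at ~0.69 nm native
    resolution, four replicate spectra per sample) and a lambda-cyhalothrin-like
    residue range of 0.96–32.36 µg/g.
    """

    n_samples: int = 100
    wavelength_start: float = 380.0
    wavelength_end: float = 1140.0
    n_native_points: int = 1101
    #: absorption band centers (nm): chlorophyll blue/red, C–H 3rd overtone, water
    band_centers: tuple[float, ...] = (420.0, 675.0, 835.0, 975.0)
    #: Gaussian sigmas (nm) of the bands
    band_widths: tuple[float, ...] = (14.0, 10.0, 12.0, 14.0)
    #: unitless absorptance amplitudes (fractional reflectance depression)
    band_depths: tuple[float, ...] = (0.30, 0.35, 0.08, 0.35)
    analyte_range: tuple[float, float] = (0.96, 32.36)
    #: (center nm, sigma nm, absorptance per µg/g) of the planted analyte band
    analyte_response: tuple[float, float, float] = (835.0, 12.0, 0.004)
    scatter_sd: float = 0.01
    noise_sd: float = 0.002
    replicates_per_sample: int = 4
    #: 'uniform' on analyte_range, or 'clusters' mimicking three dilution groups
    content_distribution: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ConfigError("n_samples must be >= 0")
        if not self.wavelength_start < self.wavelength_end:
            raise ConfigError("wavelength_start must be < wavelength_end")
        if self.n_native_points < 2:
            raise ConfigError("n_native_points must be >= 2")
        if len(self.band_centers) != len(self.band_widths) or len(
            self.band_centers
        ) != len(self.band_depths):
            raise ConfigError("band centers/widths/depths must have equal length")
        if any(w <= 0 for w in self.band_widths) or self.analyte_response[1] <= 0:
            raise ConfigError("all band widths must be > 0")
        lo, hi = self.analyte_range
        if not lo < hi:
            raise ConfigError(f"invalid analyte_range ({lo}, {hi}): min must be < max")
        if self.noise_sd < 0 or self.scatter_sd < 0:
            raise ConfigError("noise_sd and scatter_sd must be >= 0")
        if self.replicates_per_sample < 1:
            raise ConfigError("replicates_per_sample must be >= 1")
        if self.content_distribution not in ("uniform", "clusters"):
            raise ConfigError(f"unknown content_distribution {self.content_distribution!r}")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_start, self.wavelength_end, self.n_native_points)


@dataclass
class RawAcquisition:
    """Uncalibrated replicate spectra plus the white/dark reference scans."""

    spectra: SpectraSet
    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape or self.white.shape != self.spectra.wavelengths.shape:
            raise ConfigError("white/dark references must share the wavelength grid")
        if not np.all(self.white > self.dark):
            raise ConfigError("white reference must exceed dark at every wavelength")


def _gaussian(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _baseline(wl: np.ndarray, start: float, end: float) -> np.ndarray:
    # low-order polynomial rising toward the NIR
    u = (wl - start) / (end - start)
    return 0.35 + 0.45 * u - 0.15 * u**2


def generate_reference_contents(config: SimConfig) -> ReferenceTable:
    """Draw per-sample residue contents (µg/g) on the configured range.

    Uniform by default; ``'clusters'`` draws from three equally likely
    truncated-normal groups mimicking low/medium/high dilution levels.
    Reproducible under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    lo, hi = config.analyte_range
    n = config.n_samples
    if config.content_distribution == "uniform":
        contents = rng.uniform(lo, hi, size=n)
    else:
        centers = lo + (hi - lo) * np.array([0.15, 0.45, 0.80])
        group = rng.integers(0, 3, size=n)
        contents = rng.normal(centers[group], 0.08 * (hi - lo))
        contents = np.clip(contents, lo, hi)
    ids = [f"s{i + 1:03d}" for i in range(n)]
    return ReferenceTable(ids, contents)


def generate_raw_acquisition(refs: ReferenceTable, config: SimConfig) -> RawAcquisition:
    """Simulate replicate raw-count spectra for each sample in ``refs``.

    The reflectance model is

    ``R(λ) = s_i · B(λ) · Π_k (1 − depth_k G_k(λ)) · (1 − a·c_i·G_a(λ)) + ε(λ)``

    with ``B`` the smooth baseline, ``G`` unit-height Gaussians,
    ``s_i ~ N(1, scatter_sd)`` shared across a sample's replicates, and
    ``ε ~ N(0, noise_sd)`` independent per replicate and wavelength.  Raw
    counts are ``dark + R·(white − dark)`` so reflectance calibration
    inverts the construction exactly.
    """
    if len(refs) == 0:
        raise ConfigError("reference table is empty")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    wl = config.wavelengths
    clean = _baseline(wl, config.wavelength_start, config.wavelength_end)
    for center, sigma, depth in zip(config.band_centers, config.band_widths, config.band_depths):
        clean = clean * (1.0 - depth * _gaussian(wl, center, sigma))

    a_center, a_sigma, a_amp = config.analyte_response
    analyte_band = _gaussian(wl, a_center, a_sigma)

    # smooth instrument response curves, white well above dark everywhere
    u = (wl - config.wavelength_start) / (config.wavelength_end - config.wavelength_start)
    white = 30000.0 + 25000.0 * np.sin(np.pi * np.clip(0.1 + 0.8 * u, 0, 1))
    dark = 1500.0 + 400.0 * u

    n_rep = config.replicates_per_sample
    rows = []
    ids = []
    scatter = rng.normal(1.0, config.scatter_sd, size=len(refs))
    for i, (sid, c) in enumerate(zip(refs.sample_ids, refs.contents)):
        sample_r = scatter[i] * clean * (1.0 - a_amp * c * analyte_band)
        for k in range(n_rep):
            noise = rng.normal(0.0, config.noise_sd, size=wl.size) if config.noise_sd > 0 else 0.0
            reflectance = sample_r + noise
            rows.append(dark + reflectance * (white - dark))
            ids.append(f"{sid}_r{k + 1}")
    spectra = SpectraSet(wl, np.array(rows), ids, stage="raw")
    return RawAcquisition(spectra=spectra, white=white, dark=dark)
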