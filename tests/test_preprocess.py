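"""Reflectance calibration, replicate averaging, resampling and SG derivative."""

import numpy as np
import pytest

from deepspectra import (
    average_replicates,
    calibrate_reflectance,
    preprocess_pipeline,
    resample_to_length,
    savitzky_golay_first_derivative,
)
from deepspectra.exceptions import CalibrationError, GroupingError, ParameterError
from deepspectra.preprocess import replicate_grouping

from conftest import make_spectra


class TestCalibration:
    def setup_method(self):
        self.wl = np.linspace(380, 1140, 50)
        self.white = 30000 + 100 * np.arange(50.0)
        self.dark = 1500 + np.arange(50.0)

    def _raw(self, values):
        return make_spectra(values, self.wl, stage="raw")

    @pytest.mark.parametrize("frac,expected", [(1.0, 1.0), (0.0, 0.0), (0.5, 0.5)])
    def test_reference_anchors(self, frac, expected):
        raw = self._raw(self.dark + frac * (self.white - self.dark))
        cal = calibrate_reflectance(raw, self.white, self.dark)
        np.testing.assert_allclose(cal.values, expected, atol=1e-12)
        assert cal.stage == "calibrated"

    def test_error_names_offending_wavelength(self):
        white = self.white.copy()
        white[7] = self.dark[7]  # white == dark at index 7
        with pytest.raises(CalibrationError, match=f"{self.wl[7]:.2f}"):
            calibrate_reflectance(self._raw(self.dark + 1), white, self.dark)

    def test_common_gain_invariance(self, rng):
        raw_values = self.dark + rng.uniform(0, 1, (3, 50)) * (self.white - self.dark)
        cal = calibrate_reflectance(self._raw(raw_values), self.white, self.dark)
        gain = 3.7
        cal_scaled = calibrate_reflectance(
            self._raw(gain * raw_values), gain * self.white, gain * self.dark
        )
        np.testing.assert_allclose(cal.values, cal_scaled.values, rtol=1e-12)


class TestAverageReplicates:
    def test_identical_replicates_pass_through(self, rng):
        row = rng.normal(size=20)
        spectra = make_spectra(np.tile(row, (4, 1)), ids=[f"a_r{k}" for k in range(1, 5)])
        out = average_replicates(spectra)
        assert out.sample_ids == ["a"]
        np.testing.assert_allclose(out.values[0], row, rtol=1e-15)

    def test_two_point_mean(self):
        spectra = make_spectra([[0.0] * 5, [1.0] * 5], ids=["a_r1", "a_r2"])
        out = average_replicates(spectra)
        np.testing.assert_allclose(out.values, 0.5)

    def test_matches_column_mean_oracle(self, rng):
        values = rng.normal(size=(8, 30))
        ids = [f"s{i}_r{k}" for i in range(2) for k in range(4)]
        out = average_replicates(make_spectra(values, ids=ids))
        # brute-force oracle: plain means over explicit index groups
        np.testing.assert_allclose(out.values[0], values[:4].mean(axis=0), rtol=1e-15)
        np.testing.assert_allclose(out.values[1], values[4:].mean(axis=0), rtol=1e-15)

    def test_unknown_replicate_column_errors(self, rng):
        spectra = make_spectra(rng.normal(size=(2, 5)), ids=["a_r1", "a_r2"])
        with pytest.raises(GroupingError, match="missing"):
            average_replicates(spectra, {"a": ["a_r1", "a_missing"]})

    def test_grouping_inference(self):
        groups = replicate_grouping(["x_r1", "x_r2", "y_r1", "plain"])
        assert groups == {"x": ["x_r1", "x_r2"], "y": ["y_r1"], "plain": ["plain"]}


class TestResample:
    def test_identity_on_matching_uniform_grid(self, rng):
        wl = np.linspace(380, 1140, 100)
        spectra = make_spectra(rng.normal(size=(3, 100)), wl)
        out = resample_to_length(spectra, 100)
        np.testing.assert_allclose(out.values, spectra.values, rtol=1e-12)
        np.testing.assert_allclose(out.wavelengths, wl, rtol=1e-12)

    def test_linear_spectrum_reproduced_exactly(self):
        wl = np.linspace(380, 1140, 1101)
        spectra = make_spectra(0.001 * wl + 0.2, wl)
        out = resample_to_length(spectra, 1000)
        np.testing.assert_allclose(out.values[0], 0.001 * out.wavelengths + 0.2, rtol=1e-12)

    def test_sine_interpolation_error_bound(self):
        """1101 -> 1000 points on a sine stays within 1e-3 of the dense oracle."""
        wl = np.linspace(380, 1140, 1101)
        spectra = make_spectra(np.sin(2 * np.pi * wl / 100.0), wl)
        out = resample_to_length(spectra, 1000)
        oracle = np.sin(2 * np.pi * out.wavelengths / 100.0)
        assert np.max(np.abs(out.values[0] - oracle)) < 1e-3

    def test_too_few_points_rejected(self, rng):
        spectra = make_spectra(rng.normal(size=(1, 10)))
        with pytest.raises(ParameterError):
            resample_to_length(spectra, 1)


class TestSavitzkyGolay:
    def test_constant_gives_zero(self):
        spectra = make_spectra(np.full((2, 40), 3.3))
        out = savitzky_golay_first_derivative(spectra)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)
        assert out.stage == "derivative"

    def test_exact_on_quadratics_interior(self):
        wl = np.linspace(0, 10, 51)
        spectra = make_spectra(wl**2, wl)
        out = savitzky_golay_first_derivative(spectra, window=5, polyorder=2)
        np.testing.assert_allclose(out.values[0][2:-2], 2 * wl[2:-2], rtol=1e-10)

    def test_interior_matches_local_polyfit_oracle(self, rng):
        """Each interior output equals the slope of an LS quadratic over its window."""
        wl = np.linspace(0, 5, 41)
        y = rng.normal(size=41).cumsum()  # arbitrary smooth-ish signal
        out = savitzky_golay_first_derivative(make_spectra(y, wl), 5, 2).values[0]
        h = wl[1] - wl[0]
        for i in range(2, 39):
            window_x = (np.arange(-2, 3)) * h
            coeffs = np.polyfit(window_x, y[i - 2 : i + 3], 2)
            assert abs(out[i] - coeffs[1]) < 1e-10

    def test_linearity(self, rng):
        wl = np.linspace(0, 1, 30)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        d = lambda v: savitzky_golay_first_derivative(make_spectra(v, wl)).values[0]
        np.testing.assert_allclose(d(2.5 * x - 1.5 * y), 2.5 * d(x) - 1.5 * d(y), atol=1e-12)

    @pytest.mark.parametrize("window,polyorder", [(4, 2), (5, 5), (3, 4)])
    def test_invalid_filter_parameters(self, window, polyorder):
        spectra = make_spectra(np.zeros((1, 20)))
        with pytest.raises(ParameterError):
            savitzky_golay_first_derivative(spectra, window, polyorder)

    def test_nonuniform_grid_rejected(self, rng):
        wl = np.sort(rng.uniform(380, 1140, 30))
        spectra = make_spectra(rng.normal(size=(1, 30)), wl)
        with pytest.raises(ParameterError, match="uniform"):
            savitzky_golay_first_derivative(spectra)


def test_full_chain_permutation_equivariant(small_acquisition):
    """Reordering samples permutes the preprocessed output identically."""
    refs, acq = small_acquisition
    out = preprocess_pipeline(acq.spectra, acq.white, acq.dark, n_points=150)
    perm = np.arange(acq.spectra.n_samples)[::-1]
    shuffled = make_spectra(
        acq.spectra.values[perm],
        acq.spectra.wavelengths,
        stage="raw",
        ids=[acq.spectra.sample_ids[i] for i in perm],
    )
    out2 = preprocess_pipeline(shuffled, acq.white, acq.dark, n_points=150)
    lookup = {sid: row for sid, row in zip(out2.sample_ids, out2.values)}
    for sid, row in zip(out.sample_ids, out.values):
        np.testing.assert_allclose(row, lookup[sid], rtol=0, atol=1e-12)
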