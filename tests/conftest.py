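import numpy as np
import pytest

from deepspectra import SimConfig, SpectraSet, generate_raw_acquisition, generate_reference_contents


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A fast, fully featured acquisition: 12 samples, 2 replicates, 201 points."""
    return SimConfig(n_samples=12, n_native_points=201, replicates_per_sample=2, seed=42)


@pytest.fixture
def small_acquisition(small_config):
    refs = generate_reference_contents(small_config)
    return refs, generate_raw_acquisition(refs, small_config)


def make_spectra(values, wavelengths=None, stage="calibrated", ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if wavelengths is None:
        wavelengths = np.arange(values.shape[1], dtype=float)
    if ids is None:
        ids = [f"s{i}" for i in range(values.shape[0])]
    return SpectraSet(wavelengths, values, ids, stage=stage)
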