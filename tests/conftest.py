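"""Shared fixtures: tiny hand-built datasets and one simulated section."""

import numpy as np
import pytest

from osteomsi import (
    MarkerConfig,
    MSIDataset,
    PhantomSpec,
    make_phantom,
    normalize_spectra,
    simulate_dataset,
)
from osteomsi.features import extract_feature_table, mean_spectrum, select_top_n, spectrum_peaks


@pytest.fixture
def tiny_dataset():
    """3 pixels, 4 shared channels, hand-written intensities."""
    return MSIDataset(
        pixels=np.array([[0, 0], [1, 0], [0, 1]]),
        mass_axis=np.array([1000.0, 1100.0, 1570.6768, 1600.0]),
        intensities=np.array(
            [
                [1.0, 2.0, 4.0, 0.5],
                [0.0, 3.0, 2.0, 1.0],
                [2.0, 0.0, 8.0, 0.0],
            ]
        ),
    )


@pytest.fixture(scope="session")
def sim_section():
    """One simulated diseased section on the default phantom (CV 0.2)."""
    truth = make_phantom(PhantomSpec(), seed=11, diseased=True)
    ds, truth = simulate_dataset(truth, MarkerConfig(), seed=11)
    return ds, truth


@pytest.fixture(scope="session")
def sim_table(sim_section):
    """Reference-normalized top-500 feature table of the simulated section."""
    ds, truth = sim_section
    norm = normalize_spectra(ds, "reference_peak")
    peaks = spectrum_peaks(mean_spectrum(norm))
    table = extract_feature_table(norm, select_top_n(peaks, 500))
    return table, truth
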