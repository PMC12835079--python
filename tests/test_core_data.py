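"""Dataset model, I/O round trips, resampling and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteomsi import (
    MSIDataset,
    PipelineConfig,
    normalize_spectra,
    read_msi,
    resample_common_axis,
    write_msi,
)
from osteomsi.core_data import drop_flagged, remove_baseline
from osteomsi.synthetic import MarkerConfig, PhantomSpec, make_phantom, simulate_dataset


def test_tsv_identity_round_trip(tmp_path):
    """A tiny TSV reads back with the intensities exactly as written."""
    path = tmp_path / "tiny.tsv"
    path.write_text(
        "x\ty\tmz\tintensity\n"
        "0\t0\t1000.0\t1.5\n0\t0\t1200.0\t2.5\n"
        "1\t0\t1000.0\t0.5\n1\t0\t1200.0\t3.5\n"
        "0\t1\t1000.0\t4.0\n0\t1\t1200.0\t0.0\n"
    )
    ds = read_msi(path)
    assert ds.n_pixels == 3
    assert ds.has_common_axis
    np.testing.assert_array_equal(ds.mass_axis, [1000.0, 1200.0])
    np.testing.assert_array_equal(
        ds.intensities, [[1.5, 2.5], [0.5, 3.5], [4.0, 0.0]]
    )


@pytest.mark.parametrize("fmt", ["tsv", "imzml"])
def test_write_read_inverse(tiny_dataset, tmp_path, fmt):
    path = tmp_path / f"ds.{fmt if fmt == 'tsv' else 'imzML'}"
    write_msi(tiny_dataset, path, format=fmt)
    back = read_msi(path, format=fmt)
    np.testing.assert_array_equal(back.pixels, tiny_dataset.pixels)
    np.testing.assert_allclose(back.mass_axis, tiny_dataset.mass_axis, rtol=1e-6)
    np.testing.assert_allclose(back.intensities, tiny_dataset.intensities, rtol=1e-6)


def test_imzml_round_trip_synthetic(tmp_path):
    """imzML written for a simulated section keeps its pixel/channel census."""
    spec = PhantomSpec(
        grid=(10, 10),
        fractions={
            "cartilage": 0.2, "transitional": 0.0,
            "healthy_bone": 0.4, "diseased_bone": 0.1, "marrow": 0.3,
        },
    )
    truth = make_phantom(spec, seed=3)
    n_markers = len(MarkerConfig().markers)
    ds, _ = simulate_dataset(
        truth, MarkerConfig(n_null_features=500 - n_markers - 1), seed=3
    )
    path = tmp_path / "sim.imzML"
    write_msi(ds, path)
    back = read_msi(path)
    assert back.n_pixels == 100
    assert len(back.mass_axis) == 500
    assert len(back.mass_axis) == len(ds.mass_axis)
    rel = np.abs(back.intensities - ds.intensities) / np.maximum(ds.intensities, 1e-300)
    assert np.nanmax(rel[ds.intensities > 0]) <= 1e-6


def test_write_refuses_empty(tmp_path):
    ds = MSIDataset(
        pixels=np.empty((0, 2), int),
        mass_axis=np.array([100.0]),
        intensities=np.empty((0, 1)),
    )
    with pytest.raises(ValueError, match="0 pixels"):
        write_msi(ds, tmp_path / "empty.tsv")


def test_duplicate_pixel_coordinates_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        MSIDataset(
            pixels=np.array([[0, 0], [0, 0]]),
            mass_axis=np.array([100.0]),
            intensities=np.ones((2, 1)),
        )


def test_malformed_tsv_names_problem(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("x\ty\tmz\n0\t0\t100\n")
    with pytest.raises(ValueError, match="intensity"):
        read_msi(path)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_resample_single_peak_preserves_tic():
    ds = MSIDataset(
        pixels=np.array([[0, 0]]),
        spectra=[(np.array([1000.0]), np.array([7.5]))],
    )
    (out,) = resample_common_axis([ds], bin_width_da=0.1)
    assert out.tic()[0] == pytest.approx(7.5, abs=0)
    j = np.argmax(out.intensities[0])
    assert abs(out.mass_axis[j] - 1000.0) <= 0.05


def test_resample_disjoint_axes_share_one_axis():
    a = MSIDataset(
        pixels=np.array([[0, 0]]),
        spectra=[(np.array([100.0, 101.0]), np.array([1.0, 2.0]))],
    )
    b = MSIDataset(
        pixels=np.array([[0, 0]]),
        spectra=[(np.array([500.0, 501.0]), np.array([3.0, 4.0]))],
    )
    ra, rb = resample_common_axis([a, b], bin_width_da=0.5)
    np.testing.assert_array_equal(ra.mass_axis, rb.mass_axis)
    assert ra.mass_axis[0] > 99.0 and ra.mass_axis[-1] < 502.0
    assert ra.tic()[0] == pytest.approx(3.0, rel=1e-12)
    assert rb.tic()[0] == pytest.approx(7.0, rel=1e-12)


def test_resample_boundary_mass_goes_to_upper_bin():
    """A mass exactly on an interior bin edge lands in the upper bin."""
    # 0.25-wide bins with edges 100.0, 100.25, 100.5 are exactly
    # representable in binary, so 100.5 sits exactly on an edge and must
    # fall in the upper bin [100.5, 100.75), center 100.625
    ds = MSIDataset(
        pixels=np.array([[0, 0]]),
        spectra=[(np.array([100.0, 100.5]), np.array([1.0, 5.0]))],
    )
    (out,) = resample_common_axis([ds], bin_width_da=0.25)
    j = np.argmax(out.intensities[0])
    assert out.mass_axis[j] == pytest.approx(100.625)
    assert out.tic()[0] == pytest.approx(6.0, rel=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_resample_conserves_tic_property(seed):
    """TIC conservation to 1e-9 relative on random ragged spectra."""
    rng = np.random.default_rng(seed)
    n_pix = rng.integers(1, 5)
    spectra = []
    for _ in range(n_pix):
        n = int(rng.integers(1, 60))
        mz = np.sort(rng.uniform(100, 2000, n))
        mz = np.unique(mz)
        spectra.append((mz, rng.exponential(1.0, len(mz))))
    ds = MSIDataset(
        pixels=np.array([[i, 0] for i in range(len(spectra))]), spectra=spectra
    )
    (out,) = resample_common_axis([ds], bin_width_da=float(rng.uniform(0.05, 5.0)))
    np.testing.assert_allclose(out.tic(), ds.tic(), rtol=1e-9)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _ref_dataset(areas):
    """One spike-in channel per pixel with the given window areas."""
    n = len(areas)
    return MSIDataset(
        pixels=np.array([[i, 0] for i in range(n)]),
        mass_axis=np.array([1000.0, 1570.6768, 1800.0]),
        intensities=np.column_stack(
            [np.full(n, 2.0), np.asarray(areas, float), np.full(n, 4.0)]
        ),
    )


def test_reference_peak_scales_to_unit_area():
    ds = _ref_dataset([4.0, 1.0])
    out = normalize_spectra(ds, "reference_peak")
    np.testing.assert_allclose(out.intensities[0], [0.5, 1.0, 1.0])
    cfg = PipelineConfig()
    w = (out.mass_axis >= cfg.ref_mz - cfg.ref_window_da) & (
        out.mass_axis <= cfg.ref_mz + cfg.ref_window_da
    )
    np.testing.assert_allclose(out.intensities[:, w].sum(axis=1), 1.0)


def test_reference_peak_gain_invariance_and_idempotence():
    ds = _ref_dataset([4.0, 2.0, 1.0])
    rng = np.random.default_rng(0)
    gains = rng.uniform(0.1, 10.0, ds.n_pixels)
    corrupted = MSIDataset(
        pixels=ds.pixels,
        mass_axis=ds.mass_axis,
        intensities=ds.intensities * gains[:, None],
    )
    a = normalize_spectra(ds, "reference_peak")
    b = normalize_spectra(corrupted, "reference_peak")
    np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-12)
    twice = normalize_spectra(a, "reference_peak")
    np.testing.assert_allclose(twice.intensities, a.intensities, rtol=1e-12)


@pytest.mark.parametrize("method,check", [
    ("tic", lambda out: out.intensities.sum(axis=1)),
    ("rms", lambda out: np.sqrt(np.mean(out.intensities**2, axis=1))),
])
def test_tic_rms_normalize_to_unit(method, check):
    out = normalize_spectra(_ref_dataset([4.0, 2.0]), method)
    np.testing.assert_allclose(check(out), 1.0)


def test_dropout_pixels_flagged_exactly():
    """Pixels simulated without the spike-in are exactly the flagged set."""
    truth = make_phantom(PhantomSpec(grid=(20, 20)), seed=5)
    ds, truth = simulate_dataset(
        truth, MarkerConfig(n_null_features=50, ref_dropout=0.05), seed=5
    )
    out = normalize_spectra(ds, "reference_peak")
    assert set(out.flagged_pixels().tolist()) == set(truth.ref_dropout_pixels.tolist())
    assert out.metadata["n_flagged"] == len(truth.ref_dropout_pixels)
    kept = drop_flagged(out)
    assert kept.n_pixels == ds.n_pixels - len(truth.ref_dropout_pixels)


def test_normalize_errors():
    ds = _ref_dataset([4.0])
    with pytest.raises(ValueError, match="unknown normalization"):
        normalize_spectra(ds, "median")
    no_ref = MSIDataset(
        pixels=np.array([[0, 0]]),
        mass_axis=np.array([100.0, 200.0]),
        intensities=np.array([[1.0, 2.0]]),
    )
    with pytest.raises(ValueError, match="outside the mass axis|outside mass axis"):
        normalize_spectra(no_ref, "reference_peak")


def test_rolling_minimum_baseline():
    ds = MSIDataset(
        pixels=np.array([[0, 0]]),
        mass_axis=np.arange(100.0, 110.0, 1.0),
        intensities=(np.arange(10.0) + 1.0)[None, :],
    )
    out = remove_baseline(ds, window_channels=3)
    assert np.all(out.intensities >= 0)
    assert out.intensities[0, 0] == 0.0  # its own rolling minimum
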