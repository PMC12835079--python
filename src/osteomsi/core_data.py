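"""MSI dataset model, imzML/TSV I/O, common-axis resampling, normalization.

A MALDI-MSI acquisition is one mass spectrum per laser position (pixel).
:class:`MSIDataset` holds the spectra either on a shared mass axis
(continuous/resampled data: one ``pixels x channels`` matrix) or as ragged
per-pixel centroid lists (processed-mode imzML), plus integer grid
coordinates and free-form provenance metadata.

Resampling bins every centroid fully into a uniform common axis, so each
pixel's total ion current (TIC) is conserved. Normalization rescales every
pixel so the spike-in reference peptide window ([Glu1]-fibrinopeptide B at
m/z 1570.6768 by default) has unit area, cancelling pixel-to-pixel
multiplicative gain; TIC and RMS normalization are available alternatives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "MSIDataset",
    "read_msi",
    "write_msi",
    "resample_common_axis",
    "normalize_spectra",
    "remove_baseline",
    "drop_flagged",
]


# ---------------------------------------------------------------------------
# dataset model
# ---------------------------------------------------------------------------

@dataclass
class MSIDataset:
    """Pixel-indexed mass spectra with spatial coordinates.

    Exactly one of the two storage forms is populated:

    * common axis — ``mass_axis`` (m/z, strictly increasing) with
      ``intensities`` of shape ``(n_pixels, n_channels)``;
    * ragged — ``spectra``, a list of ``(mz, intensity)`` array pairs,
      one per pixel, each axis strictly increasing.

    Coordinates are 0-based integer grid indices; the physical position is
    ``index * pixel_pitch_um``.
    """

    pixels: np.ndarray
    pixel_pitch_um: float = 50.0
    metadata: dict = field(default_factory=dict)
    mass_axis: np.ndarray | None = None
    intensities: np.ndarray | None = None
    spectra: list[tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must be an (n, 2) array of grid coordinates")
        n = len(self.pixels)
        if len({(int(x), int(y)) for x, y in self.pixels}) != n:
            raise ValueError("duplicate pixel coordinates")
        has_common = self.mass_axis is not None
        if has_common == (self.spectra is not None):
            raise ValueError("provide exactly one of (mass_axis, intensities) or spectra")
        if has_common:
            self.mass_axis = np.asarray(self.mass_axis, dtype=float)
            self.intensities = np.asarray(self.intensities, dtype=float)
            _check_axis(self.mass_axis, "mass_axis")
            if self.intensities.shape != (n, len(self.mass_axis)):
                raise ValueError(
                    f"intensities shape {self.intensities.shape} != "
                    f"({n}, {len(self.mass_axis)})"
                )
            if np.any(self.intensities < 0):
                raise ValueError("negative intensities")
        else:
            if len(self.spectra) != n:
                raise ValueError("one spectrum per pixel required")
            clean = []
            for i, (mz, inten) in enumerate(self.spectra):
                mz = np.asarray(mz, dtype=float)
                inten = np.asarray(inten, dtype=float)
                _check_axis(mz, f"spectrum {i} mass axis")
                if mz.shape != inten.shape:
                    raise ValueError(f"spectrum {i}: mz/intensity length mismatch")
                if np.any(inten < 0):
                    raise ValueError(f"spectrum {i}: negative intensities")
                clean.append((mz, inten))
            self.spectra = clean

    # -- convenience -------------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def has_common_axis(self) -> bool:
        return self.mass_axis is not None

    def pixel_spectrum(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        if self.has_common_axis:
            return self.mass_axis, self.intensities[i]
        return self.spectra[i]

    def tic(self) -> np.ndarray:
        """Per-pixel total ion current."""
        if self.has_common_axis:
            return self.intensities.sum(axis=1)
        return np.array([inten.sum() for _, inten in self.spectra])

    def flagged_pixels(self) -> np.ndarray:
        """Indices of pixels flagged by normalization (empty if none)."""
        return np.asarray(self.metadata.get("flagged_pixels", []), dtype=int)


def _check_axis(mz: np.ndarray, name: str) -> None:
    if mz.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if len(mz) > 1 and np.any(np.diff(mz) <= 0):
        raise ValueError(f"{name} must be strictly increasing")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["x", "y", "mz", "intensity"]


def read_msi(path, format: str | None = None, pixel_pitch_um: float = 50.0) -> MSIDataset:
    """Read an MSI dataset from imzML (+ sidecar .ibd) or the TSV fallback.

    ``format`` is ``"imzml"`` or ``"tsv"``; when omitted it is inferred
    from the file extension. Continuous-mode imzML (and TSV whose pixels
    all share one axis) yields a common-axis dataset; processed-mode
    spectra keep their per-pixel axes until resampling.
    """
    fmt = format or _infer_format(path)
    if fmt == "imzml":
        return _read_imzml(path, pixel_pitch_um)
    if fmt == "tsv":
        return _read_tsv(path, pixel_pitch_um)
    raise ValueError(f"unknown format {fmt!r} (expected 'imzml' or 'tsv')")


def write_msi(dataset: MSIDataset, path, format: str | None = None) -> None:
    """Write a dataset to imzML or TSV, readable back by :func:`read_msi`.

    Coordinates round-trip exactly; intensities to <= 1e-6 relative
    (imzML stores 32-bit floats by default here we force 64-bit, TSV uses
    full repr). Datasets with zero pixels are refused.
    """
    if dataset.n_pixels == 0:
        raise ValueError("refusing to write a dataset with 0 pixels")
    fmt = format or _infer_format(path)
    if fmt == "imzml":
        _write_imzml(dataset, path)
    elif fmt == "tsv":
        _write_tsv(dataset, path)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'imzml' or 'tsv')")


def _infer_format(path) -> str:
    s = str(path).lower()
    if s.endswith(".imzml"):
        return "imzml"
    if s.endswith((".tsv", ".txt")):
        return "tsv"
    raise ValueError(f"cannot infer format from {path!r}; pass format=")


def _read_tsv(path, pixel_pitch_um: float) -> MSIDataset:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed TSV {path}: missing columns {missing}")
    for col in _TSV_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"malformed TSV {path}: non-numeric {col!r} at row {bad}")
    pixels, spectra = [], []
    for (x, y), grp in df.groupby(["x", "y"], sort=False):
        order = np.argsort(grp["mz"].to_numpy())
        pixels.append((int(x), int(y)))
        spectra.append((grp["mz"].to_numpy()[order], grp["intensity"].to_numpy()[order]))
    return _from_possibly_shared(pixels, spectra, pixel_pitch_um, {"source": str(path)})


def _write_tsv(dataset: MSIDataset, path) -> None:
    rows = []
    for i, (x, y) in enumerate(dataset.pixels):
        mz, inten = dataset.pixel_spectrum(i)
        rows.append(
            pd.DataFrame(
                {"x": int(x), "y": int(y), "mz": mz, "intensity": inten}
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def _read_imzml(path, pixel_pitch_um: float) -> MSIDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:
        raise ValueError(f"malformed imzML {path}: {exc}") from exc
    pixels, spectra = [], []
    for i, coord in enumerate(parser.coordinates):
        x, y = int(coord[0]) - 1, int(coord[1]) - 1  # imzML is 1-based
        mz, inten = parser.getspectrum(i)
        pixels.append((x, y))
        spectra.append((np.asarray(mz, float), np.asarray(inten, float)))
    if len({p for p in pixels}) != len(pixels):
        raise ValueError(f"malformed imzML {path}: duplicate pixel coordinate")
    return _from_possibly_shared(pixels, spectra, pixel_pitch_um, {"source": str(path)})


def _write_imzml(dataset: MSIDataset, path) -> None:
    from pyimzml.ImzMLWriter import ImzMLWriter

    mode = "continuous" if dataset.has_common_axis else "processed"
    with ImzMLWriter(
        str(path), mode=mode, mz_dtype=np.float64, intensity_dtype=np.float64
    ) as writer:
        for i, (x, y) in enumerate(dataset.pixels):
            mz, inten = dataset.pixel_spectrum(i)
            writer.addSpectrum(mz, inten, (int(x) + 1, int(y) + 1))


def _from_possibly_shared(pixels, spectra, pixel_pitch_um, metadata) -> MSIDataset:
    first_mz = spectra[0][0]
    shared = all(
        len(mz) == len(first_mz) and np.array_equal(mz, first_mz) for mz, _ in spectra
    )
    if shared:
        return MSIDataset(
            pixels=np.array(pixels),
            pixel_pitch_um=pixel_pitch_um,
            metadata=metadata,
            mass_axis=first_mz.copy(),
            intensities=np.vstack([inten for _, inten in spectra]),
        )
    return MSIDataset(
        pixels=np.array(pixels),
        pixel_pitch_um=pixel_pitch_um,
        metadata=metadata,
        spectra=spectra,
    )


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_common_axis(
    datasets: list[MSIDataset], bin_width_da: float
) -> list[MSIDataset]:
    """Rebin every dataset onto one shared uniform mass axis.

    Bins are half-open ``[lo, lo + w)`` spanning the union of all input
    ranges; each centroid's intensity is assigned in full to the bin
    containing its m/z (a mass exactly on an interior boundary goes to the
    upper bin), so per-pixel TIC is conserved. The output axis holds bin
    centers.
    """
    if bin_width_da <= 0:
        raise ValueError("bin_width_da must be positive")
    if not datasets:
        raise ValueError("no datasets to resample")
    lo = math.inf
    hi = -math.inf
    for ds in datasets:
        for i in range(ds.n_pixels):
            mz, _ = ds.pixel_spectrum(i)
            if len(mz):
                lo = min(lo, mz[0])
                hi = max(hi, mz[-1])
    if not math.isfinite(lo):
        raise ValueError("empty union mass range: no channels in any dataset")
    n_bins = max(1, math.ceil((hi - lo) / bin_width_da))
    if lo + n_bins * bin_width_da <= hi:  # guard float edge
        n_bins += 1
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width_da

    out = []
    for ds in datasets:
        binned = np.zeros((ds.n_pixels, n_bins))
        for i in range(ds.n_pixels):
            mz, inten = ds.pixel_spectrum(i)
            if not len(mz):
                continue
            idx = np.floor((mz - lo) / bin_width_da).astype(int)
            np.clip(idx, 0, n_bins - 1, out=idx)  # hi itself closes the last bin
            np.add.at(binned[i], idx, inten)
        meta = dict(ds.metadata)
        meta["resampled_bin_width_da"] = bin_width_da
        out.append(
            MSIDataset(
                pixels=ds.pixels.copy(),
                pixel_pitch_um=ds.pixel_pitch_um,
                metadata=meta,
                mass_axis=centers.copy(),
                intensities=binned,
            )
        )
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

#: Pixels whose reference window area is below this multiple of the median
#: window area are considered to be missing the spike-in peak.
REF_FLOOR_FRACTION = 1e-3


def normalize_spectra(
    dataset: MSIDataset, method: str = "reference_peak", config: PipelineConfig | None = None
) -> MSIDataset:
    """Rescale every pixel's spectrum by a per-pixel factor.

    ``reference_peak`` divides by the summed intensity inside
    ``[ref_mz - w, ref_mz + w]`` so the spike-in peak has unit area —
    exactly cancelling any per-pixel multiplicative gain. ``tic`` and
    ``rms`` scale to unit total ion current / unit root-mean-square.

    Pixels whose reference window area falls below
    ``REF_FLOOR_FRACTION x median`` (spike-in absent) are left unscaled,
    flagged in ``metadata['flagged_pixels']`` and counted in
    ``metadata['n_flagged']``; downstream statistics exclude them via
    :func:`drop_flagged`.
    """
    config = config or PipelineConfig()
    n = dataset.n_pixels
    if n == 0:
        raise ValueError("empty dataset")

    if method == "reference_peak":
        lo_w = config.ref_mz - config.ref_window_da
        hi_w = config.ref_mz + config.ref_window_da
        axis_lo, axis_hi = _axis_range(dataset)
        if not (axis_lo <= config.ref_mz <= axis_hi):
            raise ValueError(
                f"reference m/z {config.ref_mz} outside mass axis "
                f"[{axis_lo}, {axis_hi}]"
            )
        denom = np.array(
            [_window_area(dataset, i, lo_w, hi_w) for i in range(n)]
        )
        floor = REF_FLOOR_FRACTION * np.median(denom)
        flagged = denom < max(floor, 0.0)
        if np.all(flagged) or np.median(denom) <= 0:
            raise ValueError("all pixels lack the reference peak")
    elif method == "tic":
        denom = dataset.tic()
        flagged = denom <= 0
    elif method == "rms":
        denom = np.array(
            [
                math.sqrt(np.mean(np.square(dataset.pixel_spectrum(i)[1])))
                if len(dataset.pixel_spectrum(i)[1])
                else 0.0
                for i in range(n)
            ]
        )
        flagged = denom <= 0
    else:
        raise ValueError(f"unknown normalization method {method!r}")

    scale = np.ones(n)
    ok = ~flagged
    scale[ok] = 1.0 / denom[ok]

    meta = dict(dataset.metadata)
    meta["normalization"] = method
    meta["flagged_pixels"] = np.flatnonzero(flagged).tolist()
    meta["n_flagged"] = int(flagged.sum())

    if dataset.has_common_axis:
        return MSIDataset(
            pixels=dataset.pixels.copy(),
            pixel_pitch_um=dataset.pixel_pitch_um,
            metadata=meta,
            mass_axis=dataset.mass_axis.copy(),
            intensities=dataset.intensities * scale[:, None],
        )
    spectra = [
        (mz.copy(), inten * scale[i])
        for i, (mz, inten) in enumerate(dataset.spectra)
    ]
    return MSIDataset(
        pixels=dataset.pixels.copy(),
        pixel_pitch_um=dataset.pixel_pitch_um,
        metadata=meta,
        spectra=spectra,
    )


def _axis_range(dataset: MSIDataset) -> tuple[float, float]:
    if dataset.has_common_axis:
        return float(dataset.mass_axis[0]), float(dataset.mass_axis[-1])
    lo = min(mz[0] for mz, _ in dataset.spectra if len(mz))
    hi = max(mz[-1] for mz, _ in dataset.spectra if len(mz))
    return float(lo), float(hi)


def _window_area(dataset: MSIDataset, i: int, lo: float, hi: float) -> float:
    mz, inten = dataset.pixel_spectrum(i)
    if not len(mz):
        return 0.0
    sel = (mz >= lo) & (mz <= hi)
    return float(inten[sel].sum())


def remove_baseline(dataset: MSIDataset, window_channels: int = 101) -> MSIDataset:
    """Optional rolling-minimum baseline subtraction (off by default).

    Subtracts, per pixel, the running minimum over ``window_channels``
    channels. Vendor preprocessing applies an undocumented background
    step at import; this is an explicit, reproducible stand-alone
    alternative for profile-like data and is never applied implicitly.
    """
    from scipy.ndimage import minimum_filter1d

    if not dataset.has_common_axis:
        raise ValueError("baseline removal requires a common mass axis")
    baseline = minimum_filter1d(dataset.intensities, size=window_channels, axis=1, mode="nearest")
    meta = dict(dataset.metadata)
    meta["baseline"] = f"rolling_min_{window_channels}"
    return MSIDataset(
        pixels=dataset.pixels.copy(),
        pixel_pitch_um=dataset.pixel_pitch_um,
        metadata=meta,
        mass_axis=dataset.mass_axis.copy(),
        intensities=dataset.intensities - baseline,
    )


def drop_flagged(dataset: MSIDataset) -> MSIDataset:
    """Return the dataset without normalization-flagged pixels."""
    flagged = set(dataset.flagged_pixels().tolist())
    if not flagged:
        return dataset
    keep = np.array([i for i in range(dataset.n_pixels) if i not in flagged])
    meta = dict(dataset.metadata)
    meta["flagged_pixels"] = []
    meta["n_dropped"] = len(flagged)
    if dataset.has_common_axis:
        return MSIDataset(
            pixels=dataset.pixels[keep],
            pixel_pitch_um=dataset.pixel_pitch_um,
            metadata=meta,
            mass_axis=dataset.mass_axis.copy(),
            intensities=dataset.intensities[keep],
        )
    return MSIDataset(
        pixels=dataset.pixels[keep],
        pixel_pitch_um=dataset.pixel_pitch_um,
        metadata=meta,
        spectra=[dataset.spectra[i] for i in keep],
    )
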