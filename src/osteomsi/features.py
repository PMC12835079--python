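"""Mean-spectrum peak picking, top-N selection, pixels x features matrix.

The feature filter works on the cohort/tissue mean spectrum: strict local
maxima with a relative prominence floor are picked, the N most abundant
(by mean-spectrum height) are kept, and a ``pixels x features`` intensity
matrix is built by summing each pixel's intensity inside a small window
around every feature apex. All downstream statistics (segmentation,
AUROC screening, ROI means) run on this matrix.

Hotspot clipping caps the *display* scale of a feature image at a high
quantile (the paper-standard 99th); stored values are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema, peak_prominences

from .core_data import MSIDataset

__all__ = [
    "AverageSpectrum",
    "FeatureSet",
    "FeatureTable",
    "IntensityImage",
    "mean_spectrum",
    "pick_peaks",
    "centroid_peaks",
    "spectrum_peaks",
    "select_top_n",
    "merge_feature_sets",
    "extract_feature_table",
    "feature_image",
]


@dataclass
class AverageSpectrum:
    """Channel-wise mean over all pixels of a common-axis dataset."""

    mass_axis: np.ndarray
    mean_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mass_axis = np.asarray(self.mass_axis, float)
        self.mean_intensity = np.asarray(self.mean_intensity, float)
        if self.mass_axis.shape != self.mean_intensity.shape:
            raise ValueError("mass_axis and mean_intensity lengths differ")
        if np.any(self.mean_intensity < 0):
            raise ValueError("negative mean intensity")


@dataclass
class FeatureSet:
    """Selected m/z features: ``(mz_center, window_da, rank)`` triples.

    Rank 1 is the most abundant feature (mean-spectrum height), ties
    broken by lower m/z.
    """

    features: list[tuple[float, float, int]]

    def __post_init__(self) -> None:
        centers = [f[0] for f in self.features]
        if len(set(centers)) != len(centers):
            raise ValueError("duplicate feature mz_center")
        ranks = sorted(f[2] for f in self.features)
        if ranks != list(range(1, len(self.features) + 1)):
            raise ValueError("ranks must be a permutation of 1..N")

    @property
    def mz_centers(self) -> np.ndarray:
        return np.array([f[0] for f in self.features])

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class FeatureTable:
    """Pixels x features intensity matrix, the unit all statistics run on."""

    pixels: np.ndarray
    features: FeatureSet
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, int)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.pixels), len(self.features)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.pixels)}, {len(self.features)})"
            )
        if np.any(self.values < 0):
            raise ValueError("negative feature values")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def feature_index(self, mz: float, atol: float = 1e-9) -> int:
        centers = self.features.mz_centers
        hits = np.flatnonzero(np.isclose(centers, mz, rtol=0.0, atol=atol))
        if len(hits) == 0:
            raise KeyError(f"no feature at m/z {mz}")
        return int(hits[0])

    def column(self, mz: float) -> np.ndarray:
        return self.values[:, self.feature_index(mz)]

    def to_frame(self):
        import pandas as pd

        cols = {f"{c:.4f}": self.values[:, j] for j, c in enumerate(self.features.mz_centers)}
        return pd.DataFrame({"x": self.pixels[:, 0], "y": self.pixels[:, 1], **cols})


@dataclass
class IntensityImage:
    """2-D feature image with a display cap; off-tissue pixels are NaN."""

    image: np.ndarray
    display_cap: float
    mz: float

    def rendered(self) -> np.ndarray:
        """Image clipped to the display cap (rendering only)."""
        return np.clip(self.image, None, self.display_cap)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def mean_spectrum(dataset: MSIDataset) -> AverageSpectrum:
    """Arithmetic mean spectrum over all pixels (common axis required)."""
    if dataset.n_pixels == 0:
        raise ValueError("empty dataset")
    if not dataset.has_common_axis:
        raise ValueError("mean spectrum requires a common mass axis; resample first")
    return AverageSpectrum(dataset.mass_axis.copy(), dataset.intensities.mean(axis=0))


def pick_peaks(
    spectrum: AverageSpectrum, min_prominence: float = 1e-4
) -> list[tuple[float, float]]:
    """Strict local maxima of the mean spectrum, prominence-filtered.

    Returns ``(mz, height)`` pairs sorted by m/z for every strict local
    maximum whose topographic prominence is at least
    ``min_prominence * max(mean_intensity)``.
    """
    y = spectrum.mean_intensity
    if len(y) == 0:
        return []
    if len(y) < 3 or y.max() <= 0:
        return []
    idx = argrelextrema(y, np.greater)[0]  # strict: > both neighbours
    if len(idx) == 0:
        return []
    prom = peak_prominences(y, idx)[0]
    floor = min_prominence * y.max()
    keep = idx[prom >= floor]
    return [(float(spectrum.mass_axis[i]), float(y[i])) for i in keep]


def centroid_peaks(spectrum: AverageSpectrum) -> list[tuple[float, float]]:
    """Every non-zero channel of an already-centroided spectrum as a peak.

    Centroided data stores one channel per detected ion species, so local
    maxima are meaningless there; the channel heights themselves are the
    peak list.
    """
    nz = np.flatnonzero(spectrum.mean_intensity > 0)
    return [(float(spectrum.mass_axis[i]), float(spectrum.mean_intensity[i])) for i in nz]


def spectrum_peaks(
    spectrum: AverageSpectrum,
    centroided: bool | None = None,
    min_prominence: float = 1e-4,
) -> list[tuple[float, float]]:
    """Peak list for either profile or centroided mean spectra.

    With ``centroided=None`` the mode is inferred from channel spacing:
    a median gap above 0.5 Da means one channel per ion species
    (centroided); a fine uniform axis means profile data, picked by
    :func:`pick_peaks`.
    """
    if centroided is None:
        gaps = np.diff(spectrum.mass_axis)
        centroided = len(gaps) == 0 or float(np.median(gaps)) > 0.5
    if centroided:
        return centroid_peaks(spectrum)
    return pick_peaks(spectrum, min_prominence=min_prominence)


def select_top_n(peaks: list[tuple[float, float]], n: int) -> FeatureSet:
    """Keep the ``n`` tallest peaks, ranked; ties broken by lower m/z."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(peaks, key=lambda p: (-p[1], p[0]))[:n]
    return FeatureSet([(mz, 0.1, rank) for rank, (mz, _h) in enumerate(ordered, start=1)])


def merge_feature_sets(sets: list[FeatureSet], window_da: float = 0.1) -> FeatureSet:
    """Union of per-tissue feature sets, deduplicated at 2x window width.

    When several tissues are co-analysed, each contributes its own top-N;
    centers closer than ``2 * window_da`` to an already-kept center are
    treated as the same feature. Kept features are re-ranked by the best
    (lowest) rank they held in any input set.
    """
    pool: list[tuple[float, int]] = []
    for fs in sets:
        pool.extend((mz, rank) for mz, _w, rank in fs.features)
    pool.sort(key=lambda t: (t[1], t[0]))
    kept: list[tuple[float, int]] = []
    for mz, rank in pool:
        if all(abs(mz - k) >= 2 * window_da for k, _ in kept):
            kept.append((mz, rank))
    kept.sort(key=lambda t: (t[1], t[0]))
    return FeatureSet(
        [(mz, window_da, new_rank) for new_rank, (mz, _r) in enumerate(kept, start=1)]
    )


def extract_feature_table(
    dataset: MSIDataset, features: FeatureSet, window_da: float = 0.1
) -> FeatureTable:
    """Sum each pixel's intensity within ``mz_center +/- window_da`` per feature.

    Windows may overlap (overlaps are counted and recorded in provenance).
    A feature center outside the dataset's mass range is an error.
    """
    if not dataset.has_common_axis:
        raise ValueError("feature extraction requires a common mass axis")
    axis = dataset.mass_axis
    centers = features.mz_centers
    out_of_range = (centers < axis[0]) | (centers > axis[-1])
    if np.any(out_of_range):
        bad = centers[out_of_range][0]
        raise ValueError(f"feature center m/z {bad} outside mass axis range")

    n_overlaps = 0
    cols = np.empty((dataset.n_pixels, len(centers)))
    prev_hi = -np.inf
    for j, c in enumerate(np.sort(centers)):
        if c - window_da < prev_hi:
            n_overlaps += 1
        prev_hi = c + window_da
    for j, c in enumerate(centers):
        lo = np.searchsorted(axis, c - window_da, side="left")
        hi = np.searchsorted(axis, c + window_da, side="right")
        cols[:, j] = dataset.intensities[:, lo:hi].sum(axis=1)

    return FeatureTable(
        pixels=dataset.pixels.copy(),
        features=features,
        values=cols,
        provenance={
            "sample_id": dataset.metadata.get("sample_id"),
            "normalization": dataset.metadata.get("normalization"),
            "window_da": window_da,
            "n_overlapping_windows": n_overlaps,
        },
    )


def write_feature_table_tsv(table: FeatureTable, path) -> None:
    """Write the table as TSV: ``x  y  <mz1> ... <mzN>`` per pixel."""
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table_tsv(path) -> FeatureTable:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    mz_cols = [c for c in df.columns if c not in ("x", "y")]
    fs = FeatureSet([(float(c), 0.1, j + 1) for j, c in enumerate(mz_cols)])
    return FeatureTable(
        pixels=df[["x", "y"]].to_numpy(),
        features=fs,
        values=df[mz_cols].to_numpy(float),
        provenance={"source": str(path)},
    )


def export_feature_image(
    image: IntensityImage, png_path=None, matrix_path=None
) -> None:
    """Save a feature image as a rendered PNG and/or plain-text matrix.

    The PNG uses the hotspot-clipped rendering; the text matrix stores
    the unclipped values (NaN for off-tissue pixels).
    """
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        plt.imsave(
            png_path,
            np.nan_to_num(image.rendered(), nan=0.0),
            vmin=0.0,
            vmax=image.display_cap if image.display_cap > 0 else None,
            cmap="viridis",
            origin="lower",
        )
    if matrix_path is not None:
        np.savetxt(matrix_path, image.image, fmt="%.10g", delimiter="\t")


def feature_image(
    table: FeatureTable, mz: float, clip_quantile: float = 0.99
) -> IntensityImage:
    """Feature intensity on the pixel grid with a hotspot display cap.

    The cap is the ``clip_quantile`` quantile of the feature's pixel
    values; the stored matrix is untouched, so statistics computed from
    the table are unaffected by clipping.
    """
    j = table.feature_index(mz)
    vals = table.values[:, j]
    xs, ys = table.pixels[:, 0], table.pixels[:, 1]
    img = np.full((ys.max() + 1, xs.max() + 1), np.nan)
    img[ys, xs] = vals
    cap = float(np.quantile(vals, clip_quantile))
    return IntensityImage(image=img, display_cap=cap, mz=float(table.features.mz_centers[j]))
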