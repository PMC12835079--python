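"""Ground-truthed synthetic MSI cohorts for end-to-end pipeline testing.

The phantom emulates an osteochondral tissue section: a cartilage band at
the articular surface, a thin transitional (osteochondral-junction) layer,
and below it a trabecular bone network embedded in marrow space, generated
by thresholding smoothed Gaussian noise so bone pixels form connected
strands a few pixels wide (trabeculae are ~200 um across, i.e. 5-10 pixels
at 20-40 um pitch). Diseased sections carry a wedge of diseased bone
confined to one lateral edge of the bone area, mimicking subchondral
sclerosis beneath the region of cartilage loss.

The measurement model per pixel and feature is

    intensity = gain(pixel) * LogNormal(region mean, biological CV) + floor

with ``gain ~ LogNormal(mean 1, gain_cv)`` shared across a pixel's whole
spectrum — exactly the error structure spike-in reference normalization
removes. The spike-in channel (GluFib, m/z 1570.6768) carries only gain
(plus optional dropout), so reference normalization cancels gain exactly.
Log-normal biological variation makes every per-region intensity
distribution right-skewed, matching the rationale for one-sided cohort
tests. Null features share one global mean across regions.

Markers are real collagen-domain peptides placed at their true
monoisotopic [M+H]+, including hydroxyproline-modified forms elevated in
diseased bone, so the annotation stage can be exercised against a library
built from the same entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .annotation import MOD_DELTA, PeptideEntry, SpectralLibrary, peptide_mz
from .config import GLUFIB_MZ
from .core_data import MSIDataset

__all__ = [
    "REGIONS",
    "PhantomSpec",
    "Marker",
    "MarkerConfig",
    "GroundTruth",
    "make_phantom",
    "simulate_dataset",
    "simulate_cohort",
    "simulate_paired_cohort_means",
    "default_markers",
    "default_library",
    "lognormal_auroc",
]

REGIONS = ["cartilage", "transitional", "healthy_bone", "diseased_bone", "marrow"]


@dataclass
class PhantomSpec:
    """Geometry of the synthetic tissue section.

    Fractions are target area shares per region and must sum to 1; the
    realized shares differ by at most a pixel row / threshold quantum.
    """

    grid: tuple[int, int] = (120, 80)          # (width, height)
    pixel_pitch_um: float = 40.0
    fractions: dict = field(
        default_factory=lambda: {
            "cartilage": 0.15,
            "transitional": 0.05,
            "healthy_bone": 0.30,
            "diseased_bone": 0.10,
            "marrow": 0.40,
        }
    )
    trabecular_sigma_px: float = 2.5           # smoothing of the bone network field

    def __post_init__(self) -> None:
        missing = set(REGIONS) - set(self.fractions)
        if missing:
            raise ValueError(f"fractions missing regions {sorted(missing)}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("fractions must be >= 0")


@dataclass
class Marker:
    """A planted feature: its m/z, optional peptide identity and profile.

    ``region_profile`` maps region name -> multiplier on
    ``base_intensity``; the true mean of the feature in a region is
    ``base_intensity * multiplier``.
    """

    mz: float
    base_intensity: float
    region_profile: dict
    peptide: PeptideEntry | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.region_profile.values()):
            raise ValueError("region multipliers (fold-changes) must be > 0")

    def region_mean(self, region: str) -> float:
        return self.base_intensity * self.region_profile.get(region, 1.0)


@dataclass
class MarkerConfig:
    markers: list = field(default_factory=lambda: default_markers())
    n_null_features: int = 490
    null_mean: float = 1.0
    noise_cv: float = 0.2                # biological log-normal CV
    additive_floor: float = 0.01         # exponential-noise scale, adds >= 0
    gain_cv: float = 0.3                 # per-pixel multiplicative gain spread
    ref_mz: float = GLUFIB_MZ
    ref_intensity: float = 50.0
    ref_dropout: float = 0.0             # fraction of pixels missing the spike-in
    mz_range: tuple[float, float] = (800.0, 1800.0)
    axis_seed: int | None = None         # fixes the null-channel layout across sections

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.gain_cv < 0:
            raise ValueError("CVs must be >= 0")
        if not (0.0 <= self.ref_dropout < 1.0):
            raise ValueError("ref_dropout must be in [0, 1)")


@dataclass
class GroundTruth:
    """Everything a test oracle needs about one simulated section."""

    region_labels: np.ndarray            # per-pixel region index into region_names
    region_names: list[str]
    feature_mz: np.ndarray               # all feature channels except the spike-in
    region_means: np.ndarray             # n_regions x n_features true means
    planted: list                        # Marker objects actually planted
    ref_mz: float
    ref_dropout_pixels: np.ndarray       # indices of pixels missing the spike-in
    noise_cv: float
    cohort: dict = field(default_factory=dict)  # sample id, group, side, pairing

    def region_mask(self, region: str) -> np.ndarray:
        return self.region_labels == self.region_names.index(region)

    def true_auroc(self, mz: float, region_a: str, region_b: str) -> float:
        """Closed-form pixel AUROC of one feature between two regions.

        For log-normal intensities with shared log-space sigma the AUROC
        is ``Phi(ln(mu_A / mu_B) / (sigma * sqrt(2)))``; the additive
        noise floor is ignored (it is small by construction).
        """
        j = int(np.argmin(np.abs(self.feature_mz - mz)))
        ia = self.region_names.index(region_a)
        ib = self.region_names.index(region_b)
        return lognormal_auroc(
            self.region_means[ia, j], self.region_means[ib, j], self.noise_cv
        )


def lognormal_auroc(mean_a: float, mean_b: float, cv: float) -> float:
    """P(X_A > X_B) for independent log-normals with equal CV."""
    if cv == 0:
        return 1.0 if mean_a > mean_b else (0.0 if mean_a < mean_b else 0.5)
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(norm.cdf(math.log(mean_a / mean_b) / (sigma * math.sqrt(2.0))))


# ---------------------------------------------------------------------------
# default markers: real collagen-domain peptides at their true [M+H]+
# ---------------------------------------------------------------------------

def _entry(protein, seq, mods=()):
    return PeptideEntry(protein=protein, sequence=seq, mods=list(mods))


def default_markers() -> list[Marker]:
    """Region-specific marker panel used by the default phantom.

    Cartilage carries type-II collagen peptides, bone type-I collagen,
    the transitional layer a type-III collagen peptide, marrow a
    hemoglobin peptide, and diseased bone hydroxyproline-modified type-I
    collagen peptides elevated ~3-fold over healthy bone.
    """
    lo = 0.2  # background multiplier outside the marker's home regions
    cartilage = [
        _entry("COL2A1", "GPQGLAGQR"),
        _entry("COL2A1", "GPSGEPGKQGAP"),
    ]
    bone = [
        _entry("COL1A1", "GPAGARGNDGATGAA"),
        _entry("COL1A1", "GPAGERGEQ"),
    ]
    transitional = [_entry("COL3A1", "GQRGEPGPQ", [("unlocalized", "HYP")])]
    marrow = [_entry("HBA1", "VLSPADKTNVK")]
    diseased = [
        _entry("COL1A1", "IAGQRGVVGLP", [(11, "HYP")]),
        _entry("COL1A1", "GKPGEQGVPGDLGAP", [(3, "HYP"), (9, "HYP"), (15, "HYP")]),
        _entry("COL1A1", "GKPGEQGVPGDLGAP", [(3, "HYP"), (15, "HYP")]),
        _entry("COL1A1", "GLPGERGRPGAP", [(3, "HYP"), (9, "HYP"), ("unlocalized", "HYP")]),
    ]

    markers = []
    for e in cartilage:
        markers.append(
            Marker(
                mz=e.theoretical_mh,
                base_intensity=1.0,
                region_profile={
                    "cartilage": 8.0, "transitional": 2.0,
                    "healthy_bone": lo, "diseased_bone": lo, "marrow": lo,
                },
                peptide=e,
                name=e.label(),
            )
        )
    for e in bone:
        markers.append(
            Marker(
                mz=e.theoretical_mh,
                base_intensity=1.0,
                region_profile={
                    "cartilage": lo, "transitional": 2.0,
                    "healthy_bone": 8.0, "diseased_bone": 6.0, "marrow": lo,
                },
                peptide=e,
                name=e.label(),
            )
        )
    for e in transitional:
        markers.append(
            Marker(
                mz=e.theoretical_mh,
                base_intensity=1.0,
                region_profile={
                    "cartilage": 1.5, "transitional": 8.0,
                    "healthy_bone": 1.5, "diseased_bone": 1.5, "marrow": lo,
                },
                peptide=e,
                name=e.label(),
            )
        )
    for e in marrow:
        markers.append(
            Marker(
                mz=e.theoretical_mh,
                base_intensity=1.0,
                region_profile={
                    "cartilage": lo, "transitional": lo,
                    "healthy_bone": lo, "diseased_bone": lo, "marrow": 6.0,
                },
                peptide=e,
                name=e.label(),
            )
        )
    for e in diseased:
        markers.append(
            Marker(
                mz=e.theoretical_mh,
                base_intensity=1.0,
                region_profile={
                    "cartilage": lo, "transitional": 1.0,
                    "healthy_bone": 3.0, "diseased_bone": 9.0, "marrow": lo,
                },
                peptide=e,
                name=e.label(),
            )
        )
    return markers


def default_library(extra_decoys: int = 20, seed: int = 12345) -> SpectralLibrary:
    """Spectral library holding the planted peptides plus decoy entries.

    Decoys are random glycine/proline-rich tripeptide-repeat sequences
    (collagen-like) that do not collide with any planted mass within
    5 mDa, so planted features annotate uniquely at a 2 mDa tolerance.
    """
    entries = [m.peptide for m in default_markers() if m.peptide is not None]
    entries.append(_entry("GluFib", "EGVNDNEEGFFSAR"))
    planted_masses = np.array([e.theoretical_mh for e in entries])
    rng = np.random.default_rng(seed)
    residues = "GAPSVLEDKRQNT"
    made = 0
    while made < extra_decoys:
        length = int(rng.integers(8, 16))
        seq = "".join(rng.choice(list(residues), size=length))
        try:
            mh = peptide_mz(seq)
        except ValueError:  # pragma: no cover
            continue
        if np.min(np.abs(planted_masses - mh)) > 0.005:
            entries.append(_entry("DECOY", seq))
            planted_masses = np.append(planted_masses, mh)
            made += 1
    return SpectralLibrary(entries=entries, provenance="synthetic default library")


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def make_phantom(
    spec: PhantomSpec | None = None, seed: int = 0, diseased: bool = True
) -> GroundTruth:
    """Generate the per-pixel region map of one synthetic section.

    Cartilage occupies a band at the top of the grid, the transitional
    layer a thin band below it, and the remaining rows hold the
    trabecular bone network (thresholded smoothed noise) in marrow
    space. With ``diseased=True`` the bone pixels on the left edge of
    the bone area are relabelled as the diseased wedge until its target
    area share is met; with ``diseased=False`` the wedge share is folded
    into healthy bone (a lateral or control section).

    Deterministic per seed. The returned :class:`GroundTruth` carries
    only geometry; :func:`simulate_dataset` fills in the intensity model.
    """
    spec = spec or PhantomSpec()
    width, height = spec.grid
    f = dict(spec.fractions)
    if not diseased:
        f["healthy_bone"] = f["healthy_bone"] + f["diseased_bone"]
        f["diseased_bone"] = 0.0

    n_rows_cart = int(round(f["cartilage"] * height))
    n_rows_trans = int(round(f["transitional"] * height))
    for name, rows in (("cartilage", n_rows_cart), ("transitional", n_rows_trans)):
        if f[name] > 0 and rows == 0:
            raise ValueError(f"grid too small: {name} fraction {f[name]} yields 0 rows")
    bone_area_rows = height - n_rows_cart - n_rows_trans
    bone_area_frac = 1.0 - f["cartilage"] - f["transitional"]
    if bone_area_frac > 1e-9 and bone_area_rows <= 0:
        raise ValueError("grid too small for the bone/marrow area")

    labels = np.empty((height, width), dtype=int)
    idx = {name: i for i, name in enumerate(REGIONS)}
    labels[:n_rows_cart, :] = idx["cartilage"]
    labels[n_rows_cart : n_rows_cart + n_rows_trans, :] = idx["transitional"]

    rng = np.random.default_rng(seed)
    if bone_area_rows > 0:
        bone_frac = (f["healthy_bone"] + f["diseased_bone"]) / max(bone_area_frac, 1e-12)
        field_ = gaussian_filter(
            rng.standard_normal((bone_area_rows, width)), sigma=spec.trabecular_sigma_px
        )
        if bone_frac >= 1.0:
            bone = np.ones_like(field_, dtype=bool)
        elif bone_frac <= 0.0:
            bone = np.zeros_like(field_, dtype=bool)
        else:
            thr = np.quantile(field_, 1.0 - bone_frac)
            bone = field_ > thr
        sub = np.where(bone, idx["healthy_bone"], idx["marrow"])
        if diseased and f["diseased_bone"] > 0:
            target = f["diseased_bone"] / max(bone_area_frac, 1e-12) * bone.size
            col_counts = bone.sum(axis=0)
            cum = np.cumsum(col_counts)
            cut = int(np.searchsorted(cum, target) + 1)
            cut = min(cut, width)
            wedge = np.zeros_like(bone)
            wedge[:, :cut] = bone[:, :cut]
            sub[wedge] = idx["diseased_bone"]
        labels[n_rows_cart + n_rows_trans :, :] = sub

    present = [REGIONS[i] for i in np.unique(labels)]
    for name, frac in f.items():
        if frac > 0.02 and name not in present:
            raise ValueError(f"grid too small: region {name!r} received no pixels")

    return GroundTruth(
        region_labels=labels.ravel(),
        region_names=list(REGIONS),
        feature_mz=np.array([]),
        region_means=np.empty((len(REGIONS), 0)),
        planted=[],
        ref_mz=GLUFIB_MZ,
        ref_dropout_pixels=np.array([], dtype=int),
        noise_cv=0.0,
        cohort={"grid": (width, height), "pixel_pitch_um": spec.pixel_pitch_um},
    )


# ---------------------------------------------------------------------------
# intensity simulation
# ---------------------------------------------------------------------------

def _lognormal_field(rng, mean, cv, shape):
    """Log-normal draws with expectation ``mean`` and coefficient of variation ``cv``."""
    if cv == 0:
        return np.broadcast_to(mean, shape).copy()
    sigma2 = math.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, math.sqrt(sigma2), size=shape))


def simulate_dataset(
    truth: GroundTruth,
    markers: MarkerConfig | None = None,
    seed: int = 0,
    profile_mode: bool = False,
    profile_sigma_da: float = 0.03,
    profile_bin_da: float = 0.02,
) -> tuple[MSIDataset, GroundTruth]:
    """Simulate centroided spectra for every pixel of a phantom.

    Channels are the planted markers at their true monoisotopic [M+H]+,
    ``n_null_features`` null channels at random m/z (one global mean
    across regions), and the spike-in reference channel. With
    ``profile_mode=True`` every channel is rendered as a Gaussian peak
    on a fine uniform axis instead (to exercise peak picking); the area
    under each peak equals the centroid intensity.
    """
    markers = markers or MarkerConfig()
    rng = np.random.default_rng(seed)
    n_pix = len(truth.region_labels)
    width, height = truth.cohort.get("grid", (0, 0))
    if width * height != n_pix:
        raise ValueError("truth grid does not match region label count")

    planted = list(markers.markers)
    lo_mz, hi_mz = markers.mz_range
    for m in planted:
        if not (lo_mz <= m.mz <= hi_mz):
            raise ValueError(f"marker m/z {m.mz} outside axis range {markers.mz_range}")
    if not (lo_mz <= markers.ref_mz <= hi_mz):
        raise ValueError("reference m/z outside axis range")

    # null channels on a jittered grid, kept >= 0.5 Da from every planted mass;
    # the layout is shared across a cohort's sections via axis_seed
    reserved = np.array([m.mz for m in planted] + [markers.ref_mz])
    n_grid = markers.n_null_features + len(reserved) + 10
    spacing = (hi_mz - lo_mz - 2.0) / n_grid
    if spacing < 1.3:
        raise ValueError(
            f"mz_range too narrow for {markers.n_null_features} null features"
        )
    axis_rng = (
        rng if markers.axis_seed is None
        else np.random.default_rng(markers.axis_seed)
    )
    grid = lo_mz + 1.0 + np.arange(n_grid) * spacing + axis_rng.uniform(-0.4, 0.4, n_grid)
    keep = np.array([np.min(np.abs(reserved - v)) > 0.5 for v in grid])
    null_mz = np.sort(grid[keep][: markers.n_null_features])
    if len(null_mz) < markers.n_null_features:
        raise ValueError("could not place the requested number of null features")

    feature_mz = np.concatenate([[m.mz for m in planted], null_mz])
    order = np.argsort(feature_mz)

    n_regions = len(truth.region_names)
    region_means = np.empty((n_regions, len(feature_mz)))
    for r, rname in enumerate(truth.region_names):
        for j, m in enumerate(planted):
            region_means[r, j] = m.region_mean(rname)
        region_means[r, len(planted):] = markers.null_mean

    # per-pixel biological draws
    means_per_pixel = region_means[truth.region_labels]          # n_pix x n_feat
    values = _lognormal_field(rng, means_per_pixel, markers.noise_cv, means_per_pixel.shape)
    if markers.additive_floor > 0:
        values = values + rng.exponential(markers.additive_floor, size=values.shape)
    gain = _lognormal_field(rng, 1.0, markers.gain_cv, (n_pix, 1))
    values = values * gain

    ref = np.full(n_pix, markers.ref_intensity) * gain[:, 0]
    if markers.ref_dropout > 0:
        drop = rng.random(n_pix) < markers.ref_dropout
        ref[drop] = 0.0
        dropout_idx = np.flatnonzero(drop)
    else:
        dropout_idx = np.array([], dtype=int)

    # assemble channels sorted by m/z, spike-in inserted in place
    feat_sorted = feature_mz[order]
    vals_sorted = values[:, order]
    ins = int(np.searchsorted(feat_sorted, markers.ref_mz))
    axis = np.insert(feat_sorted, ins, markers.ref_mz)
    inten = np.insert(vals_sorted, ins, ref, axis=1)

    ys, xs = np.divmod(np.arange(n_pix), width)
    pixels = np.column_stack([xs, ys])
    pitch = truth.cohort.get("pixel_pitch_um", 40.0)

    if profile_mode:
        axis, inten = _render_profile(
            axis, inten, profile_sigma_da, profile_bin_da, lo_mz, hi_mz
        )

    dataset = MSIDataset(
        pixels=pixels,
        pixel_pitch_um=pitch,
        metadata={"simulated": True, "seed": seed, **truth.cohort},
        mass_axis=axis,
        intensities=inten,
    )
    out_truth = GroundTruth(
        region_labels=truth.region_labels.copy(),
        region_names=list(truth.region_names),
        feature_mz=feature_mz[order],
        region_means=region_means[:, order],
        planted=planted,
        ref_mz=markers.ref_mz,
        ref_dropout_pixels=dropout_idx,
        noise_cv=markers.noise_cv,
        cohort=dict(truth.cohort),
    )
    return dataset, out_truth


def _render_profile(centroid_mz, centroid_inten, sigma_da, bin_da, lo, hi):
    """Spread centroids into Gaussian peaks on a fine uniform axis."""
    axis = np.arange(lo - 2.0, hi + 2.0, bin_da)
    out = np.zeros((centroid_inten.shape[0], len(axis)))
    half = int(math.ceil(5 * sigma_da / bin_da))
    for j, mz in enumerate(centroid_mz):
        c = int(round((mz - axis[0]) / bin_da))
        sl = slice(max(0, c - half), min(len(axis), c + half + 1))
        w = np.exp(-0.5 * ((axis[sl] - mz) / sigma_da) ** 2)
        w /= w.sum()
        out[:, sl] += centroid_inten[:, [j]] * w[None, :]
    return axis, out


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    spec: PhantomSpec | None = None,
    markers: MarkerConfig | None = None,
    n_oa: int = 4,
    n_control: int = 4,
    donor_cv: float = 0.15,
    seed: int = 0,
) -> list[tuple[MSIDataset, GroundTruth]]:
    """Simulate the study cohort: OA donors with paired medial/lateral
    sections plus unpaired control donors (medial sections).

    Each OA medial section carries the diseased wedge; its lateral pair
    and every control section do not. A per-donor log-normal factor
    (``donor_cv``) scales all marker means of that donor's sections,
    shared between the two sides of a pair, so paired comparisons cancel
    it. Sample metadata records sample id, group, side and pairing.
    """
    spec = spec or PhantomSpec()
    markers = markers or MarkerConfig()
    master = np.random.default_rng(seed)
    sections = []

    def _make(sample_id, group, side, donor, diseased, donor_factor, sub_seed):
        truth_geom = make_phantom(spec, seed=sub_seed, diseased=diseased)
        cfg_markers = [
            Marker(
                mz=m.mz,
                base_intensity=m.base_intensity * donor_factor,
                region_profile=dict(m.region_profile),
                peptide=m.peptide,
                name=m.name,
            )
            for m in markers.markers
        ]
        cfg = MarkerConfig(
            markers=cfg_markers,
            n_null_features=markers.n_null_features,
            null_mean=markers.null_mean,
            noise_cv=markers.noise_cv,
            additive_floor=markers.additive_floor,
            gain_cv=markers.gain_cv,
            ref_mz=markers.ref_mz,
            ref_intensity=markers.ref_intensity,
            ref_dropout=markers.ref_dropout,
            mz_range=markers.mz_range,
            axis_seed=markers.axis_seed if markers.axis_seed is not None else seed,
        )
        ds, truth = simulate_dataset(truth_geom, cfg, seed=sub_seed + 1)
        ds.metadata.update(
            {"sample_id": sample_id, "group": group, "side": side, "donor": donor}
        )
        truth.cohort.update(
            {"sample_id": sample_id, "group": group, "side": side, "donor": donor}
        )
        sections.append((ds, truth))

    for d in range(n_oa):
        donor_factor = float(
            _lognormal_field(master, 1.0, donor_cv, (1,))[0]
        )
        base = int(master.integers(0, 2**31 - 10))
        _make(f"P{d + 1}-medial", "OA", "medial", f"P{d + 1}", True, donor_factor, base)
        _make(f"P{d + 1}-lateral", "OA", "lateral", f"P{d + 1}", False, donor_factor, base + 5)
    for d in range(n_control):
        donor_factor = float(
            _lognormal_field(master, 1.0, donor_cv, (1,))[0]
        )
        base = int(master.integers(0, 2**31 - 10))
        _make(f"C{d + 1}-medial", "control", "medial", f"C{d + 1}", False, donor_factor, base)
    return sections


def simulate_paired_cohort_means(
    n_pairs: int = 4,
    fold: float = 3.0,
    cv: float = 0.2,
    n_null: int = 1,
    base_mean: float = 1.0,
    seed: int = 0,
) -> dict:
    """Per-sample ROI means for a paired medial/lateral design.

    Planted features are elevated ``fold``-fold on the medial side;
    null features share one mean. Sample-level variability is log-normal
    with coefficient of variation ``cv``. Returns the
    ``{mz: {"medial": [...], "lateral": [...]}}`` mapping consumed by
    :func:`osteomsi.cohort_stats.validate_candidates`, with planted
    features keyed first (m/z 1000 + i) and nulls after (m/z 2000 + i).
    """
    rng = np.random.default_rng(seed)
    out = {}
    out[1000.0] = {
        "medial": _lognormal_field(rng, base_mean * fold, cv, (n_pairs,)).tolist(),
        "lateral": _lognormal_field(rng, base_mean, cv, (n_pairs,)).tolist(),
    }
    for i in range(n_null):
        out[2000.0 + i] = {
            "medial": _lognormal_field(rng, base_mean, cv, (n_pairs,)).tolist(),
            "lateral": _lognormal_field(rng, base_mean, cv, (n_pairs,)).tolist(),
        }
    return out
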