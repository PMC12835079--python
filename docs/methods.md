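# Methods

This note documents the models, algorithmic choices and defaults behind
`osteomsi`, and what the synthetic-data tests do and do not demonstrate
about real MALDI-MSI data.

## Data model and preprocessing

An MSI dataset is a set of pixels on an integer grid (0-based indices;
physical position = index × pixel pitch in µm), each carrying a mass
spectrum. Before resampling, processed-mode imzML pixels may have
individual centroid axes; after resampling all pixels share one axis.

**Resampling.** The common axis is built from uniform bins of
configurable width spanning the union of all input mass ranges. Bins are
half-open `[lo, lo + w)`, with a mass exactly on an interior edge
assigned to the upper bin and the global maximum closing the last bin.
Every centroid's intensity is deposited in full into its bin — no
interpolation or smearing — so each pixel's total ion current is
conserved identically (verified to 1e-9 relative in tests, the slack
covering only float summation order).

**Normalization.** The default rescales each pixel so the summed
intensity in the spike-in reference window equals exactly 1 ("unit area
under the peak"). The reference is [Glu1]-fibrinopeptide B at
monoisotopic [M+H]⁺ 1570.6768, added uniformly with the matrix, so any
pixel-to-pixel multiplicative gain (matrix crystallization, laser
coupling, detector drift) divides out exactly; this also makes separately
acquired sections comparable, which per-spectrum TIC or RMS scaling (both
provided) does not guarantee when tissue composition differs. The
integration window half-width defaults to 0.25 Da; vendor software does
not document its interval, so the value is exposed in `PipelineConfig`.
Pixels whose window area falls below 1e-3 × the median window area are
treated as missing the spike-in: they are flagged, counted, left
unscaled, and excluded from downstream statistics. The floor is relative,
hence unit-free and robust to global intensity scale.

No baseline subtraction is applied by default: the "background
normalization" step of the commercial import pipeline is proprietary and
undocumented. An explicit rolling-minimum baseline remover is available
for profile-like data and is never applied implicitly.

## Feature selection

Features are selected on the mean spectrum over all retained pixels. For
profile data, peaks are strict local maxima whose topographic prominence
exceeds 1e-4 × the spectrum maximum (prominence, not raw height, so
shoulders on large peaks are not double-counted). For centroided data —
where each channel already is one ion species — every non-zero channel is
a peak; the mode is auto-detected from channel spacing (median gap
> 0.5 Da ⇒ centroided). The N = 500 most abundant peaks are kept, ranked
by mean-spectrum height with ties broken toward lower m/z for
determinism. Ranking by mean height is a documented choice; whether the
commercial "top 500" ranks by mean, maximum or occurrence frequency is
not public.

When several tissues are analysed together, each contributes its own
top-N and the union is deduplicated at twice the feature window width;
this is the only reading of per-tissue selection that lets one matrix
cover a multi-tissue comparison. Feature values are window sums
(± 0.1 Da by default) around each apex. Hotspot clipping for feature
images caps the display scale at the 99th-percentile pixel intensity;
stored values are never modified, so statistics are unaffected by
rendering.

## Segmentation

Bisecting K-means on the pixels × features matrix: starting from one
cluster, the leaf with the largest within-cluster sum of squares (SSE)
is split by 2-means (k-means++ initialization, 10 restarts, best inertia
kept) until the requested leaf count is reached. Distance is Euclidean
on reference-normalized feature values; optional per-feature z-scoring
is off by default — with a spike-in normalized matrix the informative
scale differences between marker features are exactly what separates
tissue types, and z-scoring inflates the weight of null channels.
The split tree (members and SSE per node) is retained; splitting never
increases total SSE. The leaf count is a scientific choice (the smallest
number that separates the tissues of interest, typically 4–6); an elbow
report of SSE versus leaf count supports the choice, but no automatic
selection is performed. Results are deterministic given (data, leaves,
seed); across platforms only label permutation may differ, so tests
compare partitions by adjusted Rand index.

Manual ROIs are simple polygons in pixel coordinates; a pixel belongs to
the ROI when its center is inside by the even-odd rule, with boundary
points counted as inside. Self-intersecting polygons are rejected.

## Screening statistic

For each feature, the separation between two disjoint pixel masks is the
area under the empirical ROC curve, computed as the midrank Mann–Whitney
statistic U/(n_A·n_B) = P(a > b) + ½P(a = b). Midranks make
a(A,B) + a(B,A) = 1 exact, which matters because window-summed intensities
can tie after binning. Screening is two-sided on discriminability
max(a, 1 − a) ≥ 0.85 with the direction recorded: markers elevated in
either region are candidates, and the cohort stage then tests the fixed
disease-elevation direction. No multiplicity control is applied at this
stage — screening generates candidates, it does not perform inference.

A known caveat carried into the design: pixels within a tissue are
spatially autocorrelated, so pixel-level AUROC (and any pixel-level
p-value) overstates the effective sample size. The pipeline therefore
treats pixel-level screening as ranking only and reserves inference for
the per-sample cohort stage, where the unit of analysis is the donor.

## Cohort validation

The validation unit is the per-sample ROI mean pixel intensity of each
candidate. Paired designs (medial vs lateral halves of the same donors)
use Student's t on within-pair differences with df = n − 1; unpaired
designs use the pooled-variance Student's t with df = n_A + n_B − 2
(pooled, not Welch — the classical test). Tests are one-sided for
elevation in the diseased/medial group: per-ROI intensity distributions
are right-skewed and the workflow's validated markers are elevations.
Significance is raw P < 0.05, set a priori; 0.05 ≤ P < 0.1 is reported
as a trend. (The trend convention is stated inconsistently in the
motivating literature; this package uses 0.05 ≤ P < 0.1.) A
Benjamini–Hochberg adjusted column is reported for transparency but does
not drive the flags, mirroring the raw-P convention of the workflow.
Zero-variance differences yield P of 0 or 1 by sign with an explicit
degenerate-variance warning.

PLS-DA is computed by NIPALS (via scikit-learn's PLSRegression,
tolerance 1e-10, ≤ 500 iterations — deterministic, no randomness) on
column-autoscaled per-sample means against centred one-hot class labels.
It is a descriptive projection for visualizing group separation;
no cross-validated classification is claimed. Constant feature columns
are dropped with a warning; requested components are clipped to
min(samples − 1, features).

## Peptide mass arithmetic and annotation

Monoisotopic [M+H]⁺ = Σ residue masses + water (18.010565) + proton
(1.007276) + Σ modification deltas. Residue masses are the standard
monoisotopic table stored to five decimals in `annotation.py`;
modification deltas: hydroxyproline and methionine oxidation +15.994915,
deamidation +0.984016, N-terminal acetylation +42.010565. Localized
modifications are validated against their residue (HYP on P, deamidation
on N/Q); composition-level ("unlocalized") HYP counts are supported for
multi-proline collagen peptides without site evidence, and matching uses
total mass only. HYP ladders (0..k hydroxyprolines, k capped at the
proline count) differ by exactly 15.994915 between rungs.

Annotation is MS1-mass-only: each candidate m/z is matched against all
library entries within 2 mDa (≈ 1.5e-5 relative at m/z 1300); several
isobaric matches make the candidate ambiguous but it remains a single
feature for statistics. MS/MS confirmation is out of scope. An optional
single-point recalibration against the observed spike-in peak is
provided, since it is unknowable whether published tolerance rules apply
to raw or recalibrated masses. All reported masses are recomputed from
sequence and modifications; `library_discrepancy_report` audits printed
literature values against mass arithmetic and flags entries that differ
by more than 10 mDa (for example ladder values apparently derived by
subtracting a nominal 16 rather than 15.994915).

## Synthetic cohort generator

The phantom emulates an osteochondral section on a default 120 × 80 grid
at 40 µm pitch: a cartilage band (15% of area) at the articular surface,
a thin transitional layer (5%), and below them a trabecular bone network
(30% healthy + 10% diseased) in marrow space (40%). The network is
thresholded smoothed Gaussian noise (σ = 2.5 px), giving connected
strands ~5–10 px wide — about 200 µm, the scale of real trabeculae at
this pitch. Diseased sections confine the diseased wedge to one lateral
edge of the bone area, like subchondral sclerosis beneath the region of
cartilage loss; lateral and control sections fold the wedge share into
healthy bone.

The measurement model per pixel and feature is

    intensity = gain(pixel) · LogNormal(region mean, CV) + floor,

with gain ~ LogNormal(mean 1, CV 0.3) shared across each pixel's
spectrum, biological CV 0.2, and an exponential additive floor
(scale 0.01). The spike-in channel carries only gain (with optional
dropout), so reference normalization removes gain exactly, and the
log-normal draws make every per-region intensity distribution
right-skewed — the stated rationale for one-sided cohort tests. Planted
markers are real collagen-domain peptides at their true monoisotopic
masses: type-II collagen peptides in cartilage, type-I in bone, a
type-III peptide in the transitional layer, a hemoglobin peptide in
marrow, and four HYP-modified type-I collagen peptides elevated 3-fold
in diseased over healthy bone. 490 null channels share one global mean
across regions. For log-normal intensities with equal CV the true pixel
AUROC between regions is Φ(ln(µ_A/µ_B)/(σ√2)), σ² = ln(1 + CV²) — the
closed-form oracle the screening tests check against (the additive floor
is neglected there; it is ~1% of marker signal).

The default cohort mirrors a small paired study: 4 OA donors, each with
a diseased medial and a non-diseased lateral section, plus 4 unpaired
control donors; a per-donor log-normal factor (CV 0.15) shared within
each pair models between-donor variability that paired tests cancel.
Spectra are generated centroided (one channel per species, the same
null-channel layout across a cohort's sections); an optional Gaussian
profile mode renders each species as a peak on a fine axis to exercise
profile peak picking.

**What passing tests show, and what they do not.** The generator
realizes exactly the error structure the pipeline assumes: multiplicative
gain removable by the spike-in, independent log-normal biology,
spatially uncorrelated noise, markers exactly on their theoretical
masses. Passing tests therefore demonstrate correctness of the
algorithms under their own model. Real MSI data additionally contain
spatially correlated noise, mass-calibration drift, isotope envelopes,
matrix clusters, ion suppression, and section-to-section preprocessing
differences, none of which are simulated; performance numbers from the
phantom (segmentation ARI, screening sensitivity) are upper bounds, not
forecasts for tissue data.

## Problem sizes and numerical choices

Test and demonstration runs use the 120 × 80 default phantom (9 600
pixels, ~500 channels) and a 12-section cohort; smaller 60 × 40 grids
are used where many repetitions are needed. These sizes keep every
pipeline property measurable (≥ 500 pixels per screening mask, 4 pairs
for the paired t) while keeping the full suite fast. Determinism is
end-to-end: a single integer seed drives phantom geometry, noise draws
and 2-means restarts, and identical seeds produce byte-identical
datasets and identical output checksums.

Known limitations: no ion-mobility dimension; no profile-mode
centroiding of raw traces; no registration of histology to MSI
coordinates (polygon ROIs must already be in pixel coordinates);
screening inference is not autocorrelation-adjusted (by design, see
above); the commercial software's exact preprocessing cannot be
replicated bit-for-bit, only behaviourally.
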