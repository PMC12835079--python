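"""Pipeline configuration.

All numeric constants that steer the analysis live here: the spike-in
reference peptide ([Glu1]-fibrinopeptide B, m/z 1570.6768), the top-N
feature filter, the AUROC candidate threshold, the library mass-match
tolerance, the test significance level and the hotspot display quantile.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

#: Monoisotopic [M+H]+ of the GluFib internal standard (EGVNDNEEGFFSAR).
GLUFIB_MZ = 1570.6768


@dataclass
class PipelineConfig:
    """Tunable parameters of the discovery/validation pipeline.

    Parameters
    ----------
    ref_mz : float
        m/z of the spike-in reference peptide used for normalization.
    ref_window_da : float
        Half-width (Da) of the integration window around ``ref_mz``.
        The peak interval is ``[ref_mz - w, ref_mz + w]``.
    bin_width_da : float
        Bin width of the common mass axis built by resampling.
    top_n_features : int
        Number of most-abundant mean-spectrum peaks kept per tissue.
    feature_window_da : float
        Half-width (Da) of the integration window around each feature.
    auroc_threshold : float
        Discriminability floor ``max(AUROC, 1 - AUROC)`` for candidates.
    match_tol_da : float
        Library annotation mass tolerance (Da); 0.002 Da = 2 mDa.
    alpha : float
        One-sided significance level for cohort validation t-tests.
    hotspot_quantile : float
        Display-intensity cap quantile for feature images (0.99 removes
        the top 1% most intense pixels from the colour scale).
    min_peak_prominence : float
        Peak-picking prominence floor, as a fraction of the mean
        spectrum's maximum intensity.
    n_leaves : int
        Number of leaf regions grown by bisecting K-means.
    zscore_features : bool
        Z-score each feature column before clustering.
    seed : int
        Seed for every stochastic step (2-means restarts, simulation).
    """

    ref_mz: float = GLUFIB_MZ
    ref_window_da: float = 0.25
    bin_width_da: float = 0.1
    top_n_features: int = 500
    feature_window_da: float = 0.1
    auroc_threshold: float = 0.85
    match_tol_da: float = 0.002
    alpha: float = 0.05
    hotspot_quantile: float = 0.99
    min_peak_prominence: float = 1e-4
    n_leaves: int = 5
    zscore_features: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.auroc_threshold <= 1.0):
            raise ValueError(
                f"auroc_threshold must be in (0.5, 1.0], got {self.auroc_threshold}"
            )
        if self.match_tol_da <= 0:
            raise ValueError("match_tol_da must be positive")
        if not (0.0 < self.hotspot_quantile < 1.0):
            raise ValueError("hotspot_quantile must be in (0, 1)")
        if self.ref_window_da <= 0 or self.bin_width_da <= 0:
            raise ValueError("window and bin widths must be positive")
        if self.top_n_features < 1:
            raise ValueError("top_n_features must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
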