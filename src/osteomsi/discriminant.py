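"""ROC-based discriminating-feature screening between two tissue regions.

Each feature's pixel intensities in region A vs region B are scored by the
area under the empirical ROC curve, computed as the midrank Mann-Whitney
statistic: ``AUROC = P(a > b) + 0.5 * P(a = b)`` for ``a`` drawn from A and
``b`` from B. Features whose discriminability ``max(AUROC, 1 - AUROC)``
reaches the threshold (0.85 by default) become candidate markers, with the
direction of elevation recorded.

Screening is candidate generation, not inference: no multiplicity control
is applied here. Pixels within a tissue are spatially autocorrelated, so
pixel-level AUROC overstates the effective sample size; candidates must be
validated at the cohort level (see :mod:`osteomsi.cohort_stats`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .features import FeatureTable
from .segmentation import RegionMask

__all__ = ["CandidateFeature", "auroc", "discriminating_features"]


@dataclass
class CandidateFeature:
    mz: float
    auroc: float               # P(A > B) convention, untransformed
    direction: str             # up_in_A | up_in_B
    n_pixels_A: int
    n_pixels_B: int
    comparison_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.auroc <= 1.0):
            raise ValueError("auroc must be in [0, 1]")
        if self.direction not in {"up_in_A", "up_in_B"}:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def discriminability(self) -> float:
        return max(self.auroc, 1.0 - self.auroc)


def auroc(values_A, values_B) -> float:
    """Midrank Mann-Whitney AUROC: ``P(a > b) + 0.5 P(a = b)``.

    Equals the trapezoidal area under the empirical ROC curve treating A
    as the positive class. Ties take the midrank convention, so
    ``auroc(A, B) + auroc(B, A) == 1`` exactly.
    """
    a = np.asarray(values_A, float)
    b = np.asarray(values_B, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]), method="average")
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u) / (a.size * b.size)


def discriminating_features(
    table: FeatureTable,
    mask_A: RegionMask,
    mask_B: RegionMask,
    threshold: float = 0.85,
    comparison_id: str = "",
) -> list[CandidateFeature]:
    """Score every feature's AUROC between two disjoint region masks.

    Returns candidates with ``max(auroc, 1 - auroc) >= threshold`` sorted
    by discriminability descending (ties by lower m/z), recording whether
    the feature is elevated in A or B. Overlapping masks are an error: a
    pixel cannot belong to both classes.
    """
    mask_A.require_nonempty()
    mask_B.require_nonempty()
    if len(mask_A.mask) != table.n_pixels or len(mask_B.mask) != table.n_pixels:
        raise ValueError("mask length does not match the feature table")
    if np.any(mask_A.mask & mask_B.mask):
        raise ValueError("masks overlap: a pixel cannot be in both classes")

    A = table.values[mask_A.mask]
    B = table.values[mask_B.mask]
    centers = table.features.mz_centers
    out = []
    for j, mz in enumerate(centers):
        a = auroc(A[:, j], B[:, j])
        disc = max(a, 1.0 - a)
        if disc >= threshold:
            out.append(
                CandidateFeature(
                    mz=float(mz),
                    auroc=a,
                    direction="up_in_A" if a >= 0.5 else "up_in_B",
                    n_pixels_A=int(mask_A.n_pixels),
                    n_pixels_B=int(mask_B.n_pixels),
                    comparison_id=comparison_id,
                )
            )
    out.sort(key=lambda c: (-c.discriminability, c.mz))
    return out
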