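"""Cohort-level candidate validation and PLS-DA score plots.

Screening yields candidate m/z features from one representative pair of
tissues; validation asks whether each candidate replicates across the
donor cohort. The unit of analysis is the per-sample ROI mean pixel
intensity. Paired designs (medial vs lateral halves of the same OA
donors) use a Student's t on within-pair differences; unpaired designs
(OA vs control donors) use the pooled-variance Student's t. Tests are
one-sided for elevation in the diseased/medial group, because per-ROI
intensity distributions are right-skewed and every validated marker in
this workflow is an elevation. Significance is called at raw P < alpha
(0.05); 0.05 <= P < 0.1 is flagged as a trend. A Benjamini-Hochberg
adjusted column is reported alongside but does not drive the flags.

PLS-DA (partial least squares discriminant analysis) on the
samples x candidates matrix is descriptive only — a supervised
projection used to visualize group separation, not a classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import FeatureTable
from .segmentation import RegionMask

__all__ = [
    "ValidationResult",
    "ScoreMatrix",
    "roi_mean_intensity",
    "validate_candidates",
    "plsda_scores",
]

TREND_UPPER = 0.1


@dataclass
class ValidationResult:
    mz: float
    group_means: dict            # group label -> list of per-sample means
    t_statistic: float
    df: int
    p_value: float               # one-sided
    significant: bool
    trend: bool
    p_bh: float | None = None    # Benjamini-Hochberg adjusted (reported only)
    warning: str | None = None


@dataclass
class ScoreMatrix:
    scores: np.ndarray           # samples x components
    loadings: np.ndarray         # features x components
    explained: np.ndarray        # per-component share of X variance
    classes: np.ndarray | None = None


def roi_mean_intensity(table: FeatureTable, mask: RegionMask, mz: float) -> float:
    """Mean of one feature's pixel intensities over a region mask."""
    mask.require_nonempty()
    if len(mask.mask) != table.n_pixels:
        raise ValueError("mask length does not match the feature table")
    return float(table.column(mz)[mask.mask].mean())


def _one_sided_t(values_a: np.ndarray, values_b: np.ndarray, design: str):
    """t statistic, df and one-sided p for H1: mean(a) > mean(b)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    warning = None
    if design == "paired":
        if len(a) != len(b):
            raise ValueError("paired design requires matched sample lists")
        if len(a) < 2:
            raise ValueError("paired design needs n >= 2 pairs")
        d = a - b
        df = len(d) - 1
        sd = d.std(ddof=1)
        if sd == 0:
            warning = "degenerate: zero variance of differences"
            p = 0.0 if d.mean() > 0 else (1.0 if d.mean() < 0 else 0.5)
            t = np.inf if d.mean() > 0 else (-np.inf if d.mean() < 0 else 0.0)
            return t, df, p, warning
        t = d.mean() / (sd / np.sqrt(len(d)))
    elif design == "unpaired":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("unpaired design needs n >= 2 per group")
        df = len(a) + len(b) - 2
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
        if sp2 == 0:
            warning = "degenerate: zero pooled variance"
            diff = a.mean() - b.mean()
            p = 0.0 if diff > 0 else (1.0 if diff < 0 else 0.5)
            t = np.inf if diff > 0 else (-np.inf if diff < 0 else 0.0)
            return t, df, p, warning
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    else:
        raise ValueError(f"unknown design {design!r}")
    p = float(stats.t.sf(t, df))
    return float(t), int(df), p, warning


def validate_candidates(
    per_sample_means: dict,
    design: str,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> list[ValidationResult]:
    """One-sided t-tests on per-sample ROI means for every candidate.

    Parameters
    ----------
    per_sample_means : dict
        ``{mz: {group_label: [per-sample mean, ...], ...}, ...}``.
    design : {"paired", "unpaired"}
        Paired for within-donor medial/lateral comparisons (lists must be
        pair-aligned), unpaired between different individuals.
    group_a, group_b : str
        Group labels; the alternative tested is ``mean(A) > mean(B)``
        (disease/medial elevated).
    alpha : float
        A priori one-sided significance level.
    """
    if alternative != "greater":
        raise ValueError("only the 'greater' (elevated-in-A) alternative is supported")
    raw = []
    for mz, groups in per_sample_means.items():
        t, df, p, warning = _one_sided_t(groups[group_a], groups[group_b], design)
        raw.append((mz, groups, t, df, p, warning))
    pvals = np.array([r[4] for r in raw])
    p_bh = _benjamini_hochberg(pvals) if len(pvals) else pvals
    results = []
    for (mz, groups, t, df, p, warning), q in zip(raw, p_bh):
        results.append(
            ValidationResult(
                mz=float(mz),
                group_means={g: list(map(float, v)) for g, v in groups.items()},
                t_statistic=t,
                df=df,
                p_value=p,
                significant=bool(p < alpha),
                trend=bool(alpha <= p < TREND_UPPER),
                p_bh=float(q),
                warning=warning,
            )
        )
    return results


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def plsda_scores(X, y, n_components: int = 3) -> ScoreMatrix:
    """PLS2 (NIPALS) scores of a samples x features matrix against classes.

    X is column-autoscaled (zero mean, unit variance; constant columns
    dropped with a warning), y one-hot encoded and centred. Deterministic:
    NIPALS with convergence tolerance 1e-10 and at most 500 iterations.
    Score columns are mutually orthogonal; ``explained`` is each
    component's share of the autoscaled-X variance.
    """
    from sklearn.cross_decomposition import PLSRegression

    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be samples x features")
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in range(len(classes)):
        if (y_idx == c).sum() < 2:
            raise ValueError(f"class {classes[c]!r} has fewer than 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} constant feature column(s)")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    max_comp = min(X.shape[0] - 1, int(keep.sum()))
    if n_components > max_comp:
        warnings.warn(f"n_components clipped from {n_components} to {max_comp}")
        n_components = max_comp

    Y = np.zeros((len(y_idx), len(classes)))
    Y[np.arange(len(y_idx)), y_idx] = 1.0

    pls = PLSRegression(n_components=n_components, scale=False, max_iter=500, tol=1e-10)
    pls.fit(Xs, Y - Y.mean(axis=0))

    scores = pls.x_scores_
    loadings_full = np.zeros((X.shape[1], n_components))
    loadings_full[keep] = pls.x_loadings_
    total_var = np.sum(Xs**2)
    explained = np.array(
        [
            np.sum(np.outer(scores[:, k], pls.x_loadings_[:, k]) ** 2) / total_var
            for k in range(n_components)
        ]
    )
    return ScoreMatrix(
        scores=scores, loadings=loadings_full, explained=explained, classes=classes
    )
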