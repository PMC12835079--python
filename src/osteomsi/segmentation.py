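"""Unsupervised bisecting K-means tissue segmentation and ROI masks.

Segmentation clusters the pixels x features matrix hierarchically: starting
from one cluster holding every pixel, the leaf with the largest
within-cluster sum of squares (SSE) is repeatedly split by 2-means
(k-means++ init, 10 restarts keeping the best inertia) until the requested
number of leaves exists. The binary split tree is retained, which mirrors
how imaging software presents tissue regions: 4-6 leaves typically
separate cartilage, transitional layers, healthy and diseased bone, and
marrow space.

Regions of interest are either unions of leaves (automated) or manually
drawn polygons in pixel coordinates (guided segmentation around, e.g.,
the outer medial edge of a tibial plateau).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .features import FeatureTable

__all__ = [
    "SegmentationResult",
    "RegionMask",
    "bisect_segment",
    "roi_from_labels",
    "roi_from_polygon",
    "elbow_report",
    "spatial_median_filter",
    "save_label_map",
]


@dataclass
class SplitNode:
    """A node of the bisecting tree: its member pixels and SSE."""

    members: np.ndarray           # pixel indices
    sse: float
    leaf_id: int | None = None    # set while the node is a leaf
    children: tuple["SplitNode", "SplitNode"] | None = None


@dataclass
class SegmentationResult:
    labels: np.ndarray            # per-pixel leaf id, 0..n_leaves-1
    tree: SplitNode
    n_leaves: int

    def __post_init__(self) -> None:
        ids = np.unique(self.labels)
        if len(ids) != self.n_leaves or ids.min() < 0:
            raise ValueError("leaf ids must partition all pixels into n_leaves leaves")

    def leaf_ids(self) -> list[int]:
        return sorted(np.unique(self.labels).tolist())

    def leaf_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class RegionMask:
    """Boolean pixel mask with a name and an origin tag."""

    mask: np.ndarray
    name: str
    origin: str = "automated"     # automated | manual-polygon | guided

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.origin not in {"automated", "manual-polygon", "guided"}:
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> "RegionMask":
        if self.n_pixels == 0:
            raise ValueError(f"region {self.name!r} selects no pixels")
        return self


def _sse(X: np.ndarray) -> float:
    if len(X) == 0:
        return 0.0
    return float(np.sum((X - X.mean(axis=0)) ** 2))


def spatial_median_filter(table: FeatureTable) -> FeatureTable:
    """Optional 3x3 median filter on each feature image before clustering.

    Reduces salt-and-pepper pixel noise at the cost of blurring region
    boundaries; off unless explicitly requested.
    """
    from scipy.ndimage import median_filter

    xs, ys = table.pixels[:, 0], table.pixels[:, 1]
    h, w = ys.max() + 1, xs.max() + 1
    filtered = np.empty_like(table.values)
    for j in range(table.values.shape[1]):
        img = np.zeros((h, w))
        img[ys, xs] = table.values[:, j]
        filtered[:, j] = median_filter(img, size=3, mode="nearest")[ys, xs]
    return FeatureTable(
        pixels=table.pixels.copy(),
        features=table.features,
        values=filtered,
        provenance={**table.provenance, "spatial_filter": "median3x3"},
    )


def save_label_map(seg: SegmentationResult, table: FeatureTable, tsv_path=None, png_path=None) -> None:
    """Export per-pixel leaf labels as TSV and/or a colour PNG render."""
    xs, ys = table.pixels[:, 0], table.pixels[:, 1]
    if tsv_path is not None:
        import pandas as pd

        pd.DataFrame({"x": xs, "y": ys, "label": seg.labels}).to_csv(
            tsv_path, sep="\t", index=False
        )
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        img = np.full((ys.max() + 1, xs.max() + 1), np.nan)
        img[ys, xs] = seg.labels
        plt.imsave(png_path, np.nan_to_num(img, nan=-1), cmap="tab10", origin="lower")


def bisect_segment(
    table: FeatureTable,
    n_leaves: int,
    seed: int = 0,
    zscore: bool = False,
    n_restarts: int = 10,
    median_filter_3x3: bool = False,
) -> SegmentationResult:
    """Hierarchical bisecting K-means on the feature table.

    Euclidean distance on the (optionally per-feature z-scored) feature
    values; an optional 3x3 spatial median filter can be applied to the
    feature images first. Deterministic given ``(table, n_leaves,
    seed)``; splitting a leaf never increases the total within-cluster
    SSE.
    """
    if median_filter_3x3:
        table = spatial_median_filter(table)
    n = table.n_pixels
    if not (1 <= n_leaves <= n):
        raise ValueError(f"n_leaves must be in [1, {n}], got {n_leaves}")
    X = table.values
    if zscore:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    root = SplitNode(members=np.arange(n), sse=_sse(X), leaf_id=0)
    leaves = [root]
    rng = np.random.default_rng(seed)
    while len(leaves) < n_leaves:
        # split the splittable leaf with the largest SSE
        order = sorted(range(len(leaves)), key=lambda i: -leaves[i].sse)
        node_i = None
        for i in order:
            if len(leaves[i].members) >= 2 and leaves[i].sse > 0:
                node_i = i
                break
        if node_i is None:
            raise ValueError(
                f"cannot grow {n_leaves} leaves: remaining leaves are singletons "
                "or zero-variance"
            )
        node = leaves[node_i]
        sub = X[node.members]
        km = KMeans(
            n_clusters=2,
            init="k-means++",
            n_init=n_restarts,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(sub)
        left_m = node.members[km.labels_ == 0]
        right_m = node.members[km.labels_ == 1]
        if len(left_m) == 0 or len(right_m) == 0:  # degenerate split
            raise ValueError("2-means produced an empty child; cannot split further")
        left = SplitNode(members=left_m, sse=_sse(X[left_m]), leaf_id=node.leaf_id)
        right = SplitNode(members=right_m, sse=_sse(X[right_m]), leaf_id=len(leaves))
        node.children = (left, right)
        node.leaf_id = None
        leaves[node_i] = left
        leaves.append(right)

    labels = np.empty(n, dtype=int)
    for leaf in leaves:
        labels[leaf.members] = leaf.leaf_id
    return SegmentationResult(labels=labels, tree=root, n_leaves=len(leaves))


def elbow_report(table: FeatureTable, max_leaves: int, seed: int = 0, zscore: bool = False):
    """Total within-cluster SSE for 1..max_leaves leaves (elbow diagnostic).

    The region count is a human choice (the smallest count that separates
    the tissue types of interest); this report supports it but performs no
    automatic selection.
    """
    import pandas as pd

    rows = []
    for k in range(1, max_leaves + 1):
        seg = bisect_segment(table, k, seed=seed, zscore=zscore)
        total = sum(
            _sse(table.values[np.flatnonzero(seg.labels == lid)])
            for lid in seg.leaf_ids()
        )
        rows.append({"n_leaves": k, "total_sse": total})
    return pd.DataFrame(rows)


def roi_from_labels(seg: SegmentationResult, leaf_ids: set[int], name: str = "") -> RegionMask:
    """Union of leaf segments as a region mask (origin=automated)."""
    leaf_ids = set(leaf_ids)
    if not leaf_ids:
        raise ValueError("empty leaf id set")
    existing = set(seg.leaf_ids())
    unknown = leaf_ids - existing
    if unknown:
        raise ValueError(f"unknown leaf ids {sorted(unknown)}")
    mask = np.isin(seg.labels, sorted(leaf_ids))
    return RegionMask(mask=mask, name=name or f"leaves {sorted(leaf_ids)}", origin="automated")


def roi_from_polygon(
    vertices: list[tuple[float, float]], table: FeatureTable, name: str = "manual ROI"
) -> RegionMask:
    """Pixels whose centers fall inside a simple polygon (boundary inclusive).

    Even-odd (ray-casting) rule; self-intersecting polygons are rejected.
    """
    if len(vertices) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if _self_intersects(vertices):
        raise ValueError("self-intersecting polygon")
    pts = table.pixels.astype(float)
    inside = np.array([_point_in_polygon(x, y, vertices) for x, y in pts])
    return RegionMask(mask=inside, name=name, origin="manual-polygon")


def _point_in_polygon(px: float, py: float, verts: list[tuple[float, float]]) -> bool:
    """Even-odd rule with an explicit boundary test (boundary = inside)."""
    n = len(verts)
    # boundary check
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 and min(
                y1, y2
            ) - 1e-12 <= py <= max(y1, y2) + 1e-12:
                return True
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def _segments_properly_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def _self_intersects(verts: list[tuple[float, float]]) -> bool:
    n = len(verts)
    edges = [(verts[i], verts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if _segments_properly_intersect(*edges[i], *edges[j]):
                return True
    return False
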