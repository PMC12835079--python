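"""Bisecting K-means segmentation, split tree, polygon/leaf ROIs."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from osteomsi import MarkerConfig, PhantomSpec, make_phantom, simulate_dataset
from osteomsi.features import FeatureSet, FeatureTable
from osteomsi.segmentation import (
    RegionMask,
    bisect_segment,
    elbow_report,
    roi_from_labels,
    roi_from_polygon,
)


def _table(values, pixels=None):
    values = np.asarray(values, float)
    if pixels is None:
        pixels = np.array([[i, 0] for i in range(len(values))])
    fs = FeatureSet(
        [(1000.0 + 10 * j, 0.1, j + 1) for j in range(values.shape[1])]
    )
    return FeatureTable(pixels=pixels, features=fs, values=values)


def test_single_leaf_contains_everything():
    table = _table(np.random.default_rng(0).random((20, 3)))
    seg = bisect_segment(table, 1, seed=0)
    assert seg.n_leaves == 1
    assert np.all(seg.labels == 0)


def test_two_planted_populations_recovered_exactly():
    """Disjoint one-hot signatures split with ARI = 1 at two leaves."""
    a = np.tile([5.0, 0.0], (30, 1))
    b = np.tile([0.0, 5.0], (25, 1))
    table = _table(np.vstack([a, b]))
    seg = bisect_segment(table, 2, seed=1)
    truth = np.array([0] * 30 + [1] * 25)
    assert adjusted_rand_score(truth, seg.labels) == 1.0


def test_phantom_five_regions_recovered(sim_table):
    """Default 5-region phantom at CV 0.2: ARI >= 0.9 with 5 leaves."""
    table, truth = sim_table
    seg = bisect_segment(table, 5, seed=0)
    assert adjusted_rand_score(truth.region_labels, seg.labels) >= 0.9


def test_split_tree_partitions_and_sse_monotone(sim_table):
    table, truth = sim_table
    seg = bisect_segment(table, 5, seed=0)

    def check(node):
        if node.children is None:
            return [node]
        left, right = node.children
        merged = np.sort(np.concatenate([left.members, right.members]))
        np.testing.assert_array_equal(merged, np.sort(node.members))
        # splitting never increases within-cluster SSE
        assert left.sse + right.sse <= node.sse + 1e-9
        return check(left) + check(right)

    leaves = check(seg.tree)
    assert len(leaves) == seg.n_leaves
    sizes = sum(len(l.members) for l in leaves)
    assert sizes == table.n_pixels


def test_segmentation_seed_deterministic(sim_table):
    table, _ = sim_table
    a = bisect_segment(table, 4, seed=9)
    b = bisect_segment(table, 4, seed=9)
    assert adjusted_rand_score(a.labels, b.labels) == 1.0


def test_noise_free_phantom_leaf_means_match_signatures():
    """At zero noise the leaf mean spectra equal the planted region means."""
    truth = make_phantom(PhantomSpec(grid=(40, 30)), seed=2)
    cfg = MarkerConfig(
        n_null_features=20, noise_cv=0.0, gain_cv=0.0, additive_floor=0.0
    )
    ds, truth = simulate_dataset(truth, cfg, seed=2)
    # build the table directly on the channels (spike-in included)
    fs = FeatureSet(
        [(float(mz), 0.1, j + 1) for j, mz in enumerate(ds.mass_axis)]
    )
    table = FeatureTable(pixels=ds.pixels, features=fs, values=ds.intensities)
    present = len(np.unique(truth.region_labels))
    seg = bisect_segment(table, present, seed=0)
    assert adjusted_rand_score(truth.region_labels, seg.labels) == 1.0
    for leaf in np.unique(seg.labels):
        sel = seg.labels == leaf
        region = truth.region_labels[sel][0]
        leaf_mean = table.values[sel].mean(axis=0)
        truth_cols = [
            float(np.argmin(np.abs(ds.mass_axis - mz))) for mz in truth.feature_mz
        ]
        expected = truth.region_means[region]
        got = np.array(
            [leaf_mean[int(c)] for c in truth_cols]
        )
        np.testing.assert_allclose(got, expected, rtol=0.01)


def test_elbow_report_sse_decreases(sim_table):
    table, _ = sim_table
    rep = elbow_report(table, 4, seed=0)
    sse = rep["total_sse"].to_numpy()
    assert np.all(np.diff(sse) <= 1e-9)


def test_n_leaves_bounds():
    table = _table(np.random.default_rng(0).random((5, 2)))
    with pytest.raises(ValueError):
        bisect_segment(table, 6, seed=0)
    with pytest.raises(ValueError):
        bisect_segment(table, 0, seed=0)


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

def test_roi_from_labels_set_arithmetic(sim_table):
    table, _ = sim_table
    seg = bisect_segment(table, 4, seed=0)
    full = roi_from_labels(seg, set(seg.leaf_ids()))
    assert full.n_pixels == table.n_pixels
    sizes = seg.leaf_sizes()
    two = roi_from_labels(seg, {0, 1})
    assert two.n_pixels == sizes[0] + sizes[1]
    with pytest.raises(ValueError, match="empty"):
        roi_from_labels(seg, set())
    with pytest.raises(ValueError, match="unknown"):
        roi_from_labels(seg, {99})


def test_polygon_rectangle_covers_grid():
    pix = np.array([[x, y] for y in range(5) for x in range(5)])
    table = FeatureTable(
        pixels=pix, features=FeatureSet([(1000.0, 0.1, 1)]), values=np.ones((25, 1))
    )
    roi = roi_from_polygon([(-1, -1), (5, -1), (5, 5), (-1, 5)], table)
    assert roi.n_pixels == 25
    assert roi.origin == "manual-polygon"


def test_polygon_boundary_counts_inside():
    pix = np.array([[0, 0], [1, 0], [2, 0]])
    table = FeatureTable(
        pixels=pix, features=FeatureSet([(1000.0, 0.1, 1)]), values=np.ones((3, 1))
    )
    roi = roi_from_polygon([(0, 0), (1, 0), (1, 1), (0, 1)], table)
    assert roi.mask.tolist() == [True, True, False]


def test_polygon_covering_no_pixel_centers_flagged_on_use():
    pix = np.array([[0, 0], [5, 5]])
    table = FeatureTable(
        pixels=pix, features=FeatureSet([(1000.0, 0.1, 1)]), values=np.ones((2, 1))
    )
    roi = roi_from_polygon([(2.1, 2.1), (2.9, 2.1), (2.5, 2.9)], table)
    with pytest.raises(ValueError, match="no pixels"):
        roi.require_nonempty()


def test_self_intersecting_polygon_rejected():
    pix = np.array([[0, 0]])
    table = FeatureTable(
        pixels=pix, features=FeatureSet([(1000.0, 0.1, 1)]), values=np.ones((1, 1))
    )
    bowtie = [(0, 0), (2, 2), (2, 0), (0, 2)]
    with pytest.raises(ValueError, match="self-intersect"):
        roi_from_polygon(bowtie, table)


def test_polygon_matches_shapely_oracle():
    """Random simple polygons on a 50x50 grid vs an independent geometry oracle."""
    shapely = pytest.importorskip("shapely")
    from shapely.geometry import Point, Polygon

    rng = np.random.default_rng(5)
    pix = np.array([[x, y] for y in range(50) for x in range(50)])
    table = FeatureTable(
        pixels=pix,
        features=FeatureSet([(1000.0, 0.1, 1)]),
        values=np.ones((2500, 1)),
    )
    from scipy.spatial import ConvexHull

    polygons = [
        # fixed concave L-shape and chevron
        [(5, 5), (40, 5), (40, 20), (20, 20), (20, 40), (5, 40)],
        [(10, 10), (25, 30), (40, 10), (40, 45), (10, 45)],
    ]
    for _ in range(8):
        pts = rng.uniform(3, 47, size=(int(rng.integers(5, 15)), 2))
        hull = ConvexHull(pts)
        polygons.append([tuple(pts[v]) for v in hull.vertices])
    for verts in polygons:
        roi = roi_from_polygon(verts, table)
        poly = Polygon(verts)
        oracle = np.array([poly.covers(Point(x, y)) for x, y in pix])
        np.testing.assert_array_equal(roi.mask, oracle)


def test_spatial_median_filter_removes_salt_noise():
    from osteomsi.segmentation import spatial_median_filter

    pix = np.array([[x, y] for y in range(9) for x in range(9)])
    vals = np.ones((81, 1))
    vals[40, 0] = 100.0  # single hot pixel at the grid center
    table = FeatureTable(
        pixels=pix,
        features=FeatureSet([(1000.0, 0.1, 1)]),
        values=vals,
    )
    out = spatial_median_filter(table)
    assert out.values[40, 0] == 1.0
    assert table.values[40, 0] == 100.0  # input untouched


def test_save_label_map_outputs(tmp_path, sim_table):
    from osteomsi.segmentation import save_label_map

    table, _ = sim_table
    seg = bisect_segment(table, 3, seed=0)
    tsv, png = tmp_path / "labels.tsv", tmp_path / "labels.png"
    save_label_map(seg, table, tsv_path=tsv, png_path=png)
    import pandas as pd

    df = pd.read_csv(tsv, sep="\t")
    assert len(df) == table.n_pixels
    assert set(df["label"]) == set(seg.leaf_ids())
    assert png.stat().st_size > 0
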