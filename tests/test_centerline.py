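"""Skeletonization, tree extraction, branch point, division, standardization."""

import numpy as np
import pytest

from carotidseg import centerline as cl
from carotidseg.io_core import LabelMap


def _lm(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelMap(np.asarray(arr, dtype=np.int16), spacing)


def draw_path(shape, points):
    """Rasterize integer waypoints into a voxel line (inclusive)."""
    arr = np.zeros(shape, dtype=np.int16)
    for a, b in zip(points[:-1], points[1:]):
        a, b = np.asarray(a), np.asarray(b)
        n = int(np.abs(b - a).max())
        for t in np.linspace(0.0, 1.0, n + 1):
            arr[tuple(np.rint(a + t * (b - a)).astype(int))] = 1
    return arr


class TestSkeletonize:
    def test_cylinder_skeleton_near_axis(self):
        xx, yy = np.meshgrid(np.arange(21) - 10.2, np.arange(21) - 10.2,
                             indexing="ij")
        disk = xx**2 + yy**2 <= 36
        mask = np.broadcast_to(disk[:, :, None], (21, 21, 40)).astype(np.int16)
        skel = cl.skeletonize(_lm(mask))
        vox = np.argwhere(skel.labels > 0)
        # all skeleton voxels within one voxel of the axis (x=y=10.2)
        assert np.abs(vox[:, :2] - 10.2).max() <= 1.5
        assert np.all(mask[tuple(vox.T)] > 0)  # skeleton subset of mask

    def test_ball_collapses(self):
        mask = np.zeros((15, 15, 15), dtype=np.int16)
        x, y, z = np.meshgrid(*([np.arange(15) - 7.2] * 3), indexing="ij")
        mask[x**2 + y**2 + z**2 <= 25] = 1
        skel = cl.skeletonize(_lm(mask))
        assert 0 < skel.labels.sum() <= 5

    def test_idempotent(self):
        arr = draw_path((12, 12, 12), [(2, 2, 2), (9, 9, 9)])
        once = cl.skeletonize(_lm(arr))
        twice = cl.skeletonize(once)
        assert np.array_equal(once.labels, twice.labels)

    def test_empty_and_disconnected_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cl.skeletonize(_lm(np.zeros((5, 5, 5))))
        arr = np.zeros((8, 8, 8), dtype=np.int16)
        arr[1, 1, 1] = arr[6, 6, 6] = 1
        with pytest.raises(ValueError, match="components"):
            cl.skeletonize(_lm(arr))


class TestExtractTree:
    def test_y_shape_counts(self):
        arr = draw_path((30, 5, 30), [(15, 2, 2), (15, 2, 15)])
        arr |= draw_path((30, 5, 30), [(15, 2, 15), (25, 2, 27)])
        arr |= draw_path((30, 5, 30), [(15, 2, 15), (5, 2, 27)])
        tree = cl.extract_tree(_lm(arr), prune_mm=0.0)
        assert len(tree.junctions()) == 1
        assert sum(n.kind == "endpoint" for n in tree.nodes.values()) == 3
        assert len(tree.edges) == 3

    def test_straight_path(self):
        arr = draw_path((20, 5, 5), [(2, 2, 2), (17, 2, 2)])
        tree = cl.extract_tree(_lm(arr))
        assert len(tree.junctions()) == 0
        assert sum(n.kind == "endpoint" for n in tree.nodes.values()) == 2
        assert len(tree.edges) == 1

    def test_spur_pruned(self):
        arr = draw_path((30, 5, 30), [(15, 2, 2), (15, 2, 15)])
        arr |= draw_path((30, 5, 30), [(15, 2, 15), (25, 2, 27)])
        arr |= draw_path((30, 5, 30), [(15, 2, 15), (5, 2, 27)])
        arr |= draw_path((30, 5, 30), [(15, 2, 15), (17, 2, 16)])  # 2-vox spur
        tree = cl.extract_tree(_lm(arr), prune_mm=3.0)
        assert len(tree.junctions()) == 1
        assert len(tree.edges) == 3

    def test_cycle_rejected(self):
        arr = draw_path((12, 5, 12), [(2, 2, 2), (2, 2, 9), (9, 2, 9),
                                      (9, 2, 2), (2, 2, 2)])
        with pytest.raises(ValueError, match="cyclic"):
            cl.extract_tree(_lm(arr))


class TestBranchPoint:
    def test_phantom_branch_point_recovered(self, clean_phantom):
        _, truth, model = clean_phantom
        union = _lm(truth.labels > 0, truth.spacing)
        union = LabelMap((truth.labels > 0).astype(np.int16), truth.spacing,
                         truth.origin)
        tree = cl.extract_tree(cl.skeletonize(union))
        bp = cl.find_branch_point(tree)
        # within 2 voxels (~1 mm) of the analytic branch point
        assert np.linalg.norm(bp - model.branch_point) <= 1.0

    def test_straight_vessel_has_no_branch_point(self):
        arr = draw_path((20, 5, 5), [(2, 2, 2), (17, 2, 2)])
        tree = cl.extract_tree(_lm(arr))
        with pytest.raises(ValueError, match="no bifurcation"):
            cl.find_branch_point(tree)

    def test_caudal_cranial_pattern_selects_junction(self):
        # bifurcation at z=15 plus a spurious junction on the ICA at z=24
        arr = draw_path((40, 5, 40), [(20, 2, 2), (20, 2, 15)])
        arr |= draw_path((40, 5, 40), [(20, 2, 15), (29, 2, 24)])
        arr |= draw_path((40, 5, 40), [(20, 2, 15), (11, 2, 24)])
        arr |= draw_path((40, 5, 40), [(29, 2, 24), (29, 2, 36)])
        arr |= draw_path((40, 5, 40), [(29, 2, 24), (37, 2, 30)])
        tree = cl.extract_tree(_lm(arr), prune_mm=0.0)
        assert len(tree.junctions()) == 2
        bp = cl.find_branch_point(tree)
        assert np.linalg.norm(bp - np.array([20, 2, 15])) < 4.0


class TestDivideAndStandardize:
    def test_division_is_partition(self, clean_phantom):
        _, truth, _ = clean_phantom
        union = LabelMap((truth.labels > 0).astype(np.int16), truth.spacing,
                         truth.origin)
        tree = cl.extract_tree(cl.skeletonize(union))
        bp = cl.find_branch_point(tree)
        div = cl.divide_branches(union, tree, bp)
        assert np.array_equal(div.labels > 0, truth.labels > 0)
        assert set(np.unique(div.labels)) == {0, 1, 2, 3}

    def test_division_matches_truth(self, clean_phantom):
        _, truth, _ = clean_phantom
        union = LabelMap((truth.labels > 0).astype(np.int16), truth.spacing,
                         truth.origin)
        tree = cl.extract_tree(cl.skeletonize(union))
        bp = cl.find_branch_point(tree)
        div = cl.divide_branches(union, tree, bp)
        fg = truth.labels > 0
        assert (div.labels[fg] == truth.labels[fg]).mean() >= 0.95

    def test_standardize_monotone_in_length(self, clean_phantom):
        _, truth, _ = clean_phantom
        union = LabelMap((truth.labels > 0).astype(np.int16), truth.spacing,
                         truth.origin)
        tree = cl.extract_tree(cl.skeletonize(union))
        bp = cl.find_branch_point(tree)
        div = cl.divide_branches(union, tree, bp)
        short = cl.standardize_length(div, tree, 15.0, branch_point=bp)
        long = cl.standardize_length(div, tree, 22.0, branch_point=bp)
        assert np.all((short.labels > 0) <= (long.labels > 0))

    def test_branches_shorter_than_cut_unchanged(self, clean_phantom):
        _, truth, _ = clean_phantom
        union = LabelMap((truth.labels > 0).astype(np.int16), truth.spacing,
                         truth.origin)
        tree = cl.extract_tree(cl.skeletonize(union))
        bp = cl.find_branch_point(tree)
        div = cl.divide_branches(union, tree, bp)
        out = cl.standardize_length(div, tree, 500.0, branch_point=bp)
        assert np.array_equal(out.labels, div.labels)

    def test_zero_length_empties_foreground(self, clean_phantom):
        _, truth, _ = clean_phantom
        union = LabelMap((truth.labels > 0).astype(np.int16), truth.spacing,
                         truth.origin)
        tree = cl.extract_tree(cl.skeletonize(union))
        bp = cl.find_branch_point(tree)
        div = cl.divide_branches(union, tree, bp)
        out = cl.standardize_length(div, tree, 0.0, branch_point=bp)
        assert out.labels.max() == 0


class TestSmoothCenterline:
    def test_collinear_fixed_point(self):
        pts = np.stack([np.zeros(20), np.zeros(20), np.arange(20.0)], axis=1)
        out = cl.smooth_centerline(pts, 5)
        np.testing.assert_allclose(out, pts, atol=1e-12)

    def test_window_one_is_identity(self, rng):
        pts = rng.normal(size=(15, 3))
        np.testing.assert_array_equal(cl.smooth_centerline(pts, 1), pts)

    def test_endpoints_preserved(self, rng):
        pts = rng.normal(size=(15, 3))
        out = cl.smooth_centerline(pts, 7)
        np.testing.assert_array_equal(out[0], pts[0])
        np.testing.assert_array_equal(out[-1], pts[-1])
        assert len(out) == len(pts)

    def test_zigzag_deviation_halved(self):
        z = np.arange(40.0)
        x = np.where(z % 2 == 0, 1.0, -1.0)
        pts = np.stack([x, np.zeros(40), z], axis=1)
        out = cl.smooth_centerline(pts, 5)
        assert np.abs(out[5:-5, 0]).max() <= 0.5 * np.abs(x).max()

    def test_bad_window_rejected(self, rng):
        pts = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            cl.smooth_centerline(pts, 4)
        with pytest.raises(ValueError):
            cl.smooth_centerline(pts, 11)
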