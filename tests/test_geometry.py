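"""Diameter profiles, ratios, bifurcation angle, cohort statistics."""

import numpy as np
import pytest

from carotidseg import geometry, phantom
from carotidseg.geometry import (GeometryReport, bifurcation_angle,
                                 cohort_stats, diameter_profile,
                                 diameter_ratios, mean_branch_diameter)
from carotidseg.io_core import LabelMap


def make_tube_mask(direction, diameter, length=30.0, spacing=(0.48, 0.48, 0.5),
                   semi_other=None):
    """Voxelized tube (or elliptical tube) around a straight centerline."""
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)
    r = diameter / 2.0
    pad = max(r, semi_other or r) + 2.0
    t = np.linspace(0, length, int(length / 0.2) + 1)
    line = t[:, None] * direction[None, :]
    lo = line.min(axis=0) - pad
    hi = line.max(axis=0) + pad
    origin = lo
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing[i])) + 1
                  for i in range(3))
    idx = np.indices(shape).reshape(3, -1).T
    pos = origin + idx * np.asarray(spacing)
    # distance to the infinite line, decomposed into two normal components
    ref = np.array([1.0, 0, 0]) if abs(direction[0]) < 0.9 else \
        np.array([0.0, 1, 0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    s = pos @ direction
    du = pos @ u
    dv = pos @ v
    b = semi_other or r
    inside = ((du / r)**2 + (dv / b)**2 <= 1.0) & (s >= 0) & (s <= length)
    mask = np.zeros(shape, dtype=np.int16)
    mask[tuple(idx[inside].T)] = 1
    return LabelMap(mask, spacing, tuple(origin)), line


class TestDiameterProfile:
    def test_axis_aligned_cylinder(self):
        mask, line = make_tube_mask([0, 0, 1], 8.0)
        prof = diameter_profile(mask, line[::5])
        assert mean_branch_diameter(prof) == pytest.approx(8.0, abs=0.5)

    def test_oblique_cylinder_same_recovery(self):
        d = np.array([np.sin(np.radians(30)), 0.1, np.cos(np.radians(30))])
        mask, line = make_tube_mask(d, 8.0)
        prof = diameter_profile(mask, line[::5])
        assert mean_branch_diameter(prof) == pytest.approx(8.0, abs=0.5)

    def test_elliptical_tube_equivalent_diameter(self):
        # 8 x 4 mm ellipse: area-equivalent circle diameter = 2 sqrt(ab)
        mask, line = make_tube_mask([0, 0, 1], 8.0, semi_other=2.0)
        prof = diameter_profile(mask, line[::5])
        assert mean_branch_diameter(prof) == pytest.approx(
            2 * np.sqrt(4.0 * 2.0), abs=0.5)

    def test_ends_excluded(self):
        mask, line = make_tube_mask([0, 0, 1], 8.0, length=30.0)
        prof = diameter_profile(mask, line[::5], end_exclusion_mm=2.0)
        arcs = [a for a, _ in prof]
        assert min(arcs) >= 2.0
        assert max(arcs) <= 28.0


class TestSimpleOps:
    def test_mean_diameter(self):
        assert mean_branch_diameter([(0, 6.0), (1, 8.0), (2, 10.0)]) == 8.0
        assert mean_branch_diameter([(0, 8.0)] * 5) == 8.0
        with pytest.raises(ValueError):
            mean_branch_diameter([])

    def test_ratios(self):
        r_ica, r_eca = diameter_ratios(8.7, 7.5, 5.7)
        assert r_ica == pytest.approx(0.862, abs=1e-3)
        assert r_eca == pytest.approx(0.655, abs=1e-3)
        assert diameter_ratios(5.0, 5.0, 5.0) == (1.0, 1.0)
        with pytest.raises(ValueError):
            diameter_ratios(0.0, 1.0, 1.0)

    @pytest.mark.parametrize("angle", [0.0, 60.0, 180.0])
    def test_angle_trivial_cases(self, angle):
        t = np.linspace(0, 20, 41)
        a = np.stack([np.zeros_like(t), np.zeros_like(t), t], axis=1)
        rad = np.radians(angle)
        b = np.stack([np.sin(rad) * t, np.zeros_like(t), np.cos(rad) * t],
                     axis=1)
        assert bifurcation_angle(a, b, np.zeros(3)) == pytest.approx(
            angle, abs=1e-9)

    def test_report_ratio_invariant(self):
        rep = GeometryReport(8.0, 6.0, 4.0, 0.75, 0.5, 50.0)
        assert rep.ratio_ica_cca == rep.d_ica / rep.d_cca
        with pytest.raises(ValueError):
            GeometryReport(8.0, 6.0, 4.0, 0.9, 0.5, 50.0)


class TestAnalyzeBifurcation:
    def test_default_phantom_recovery(self, clean_phantom):
        _, truth, _ = clean_phantom
        rep = geometry.analyze_bifurcation(truth)
        assert rep.d_cca == pytest.approx(8.7, abs=0.5)
        assert rep.d_ica == pytest.approx(7.5, abs=0.5)
        assert rep.d_eca == pytest.approx(5.7, abs=0.5)
        assert rep.theta == pytest.approx(50.0, abs=5.0)
        assert rep.ratio_ica_cca == pytest.approx(rep.d_ica / rep.d_cca)

    def test_single_branch_rejected(self):
        mask, _ = make_tube_mask([0, 0, 1], 8.0)
        with pytest.raises(ValueError):
            geometry.analyze_bifurcation(mask)

    def test_rotation_invariance(self, clean_spec):
        base = phantom.make_centerline_tree(clean_spec)
        rep0 = geometry.analyze_bifurcation(
            phantom.rasterize_phantom(base, clean_spec)[1])
        ang = np.radians(30.0)
        rot = np.array([[np.cos(ang), 0, np.sin(ang)], [0, 1, 0],
                        [-np.sin(ang), 0, np.cos(ang)]])
        rotated = phantom.BifurcationModel(
            base.cca_centerline @ rot.T, base.ica_centerline @ rot.T,
            base.eca_centerline @ rot.T, base.branch_point @ rot.T,
            base.radii)
        rep1 = geometry.analyze_bifurcation(
            phantom.rasterize_phantom(rotated, clean_spec)[1])
        for p in ("d_cca", "d_ica", "d_eca"):
            assert abs(getattr(rep1, p) - getattr(rep0, p)) < 0.3
        assert abs(rep1.theta - rep0.theta) < 3.0

    def test_resolution_consistency(self, clean_spec):
        from dataclasses import replace
        fine_spec = replace(clean_spec, spacing=(0.25, 0.25, 0.25))
        coarse_spec = replace(clean_spec, spacing=(0.5, 0.5, 0.5))
        rep_f = geometry.analyze_bifurcation(
            phantom.generate_phantom(fine_spec)[1])
        rep_c = geometry.analyze_bifurcation(
            phantom.generate_phantom(coarse_spec)[1])
        for p in ("d_cca", "d_ica", "d_eca"):
            assert abs(getattr(rep_f, p) - getattr(rep_c, p)) < 0.5


class TestCohortStats:
    def test_identical_reports(self):
        rep = GeometryReport(8.0, 6.0, 4.0, 0.75, 0.5, 50.0)
        st = cohort_stats([rep, rep])
        assert st.stats["d_cca"]["sd"] == 0.0
        assert st.stats["d_cca"]["cv"] == 0.0

    def test_hand_arithmetic(self):
        reps = [GeometryReport(8.0, 6.0, 4.0, 0.75, 0.5, 50.0),
                GeometryReport(10.0, 6.0, 4.0, 0.6, 0.4, 50.0)]
        st = cohort_stats(reps)
        assert st.stats["d_cca"]["mean"] == 9.0
        assert st.stats["d_cca"]["sd"] == pytest.approx(np.sqrt(2))
        assert st.stats["d_cca"]["cv"] == pytest.approx(np.sqrt(2) / 9.0)

    def test_normal_cohort_recovery(self, rng):
        # emulate a population with CCA diameter 8.7 +/- 1.1 mm, n = 388
        vals = rng.normal(8.7, 1.1, size=388)
        reps = [GeometryReport(v, 7.5, 5.7, 7.5 / v, 5.7 / v, 49.5)
                for v in vals]
        st = cohort_stats(reps)
        assert st.stats["d_cca"]["mean"] == pytest.approx(8.7, abs=0.2)
        assert st.stats["d_cca"]["sd"] == pytest.approx(1.1, abs=0.2)

    def test_single_report_rejected(self):
        with pytest.raises(ValueError):
            cohort_stats([GeometryReport(8.0, 6.0, 4.0, 0.75, 0.5, 50.0)])
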