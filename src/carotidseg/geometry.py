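"""Geometric quantification of the carotid bifurcation.

Three descriptors per bifurcation, computed from the divided, length-
standardized label map: the mean diameter of each branch, the two
downstream/upstream diameter ratios (ICA/CCA, ECA/CCA) and the
bifurcation angle theta between the ICA and ECA centerline vectors.

Diameters follow the planar-area definition: at each centerline point, a
plane normal to the local tangent is sampled on a fine grid; the in-mask
area connected to the centerline point gives an equivalent-circle
diameter ``d = 2 sqrt(A/pi)``.  The angle is measured between vectors
from the branch point to the arc-length midpoint of each standardized
daughter centerline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .centerline import _arc_lengths, centerline_from_labels, smooth_centerline
from .io_core import LabelMap


@dataclass
class GeometryReport:
    """Per-bifurcation geometric descriptors (mm / degrees)."""

    d_cca: float
    d_ica: float
    d_eca: float
    ratio_ica_cca: float
    ratio_eca_cca: float
    theta: float
    profiles: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self):
        if min(self.d_cca, self.d_ica, self.d_eca) <= 0:
            raise ValueError("diameters must be positive")
        if not (0.0 <= self.theta <= 180.0):
            raise ValueError("theta must lie in [0, 180] degrees")
        for r, num in ((self.ratio_ica_cca, self.d_ica),
                       (self.ratio_eca_cca, self.d_eca)):
            if abs(r - num / self.d_cca) > 1e-9:
                raise ValueError("ratios inconsistent with stored diameters")

    PARAMS = ("d_cca", "d_ica", "d_eca", "ratio_ica_cca", "ratio_eca_cca",
              "theta")

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in self.PARAMS}


@dataclass
class CohortStats:
    """Mean, sample SD and coefficient of variation per parameter."""

    stats: dict[str, dict[str, float]]
    n: int

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.stats).T[["mean", "sd", "cv"]]


def diameter_profile(mask: LabelMap, centerline: np.ndarray,
                     end_exclusion_mm: float = 2.0,
                     pitch_frac: float = 0.25,
                     max_radius_mm: float = 8.0,
                     ) -> list[tuple[float, float]]:
    """Diameter along a centerline from normal-plane areas.

    At each centerline point (excluding ``end_exclusion_mm`` of arc
    length at both ends), the plane normal to the local tangent is
    sampled at a pitch of ``pitch_frac`` times the smallest voxel
    dimension out to ``max_radius_mm``.  The area is that of the in-mask
    in-plane connected component containing the centerline point — so a
    neighbouring branch crossing the plane is not counted — and the
    diameter assumes circularity: ``d = 2 sqrt(A/pi)``.  Centerline
    points falling outside the mask are skipped with a warning.
    """
    fg = np.asarray(mask.labels) > 0
    pts = np.asarray(centerline, dtype=float)
    if len(pts) < 3:
        raise ValueError("centerline needs >= 3 points")
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    shape = np.asarray(mask.shape)

    arc = _arc_lengths(pts)
    total = arc[-1]
    tangents = np.gradient(pts, arc, axis=0)

    pitch = pitch_frac * float(spacing.min())
    k = int(np.ceil(max_radius_mm / pitch))
    offs = np.arange(-k, k + 1) * pitch
    aa, bb = np.meshgrid(offs, offs, indexing="ij")

    profile: list[tuple[float, float]] = []
    skipped = 0
    for i in range(len(pts)):
        if arc[i] < end_exclusion_mm or total - arc[i] < end_exclusion_mm:
            continue
        t = tangents[i]
        norm = np.linalg.norm(t)
        if norm == 0:
            continue
        t = t / norm
        ref = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else \
            np.array([0.0, 1.0, 0.0])
        u = np.cross(t, ref)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        plane = (pts[i][None, None, :] + aa[..., None] * u[None, None, :]
                 + bb[..., None] * v[None, None, :])
        idx = np.rint((plane - origin) / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=-1)
        sample = np.zeros(aa.shape, dtype=bool)
        ii = idx[inside]
        sample[inside] = fg[ii[:, 0], ii[:, 1], ii[:, 2]]
        if not sample[k, k]:
            skipped += 1
            continue
        comp, _ = ndimage.label(sample, structure=np.ones((3, 3), dtype=bool))
        area = float(np.count_nonzero(comp == comp[k, k])) * pitch * pitch
        profile.append((float(arc[i]), 2.0 * np.sqrt(area / np.pi)))
    if skipped:
        warnings.warn(f"{skipped} centerline point(s) outside the mask were "
                      "skipped in the diameter profile")
    return profile


def mean_branch_diameter(profile) -> float:
    """Arithmetic mean of the profile diameters; errors on an empty profile."""
    if len(profile) == 0:
        raise ValueError("empty diameter profile")
    return float(np.mean([d for _, d in profile]))


def diameter_ratios(d_cca: float, d_ica: float, d_eca: float
                    ) -> tuple[float, float]:
    """Downstream/upstream diameter ratios (ICA/CCA, ECA/CCA)."""
    if d_cca <= 0:
        raise ValueError("d_cca must be positive")
    return d_ica / d_cca, d_eca / d_cca


def bifurcation_angle(ica_cl: np.ndarray, eca_cl: np.ndarray,
                      branch_point) -> float:
    """Angle (degrees) between centerline-aligned ICA and ECA vectors.

    Each vector runs from the branch's first centerline point (the one
    nearest the bifurcation) to the arc-length midpoint of that branch's
    standardized centerline.
    """
    vecs = []
    for cl in (ica_cl, eca_cl):
        cl = np.asarray(cl, dtype=float)
        if len(cl) < 3:
            raise ValueError("centerline needs >= 3 points")
        arc = _arc_lengths(cl)
        mid = np.array([np.interp(arc[-1] / 2.0, arc, cl[:, a])
                        for a in range(3)])
        v = mid - cl[0]
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("zero-length centerline vector")
        vecs.append(v / n)
    cosang = float(np.clip(np.dot(vecs[0], vecs[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def _truncate(points: np.ndarray, length_mm: float) -> np.ndarray:
    arc = _arc_lengths(points)
    return points[arc <= length_mm]


def _line_radius(line: np.ndarray, edt: np.ndarray, labels: LabelMap,
                 lo: float = 5.0, hi: float = 15.0) -> float:
    """Mean lumen radius along a centerline window, from the EDT."""
    arc = _arc_lengths(line)
    sel = (arc >= lo) & (arc <= hi)
    pts = line[sel] if np.count_nonzero(sel) >= 2 else line
    idx = np.clip(np.rint((pts - np.asarray(labels.origin))
                          / np.asarray(labels.spacing)).astype(int),
                  0, np.asarray(labels.shape) - 1)
    return float(np.mean(edt[tuple(idx.T)]))


def _match_daughters_to_labels(lines: dict[int, np.ndarray],
                               labels: LabelMap) -> dict[int, np.ndarray]:
    """Swap the ICA/ECA centerlines when the label map disagrees.

    Branch identity in the extracted tree uses the wider-daughter
    heuristic; when an annotated label map is available, the labels are
    authoritative, so each daughter centerline is matched to the class it
    actually runs through (majority vote away from the bulb)."""
    lab = np.asarray(labels.labels)
    if not ({2, 3} <= set(np.unique(lab))):
        return lines
    votes = {}
    for code in (2, 3):
        line = lines[code]
        arc = _arc_lengths(line)
        sel = arc >= 6.0
        pts = line[sel] if np.count_nonzero(sel) >= 3 else line
        idx = np.clip(np.rint((pts - np.asarray(labels.origin))
                              / np.asarray(labels.spacing)).astype(int),
                      0, np.asarray(labels.shape) - 1)
        vals = lab[tuple(idx.T)]
        vals = vals[np.isin(vals, (2, 3))]
        votes[code] = int(np.bincount(vals, minlength=4).argmax()) \
            if len(vals) else code
    if votes == {2: 3, 3: 2}:
        lines = {**lines, 2: lines[3], 3: lines[2]}
    return lines


def analyze_bifurcation(labels: LabelMap,
                        standard_length_mm: float = 20.0,
                        end_exclusion_mm: float = 2.0,
                        smooth_window: int = 9,
                        prune_mm: float = 3.0,
                        ica_side: str | None = None) -> GeometryReport:
    """Complete geometric analysis of a divided 3-class label map.

    Extracts branch centerlines from the foreground skeleton, smooths
    them, truncates them to the standard branch length (2 cm by default,
    matching the length standardization of the segmentations), measures
    per-branch diameter profiles within each branch's class mask, and
    computes mean diameters, the two ratios and the bifurcation angle.
    """
    present = set(np.unique(np.asarray(labels.labels))) - {0}
    if not {1, 2, 3} <= present:
        raise ValueError(f"need all three branch classes, found {sorted(present)}")
    tree, bp, lines = centerline_from_labels(labels, prune_mm=prune_mm,
                                             ica_side=ica_side)
    lines = _match_daughters_to_labels(lines, labels)

    # smooth and truncate once; measure everything on these centerlines
    std_lines: dict[int, np.ndarray] = {}
    for code in (1, 2, 3):
        w = min(smooth_window, len(lines[code]))
        w = w - 1 if w % 2 == 0 else w
        cl = smooth_centerline(lines[code], max(w, 1))
        std_lines[code] = _truncate(cl, standard_length_mm)
    theta = bifurcation_angle(std_lines[2], std_lines[3], bp)

    # The bulb and the merged daughter lumina make near-branch-point planes
    # meaningless for single-branch diameters: the profile starts where the
    # daughter tubes have separated (radii from the distance transform, the
    # measured angle for the separation arc), never earlier than the plain
    # end exclusion.
    spacing = np.asarray(labels.spacing)
    edt = ndimage.distance_transform_edt(np.asarray(labels.labels) > 0,
                                         sampling=spacing)
    radii = {code: _line_radius(std_lines[code], edt, labels)
             for code in (1, 2, 3)}
    half_sin = max(np.sin(np.radians(theta / 2.0)), 0.1)
    s_sep = float(np.clip((radii[2] + radii[3] + 1.0) / (2.0 * half_sin),
                          5.0, 15.0))

    names = {1: "cca", 2: "ica", 3: "eca"}
    diameters: dict[str, float] = {}
    profiles: dict[str, list[tuple[float, float]]] = {}
    for code, name in names.items():
        cl = std_lines[code]
        total = float(np.sum(np.linalg.norm(np.diff(cl, axis=0), axis=1)))
        start = s_sep if s_sep < total - end_exclusion_mm - 1.0 \
            else end_exclusion_mm
        class_mask = LabelMap((np.asarray(labels.labels) == code
                               ).astype(np.int16),
                              labels.spacing, labels.origin)
        prof = diameter_profile(class_mask, cl,
                                end_exclusion_mm=end_exclusion_mm)
        prof = [(a, d) for a, d in prof if a >= start] or prof
        if not prof:
            raise ValueError(f"no valid diameter samples on branch {name}")
        diameters[name] = mean_branch_diameter(prof)
        profiles[name] = prof
    r_ica, r_eca = diameter_ratios(diameters["cca"], diameters["ica"],
                                   diameters["eca"])
    return GeometryReport(diameters["cca"], diameters["ica"],
                          diameters["eca"], r_ica, r_eca, theta,
                          profiles=profiles)


def cohort_stats(reports: list[GeometryReport]) -> CohortStats:
    """Cohort-wide mean, sample SD (n-1) and CV = sd/mean per parameter."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports for cohort statistics")
    stats = {}
    for p in GeometryReport.PARAMS:
        vals = np.array([getattr(r, p) for r in reports], dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        stats[p] = {"mean": mean, "sd": sd,
                    "cv": sd / mean if mean != 0 else float("nan")}
    return CohortStats(stats, n=len(reports))
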