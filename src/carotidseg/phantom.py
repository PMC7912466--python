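"""Synthetic carotid-bifurcation phantoms with exactly known geometry.

The clinical angiography data this pipeline targets is not redistributable,
so every quantitative test in the repository runs on parametric phantoms:
a common carotid artery (CCA) running caudal→cranial (+z) to a branch
point, from which the internal (ICA) and external (ECA) carotids diverge
symmetrically about +z in the x–z plane with a prescribed bifurcation
angle.  The lumen is a varying-radius tube around each centerline; a
smooth bulb dilation at the bifurcation reproduces the carotid bulb, the
region that makes branch division genuinely hard.  Intensities emulate
bright-blood contrast-enhanced MRA: bright lumen on a dark background,
point-spread blur, additive Gaussian noise.  The label map is noise-free
truth, assigned by nearest centerline branch.

Default voxel spacing is 0.48 x 0.48 x 0.50 mm, the reconstructed
resolution of the acquisitions the phantoms emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .io_core import DEFAULT_SPACING, ImageVolume, LabelMap

#: arc-length step between consecutive centerline points (mm); kept below the
#: smallest voxel dimension so the rasterized tube has no gaps.
CENTERLINE_STEP_MM = 0.2

#: extent of the bulb dilation on either side of the branch point (mm).
BULB_EXTENT_MM = 5.0

#: cohort parameter ranges (mm / degrees): mean +/- 2 SD of the study
#: population (CCA 8.7+/-1.1, ICA 7.5+/-1.4, ECA 5.7+/-1.0, angle 49.5+/-13.4).
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "d_cca": (6.5, 10.9),
    "d_ica": (4.7, 10.3),
    "d_eca": (3.7, 7.7),
    "theta": (22.7, 76.3),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic bifurcation.

    Diameters are in mm, ``theta`` (the ICA–ECA bifurcation angle) in
    degrees. ``bulb_scale`` multiplies the local radius across the last
    5 mm of the CCA and first 5 mm of the ICA; ``tortuosity_amp`` adds a
    sinusoidal out-of-plane (y) undulation; ``stenosis_frac`` carves a
    Gaussian-profile diameter reduction at the ICA midpoint.
    """

    d_cca: float = 8.7
    d_ica: float = 7.5
    d_eca: float = 5.7
    theta: float = 50.0
    branch_length: float = 30.0
    bulb_scale: float = 1.2
    tortuosity_amp: float = 0.0
    stenosis_frac: float = 0.0
    lumen_intensity: float = 1000.0
    background_intensity: float = 100.0
    blur_sigma_mm: float = 0.5
    noise_sd: float = 20.0
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_cca", "d_ica", "d_eca"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.theta < 180.0):
            raise ValueError(f"theta={self.theta} outside [0, 180)")
        if not (0.0 <= self.stenosis_frac < 1.0):
            raise ValueError("stenosis_frac must be in [0, 1)")
        if self.bulb_scale < 1.0:
            raise ValueError("bulb_scale must be >= 1")
        if self.branch_length <= 0:
            raise ValueError("branch_length must be positive")
        limit = self.d_cca * self.bulb_scale
        if self.d_ica > limit or self.d_eca > limit:
            raise ValueError(
                f"daughter diameters ({self.d_ica}, {self.d_eca}) exceed "
                f"d_cca * bulb_scale = {limit:.2f}; geometrically infeasible")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class BifurcationModel:
    """Three branch centerlines plus the branch point, in physical mm.

    Each centerline is an ``(n, 3)`` array ordered away from the branch
    point (first point nearest the branch point, arc length strictly
    increasing).
    """

    cca_centerline: np.ndarray
    ica_centerline: np.ndarray
    eca_centerline: np.ndarray
    branch_point: np.ndarray
    radii: dict[str, np.ndarray] = field(default_factory=dict)

    def branches(self) -> dict[int, np.ndarray]:
        """Centerlines keyed by label code (1 CCA, 2 ICA, 3 ECA)."""
        return {1: self.cca_centerline, 2: self.ica_centerline,
                3: self.eca_centerline}

    def validate(self) -> None:
        for code, pts in self.branches().items():
            if len(pts) < 2:
                raise ValueError(f"branch {code} has fewer than 2 points")
            steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if np.any(steps <= 0):
                raise ValueError(f"branch {code} arc length not increasing")
            d = np.linalg.norm(pts - self.branch_point, axis=1)
            if np.argmin(d) != 0:
                raise ValueError(f"branch {code} first point is not the one "
                                 "nearest the branch point")


def _bulb_factor(s: np.ndarray, bulb_scale: float) -> np.ndarray:
    """Smooth radial dilation: ``bulb_scale`` at the branch point (s=0),
    decaying with a raised-cosine window to 1 at ``s >= BULB_EXTENT_MM``."""
    w = np.zeros_like(s)
    inside = s < BULB_EXTENT_MM
    w[inside] = 0.5 * (1.0 + np.cos(np.pi * s[inside] / BULB_EXTENT_MM))
    return 1.0 + (bulb_scale - 1.0) * w


def make_centerline_tree(spec: PhantomSpec) -> BifurcationModel:
    """Analytic centerline tree for a phantom spec.

    The branch point sits at the mm origin.  The CCA descends along −z;
    ICA and ECA ascend in the x–z plane at ±theta/2 from +z (ICA on +x),
    so the angle between their initial direction vectors is exactly
    ``spec.theta``.  Optional sinusoidal tortuosity is superimposed along
    y (orthogonal to the bifurcation plane), vanishing at the branch
    point.  Radii along arc length (bulb, optional ICA stenosis) are
    stored per branch for rasterization.
    """
    bp = np.zeros(3)
    L = spec.branch_length
    n = max(2, int(np.ceil(L / CENTERLINE_STEP_MM)) + 1)
    s = np.linspace(0.0, L, n)

    half = np.deg2rad(spec.theta / 2.0)
    dirs = {
        1: np.array([0.0, 0.0, -1.0]),
        2: np.array([np.sin(half), 0.0, np.cos(half)]),
        3: np.array([-np.sin(half), 0.0, np.cos(half)]),
    }
    wiggle = spec.tortuosity_amp * np.sin(2.0 * np.pi * s / L)

    lines: dict[int, np.ndarray] = {}
    for code, d in dirs.items():
        pts = bp[None, :] + s[:, None] * d[None, :]
        pts = pts + wiggle[:, None] * np.array([0.0, 1.0, 0.0])[None, :]
        lines[code] = pts

    radii = {
        "cca": 0.5 * spec.d_cca * _bulb_factor(s, spec.bulb_scale),
        "ica": 0.5 * spec.d_ica * _bulb_factor(s, spec.bulb_scale),
        "eca": np.full(n, 0.5 * spec.d_eca),
    }
    if spec.stenosis_frac > 0:
        mid = L / 2.0
        radii["ica"] = radii["ica"] * (
            1.0 - spec.stenosis_frac * np.exp(-((s - mid) ** 2) / (2 * 2.0**2)))

    model = BifurcationModel(lines[1], lines[2], lines[3], bp, radii)
    model.validate()
    return model


def _stacked_centerline(model: BifurcationModel):
    """All centerline points with per-point branch code and radius."""
    key = {1: "cca", 2: "ica", 3: "eca"}
    pts, codes, rads = [], [], []
    for code, line in model.branches().items():
        r = model.radii.get(key[code])
        if r is None or len(r) != len(line):
            raise ValueError("model is missing per-point radii; build it with "
                             "make_centerline_tree")
        pts.append(line)
        codes.append(np.full(len(line), code, dtype=np.int16))
        rads.append(np.asarray(r, dtype=float))
    return np.vstack(pts), np.concatenate(codes), np.concatenate(rads)


def rasterize_phantom(model: BifurcationModel, spec: PhantomSpec,
                      shape: tuple[int, int, int] | None = None,
                      origin: tuple[float, float, float] | None = None,
                      ) -> tuple[ImageVolume, LabelMap]:
    """Render a centerline tree to an intensity volume and truth label map.

    A voxel belongs to the lumen when its centre lies within the local
    radius of the *nearest* centerline point, and is labelled with that
    point's branch — the same nearest-centerline rule the branch-division
    stage uses, so phantom truth and automatic division agree by
    construction away from the bulb.  The intensity image is piecewise
    constant (lumen/background), Gaussian-blurred by ``blur_sigma_mm``
    and corrupted with seeded additive Gaussian noise.  The label map is
    noise-free truth and independent of ``noise_sd``.
    """
    pts, codes, rads = _stacked_centerline(model)
    spacing = np.asarray(spec.spacing, dtype=float)
    margin = float(rads.max()) + 3.0 * spec.blur_sigma_mm + 2.0

    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    if origin is None:
        # anchor the grid so the branch point sits at a fixed, non-central
        # fractional voxel position: a real scan's lattice is never aligned
        # with the vessel's symmetry planes, and exactly symmetric tubes are
        # a degenerate input for thinning-based skeletonization
        frac = np.array([0.28, 0.34, 0.41])
        bp = np.asarray(model.branch_point, dtype=float)
        n = np.ceil((bp - lo) / spacing - frac)
        origin = tuple(bp - (n + frac) * spacing)
    if shape is None:
        shape = tuple(int(np.ceil((hi[i] - origin[i]) / spacing[i])) + 1
                      for i in range(3))
    else:
        covered = np.asarray(origin) + (np.asarray(shape) - 1) * spacing
        if np.any(np.asarray(origin) > lo) or np.any(covered < hi):
            raise ValueError(
                f"grid too small for the model: need origin <= {tuple(lo)} "
                f"and extent >= {tuple(hi)} mm")

    ix = np.arange(shape[0]) * spacing[0] + origin[0]
    iy = np.arange(shape[1]) * spacing[1] + origin[1]
    iz = np.arange(shape[2]) * spacing[2] + origin[2]
    xx, yy, zz = np.meshgrid(ix, iy, iz, indexing="ij")
    centers = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)

    tree = cKDTree(pts)
    dist, idx = tree.query(centers, k=1, workers=-1)
    lumen = dist <= rads[idx]
    labels = np.zeros(len(centers), dtype=np.int16)
    labels[lumen] = codes[idx[lumen]]
    labels = labels.reshape(shape)

    img = np.where(labels > 0, spec.lumen_intensity,
                   spec.background_intensity).astype(np.float64)
    if spec.blur_sigma_mm > 0:
        img = gaussian_filter(img, sigma=spec.blur_sigma_mm / spacing)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    vol = ImageVolume(img.astype(np.float32), tuple(spacing), tuple(origin))
    lm = LabelMap(labels, tuple(spacing), tuple(origin))
    return vol, lm


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelMap,
                                                 BifurcationModel]:
    """Convenience: centerline tree + rasterization in one call."""
    model = make_centerline_tree(spec)
    vol, lm = rasterize_phantom(model, spec)
    return vol, lm, model


def sample_cohort(n: int,
                  ranges: dict[str, tuple[float, float]] | None = None,
                  seed: int = 0,
                  base: PhantomSpec | None = None) -> list[PhantomSpec]:
    """Draw ``n`` independent phantom specs uniformly within parameter ranges.

    Default ranges span the study population mean ± 2 SD for the branch
    diameters and the bifurcation angle; draws violating geometric
    feasibility (daughter diameter above ``d_cca * bulb_scale``) are
    rejected and redrawn.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_COHORT_RANGES if ranges is None else ranges)
    unknown = set(ranges) - set(DEFAULT_COHORT_RANGES)
    if unknown:
        raise ValueError(f"unknown cohort parameters: {sorted(unknown)}")
    for k, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"range for {k} is empty: ({lo}, {hi})")
    base = base if base is not None else PhantomSpec()
    if ranges.get("d_ica", (0, 0))[0] > ranges.get(
            "d_cca", (base.d_cca, base.d_cca))[1] * base.bulb_scale:
        raise ValueError("infeasible range combination: every d_ica exceeds "
                         "the largest feasible d_cca * bulb_scale")

    rng = np.random.default_rng(seed)
    cohort: list[PhantomSpec] = []
    for i in range(n):
        for _ in range(1000):
            draw = {k: float(rng.uniform(lo, hi))
                    for k, (lo, hi) in ranges.items()}
            child_seed = int(rng.integers(0, 2**31 - 1))
            try:
                cohort.append(replace(base, seed=child_seed, **draw))
                break
            except ValueError:
                continue
        else:
            raise ValueError("infeasible range combination: could not draw a "
                             "feasible spec in 1000 attempts")
    return cohort
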