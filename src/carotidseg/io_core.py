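"""Domain types, volume I/O and configuration for the carotid pipeline.

Axis convention (fixed, never inferred from content): arrays are indexed
``(x, y, z)`` where

* ``x`` — left–right (sagittal axis; the sagittal split cuts along it),
* ``y`` — anterior–posterior,
* ``z`` — inferior–superior (the CCA runs caudal→cranial, i.e. along +z).

All geometric computation downstream happens in physical millimetres:
``mm = origin + index * spacing``, with ``spacing`` in mm per voxel along
each axis.  Volumes are stored as NIfTI (.nii / .nii.gz) with a diagonal
affine carrying spacing and origin.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger("carotidseg")

#: Integer label codes shared by every module.
CODE_TABLE: Mapping[int, str] = {0: "background", 1: "CCA", 2: "ICA", 3: "ECA"}

#: Default voxel spacing in mm (x, y, z) — the reconstructed resolution the
#: phantom generator emulates.
DEFAULT_SPACING = (0.48, 0.48, 0.50)


def _as_triple(value, name: str) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).ravel()
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 components, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular anisotropic grid.

    Parameters
    ----------
    data : ndarray, shape (Nx, Ny, Nz)
        Scalar intensities, arbitrary units.
    spacing : (sx, sy, sz)
        Voxel size in mm along x, y, z.  All components must be positive.
    origin : (ox, oy, oz)
        Physical mm position of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_mm(self, idx) -> np.ndarray:
        """Physical mm coordinates of (fractional) voxel indices, shape (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def mm_to_index(self, pos) -> np.ndarray:
        """Fractional voxel indices of physical mm positions, shape (..., 3)."""
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class LabelMap:
    """Integer-coded multi-class mask on the same grid as an :class:`ImageVolume`.

    Codes follow :data:`CODE_TABLE`: 0 background, 1 CCA, 2 ICA, 3 ECA.
    Six-class bilateral maps (4/5/6 for the right side) are accepted only as
    input to the sagittal split, which remaps them to 3 foreground classes
    per side.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    code_table: Mapping[int, str] = field(default_factory=lambda: dict(CODE_TABLE))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D label map, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(np.asarray(self.labels, dtype=float))
            if not np.allclose(self.labels, rounded, atol=1e-6):
                raise ValueError("label map must contain integers")
            self.labels = rounded.astype(np.int16)
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def validate_codes(self) -> None:
        present = np.unique(self.labels)
        unknown = [int(v) for v in present if int(v) not in self.code_table]
        if unknown:
            raise ValueError(f"label codes {unknown} not in code table "
                             f"{sorted(self.code_table)}")

    def foreground(self) -> np.ndarray:
        """Boolean mask of the foreground union (all non-background classes)."""
        return self.labels > 0

    def class_mask(self, code: int) -> np.ndarray:
        return self.labels == code

    index_to_mm = ImageVolume.index_to_mm
    mm_to_index = ImageVolume.mm_to_index
    voxel_volume = ImageVolume.voxel_volume


def same_grid(a, b, atol: float = 1e-6) -> bool:
    """True when two volumes/label maps share shape, spacing and origin."""
    return (a.shape == b.shape
            and np.allclose(a.spacing, b.spacing, atol=atol)
            and np.allclose(a.origin, b.origin, atol=atol))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _load_nifti(path: str):
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types for bad headers
        raise ValueError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return data, spacing, origin


def read_volume(path: str) -> ImageVolume:
    """Load a 3D scalar NIfTI volume; spacing and origin come from the header."""
    data, spacing, origin = _load_nifti(path)
    return ImageVolume(np.asarray(data, dtype=np.float32), spacing, origin)


def write_volume(vol: ImageVolume, path: str) -> None:
    """Write a volume as NIfTI; deterministic serialization (re-read == written)."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                          _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, path)


def read_label_map(path: str) -> LabelMap:
    """Load an integer-coded label map from NIfTI and validate its codes."""
    data, spacing, origin = _load_nifti(path)
    lm = LabelMap(np.asarray(np.rint(data), dtype=np.int16), spacing, origin)
    return lm


def write_label_map(labels: LabelMap, path: str) -> None:
    img = nib.Nifti1Image(np.asarray(labels.labels, dtype=np.int16),
                          _affine(labels.spacing, labels.origin))
    img.header.set_zooms(labels.spacing)
    nib.save(img, path)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------
# Every numeric default of the pipeline lives in this schema:
# section -> key -> (default, lower bound, upper bound, inclusive-upper?).
# Bounds of None are unchecked; list-valued keys are validated elementwise.

_INF = float("inf")

CONFIG_SCHEMA: dict[str, dict[str, tuple]] = {
    "phantom": {
        "d_cca": (8.7, 0.0, 30.0, False),
        "d_ica": (7.5, 0.0, 30.0, False),
        "d_eca": (5.7, 0.0, 30.0, False),
        "theta": (50.0, 0.0, 180.0, False),
        "branch_length": (30.0, 1.0, 200.0, True),
        "bulb_scale": (1.2, 1.0, 2.0, True),
        "tortuosity_amp": (0.0, 0.0, 10.0, True),
        "stenosis_frac": (0.0, 0.0, 1.0, False),
        "lumen_intensity": (1000.0, None, None, True),
        "background_intensity": (100.0, None, None, True),
        "blur_sigma_mm": (0.5, 0.0, 5.0, True),
        "noise_sd": (20.0, 0.0, _INF, True),
        "spacing": (list(DEFAULT_SPACING), 0.0, 10.0, False),
        "seed": (0, 0, 2**31 - 1, True),
    },
    "preprocess": {
        "mirror_right": (False, None, None, True),
    },
    "network": {
        "pathway_subsampling": ([1, 3, 5], 1, 16, True),
        "n_layers_conv": (8, 1, 16, True),
        "beta": (2.0, 0.0, 10.0, True),
        "n_classes": (4, 2, 16, True),
        "loss_variant": ("precision_recall", None, None, True),
    },
    "training": {
        "epochs": (20, 1, 10000, True),
        "batch_size": (8, 1, 1024, True),
        "segments_per_volume": (64, 1, 100000, True),
        "foreground_fraction": (0.5, 0.0, 1.0, False),
        "optimizer": ("adam", None, None, True),  # adam | sgd
        "learning_rate": (0.003, 0.0, 10.0, False),
        "momentum": (0.9, 0.0, 1.0, False),
        "lr_decay": (0.97, 0.0, 1.0, True),
        "seed": (0, 0, 2**31 - 1, True),
    },
    "postprocess": {
        "connectivity": (26, None, None, True),   # 6 or 26, checked specially
        "crop_radius_mm": (20.0, 0.0, 1000.0, False),
    },
    "geometry": {
        "standard_length_mm": (20.0, 0.0, 200.0, False),
        "end_exclusion_mm": (2.0, 0.0, 50.0, True),
        "profile_pitch_frac": (0.25, 0.0, 1.0, True),
        "profile_max_radius_mm": (8.0, 1.0, 50.0, True),
        "smooth_window": (9, 1, 99, True),
        "prune_mm": (3.0, 0.0, 50.0, True),
    },
}


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run, one namespace per stage."""

    phantom: SimpleNamespace
    preprocess: SimpleNamespace
    network: SimpleNamespace
    training: SimpleNamespace
    postprocess: SimpleNamespace
    geometry: SimpleNamespace

    def as_dict(self) -> dict:
        return {name: dict(vars(getattr(self, name))) for name in CONFIG_SCHEMA}


def _check_range(section: str, key: str, value, lo, hi, hi_incl: bool):
    vals = value if isinstance(value, (list, tuple)) else [value]
    for v in vals:
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise ValueError(f"{section}.{key}: expected a number, got {v!r}")
        if lo is not None and v < lo:
            raise ValueError(f"{section}.{key}={v} out of range "
                             f"[{lo}, {hi}{']' if hi_incl else ')'}")
        if hi is not None and (v > hi if hi_incl else v >= hi):
            raise ValueError(f"{section}.{key}={v} out of range "
                             f"[{lo}, {hi}{']' if hi_incl else ')'}")


def _validate_section(section: str, user: dict) -> SimpleNamespace:
    schema = CONFIG_SCHEMA[section]
    unknown = set(user) - set(schema)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in section '{section}'; "
                         f"permitted: {sorted(schema)}")
    out = {}
    for key, (default, lo, hi, hi_incl) in schema.items():
        value = user.get(key, default)
        if isinstance(default, bool):
            if not isinstance(value, bool):
                raise ValueError(f"{section}.{key}: expected true/false")
        elif isinstance(default, str):
            pass
        else:
            _check_range(section, key, value, lo, hi, hi_incl)
        out[key] = value
    if section == "postprocess" and out["connectivity"] not in (6, 26):
        raise ValueError("postprocess.connectivity must be 6 or 26")
    if section == "network":
        if 1 not in out["pathway_subsampling"]:
            raise ValueError("network.pathway_subsampling must contain the "
                             "full-resolution factor 1")
        if out["loss_variant"] not in ("precision_recall",
                                       "specificity_sensitivity"):
            raise ValueError("network.loss_variant must be 'precision_recall' "
                             "or 'specificity_sensitivity'")
    if section == "training" and out["optimizer"] not in ("adam", "sgd"):
        raise ValueError("training.optimizer must be 'adam' or 'sgd'")
    if section == "geometry" and out["smooth_window"] % 2 == 0:
        raise ValueError("geometry.smooth_window must be odd")
    return SimpleNamespace(**out)


def default_config() -> PipelineConfig:
    return load_config(None)


def load_config(path: str | None) -> PipelineConfig:
    """Load a YAML config file, reject unknown keys, validate ranges, fill defaults.

    ``path=None`` (or an empty file) yields all documented defaults.  The
    effective configuration is logged so every run records its parameters.
    """
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config root must be a mapping, got {type(user)}")
    unknown = set(user) - set(CONFIG_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config section(s) {sorted(unknown)}; "
                         f"permitted: {sorted(CONFIG_SCHEMA)}")
    sections = {name: _validate_section(name, user.get(name, {}) or {})
                for name in CONFIG_SCHEMA}
    cfg = PipelineConfig(**sections)
    logger.info("effective config: %s", cfg.as_dict())
    return cfg
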