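"""Intensity normalization and sagittal left/right splitting.

Volumes are z-normalized to zero mean and unit variance over all voxels,
then divided in the sagittal plane and processed one side at a time,
reducing a bilateral 6-class problem to 3 foreground classes per side.
"""

from __future__ import annotations

import numpy as np

from .io_core import ImageVolume, LabelMap, same_grid


def znormalize(vol: ImageVolume) -> ImageVolume:
    """Return a copy with zero mean and unit variance over all voxels.

    Raises on a constant volume (zero variance undefined).  Spacing and
    origin are unchanged; normalization is idempotent to float tolerance.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if data.size <= 1:
        raise ValueError("volume must have more than one voxel")
    sd = data.std()
    if sd == 0:
        raise ValueError("zero variance: cannot normalize a constant volume")
    out = (data - data.mean()) / sd
    return ImageVolume(out, vol.spacing, vol.origin)


def _split_array(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    nx = arr.shape[0]
    if nx < 2:
        raise ValueError("x-axis extent must be >= 2 to split")
    mid = nx // 2
    return arr[:mid], arr[mid:], mid


def _remap_six_class(labels: np.ndarray) -> np.ndarray:
    """Map right-side codes 4/5/6 (CCA/ICA/ECA) down to 1/2/3."""
    out = labels.copy()
    high = out >= 4
    out[high] = out[high] - 3
    return out


def split_sagittal(vol: ImageVolume, labels: LabelMap | None = None,
                   mirror_right: bool = False):
    """Split a volume (and optional label map) into left and right halves.

    The cut is half-open at ``floor(Nx/2)``: left = columns ``[0, mid)``,
    right = ``[mid, Nx)``, so the halves tile the volume exactly.  Each
    half keeps a corrected origin, preserving physical mm coordinates.
    Six-class bilateral label maps are remapped to codes 1–3 per side.
    With ``mirror_right`` the right half is flipped along x so both sides
    present the same chirality (its origin then refers to the flipped
    grid; mm coordinates of the mirrored half are not preserved, which is
    why the flag defaults to off).

    Returns ``(left_vol, right_vol)`` or, with labels,
    ``((left_vol, left_labels), (right_vol, right_labels))``.
    """
    if labels is not None and not same_grid(vol, labels):
        raise ValueError("volume and label map are on different grids")
    lv, rv, mid = _split_array(vol.data)
    right_origin = (vol.origin[0] + mid * vol.spacing[0],
                    vol.origin[1], vol.origin[2])
    left = ImageVolume(lv.copy(), vol.spacing, vol.origin)
    right = ImageVolume(rv.copy() if not mirror_right else rv[::-1].copy(),
                        vol.spacing, right_origin)
    if labels is None:
        return left, right
    ll, rl, _ = _split_array(labels.labels)
    rl = rl if not mirror_right else rl[::-1]
    if labels.labels.max() > 3:
        ll, rl = _remap_six_class(ll), _remap_six_class(rl)
    left_lm = LabelMap(ll.copy(), labels.spacing, vol.origin)
    right_lm = LabelMap(rl.copy(), labels.spacing, right_origin)
    return (left, left_lm), (right, right_lm)
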