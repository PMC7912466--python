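"""Label-map post-processing: component cleanup, boundary smoothing, radial crop.

Raw network output is cleaned in three stages: (1) per class, every
connected component other than the largest is merged into an adjacent
non-background class or removed; (2) per-class morphological opening and
closing with a 2x2x2 structuring element smooths the inter-class
boundaries in the bulb while preserving the foreground union exactly;
(3) foreground farther than a physical radius (default 20 mm) from the
bifurcation centre is cropped away, standardizing the analysed extent.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .io_core import LabelMap

_FOREGROUND_CODES = (1, 2, 3)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def component_cleanup(labels: LabelMap, connectivity: int = 26) -> LabelMap:
    """Keep one connected component per class; merge or drop the rest.

    For each foreground class, components other than the largest are
    relabeled to an adjacent non-background class when one exists —
    choosing, among several, the class with the largest contact surface
    (ties broken by lowest class code) — and removed otherwise.  The rule
    is iterated to a fixed point (merging can re-partition components);
    any class still split after that keeps only its largest component,
    guaranteeing exactly one component per present class.
    """
    struct = _structure(connectivity)
    out = labels.labels.copy()
    for _ in range(10):
        changed = False
        for code in _FOREGROUND_CODES:
            mask = out == code
            if not mask.any():
                continue
            comp, ncomp = ndimage.label(mask, structure=struct)
            if ncomp <= 1:
                continue
            sizes = np.bincount(comp.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1
            for ci in range(1, ncomp + 1):
                if ci == keep:
                    continue
                frag = comp == ci
                halo = ndimage.binary_dilation(frag, structure=struct) & ~frag
                contact = {c: int(np.count_nonzero(out[halo] == c))
                           for c in _FOREGROUND_CODES if c != code}
                contact = {c: n for c, n in contact.items() if n > 0}
                if contact:
                    best = max(sorted(contact), key=lambda c: contact[c])
                    out[frag] = best
                else:
                    out[frag] = 0
                changed = True
        if not changed:
            break
    else:  # still churning: enforce the postcondition directly
        for code in _FOREGROUND_CODES:
            mask = out == code
            if not mask.any():
                continue
            comp, ncomp = ndimage.label(mask, structure=struct)
            if ncomp > 1:
                sizes = np.bincount(comp.ravel())[1:]
                keep = int(np.argmax(sizes)) + 1
                out[mask & (comp != keep)] = 0
    return LabelMap(out, labels.spacing, labels.origin)


def boundary_smoothing(labels: LabelMap) -> LabelMap:
    """Open+close each class with a 2x2x2 element; preserve the foreground union.

    Each class mask is opened then closed (the composite is a
    reference-point-independent set operation, so the even element
    introduces no net shift).  Within the original foreground union,
    voxels claimed by several classes after closing go to the class with
    the nearest centroid; voxels vacated by every class return to the
    nearest original class (Euclidean mm distance, ties to the lowest
    class code).  Voxels the closing would add outside the original union
    are discarded, so the union — and the foreground voxel count — is
    unchanged.
    """
    s2 = np.ones((2, 2, 2), dtype=bool)
    lab = labels.labels
    union = lab > 0
    if not union.any():
        return LabelMap(lab.copy(), labels.spacing, labels.origin)
    spacing = np.asarray(labels.spacing)

    smoothed, centroids, edt = {}, {}, {}
    pad = 2
    for code in _FOREGROUND_CODES:
        mask = lab == code
        if not mask.any():
            continue
        m = np.pad(mask, pad)
        m = ndimage.binary_closing(ndimage.binary_opening(m, s2), s2)
        smoothed[code] = m[pad:-pad, pad:-pad, pad:-pad]
        centroids[code] = np.asarray(ndimage.center_of_mass(mask)) * spacing
        edt[code] = ndimage.distance_transform_edt(~mask, sampling=spacing)

    codes = sorted(smoothed)
    claims = np.stack([smoothed[c] for c in codes])
    n_claims = claims.sum(axis=0)
    out = np.zeros_like(lab)

    single = (n_claims == 1) & union
    for i, c in enumerate(codes):
        out[single & claims[i]] = c

    multi = (n_claims > 1) & union
    if multi.any():
        idx = np.argwhere(multi)
        pos = idx * spacing  # origin cancels in distance comparison
        dists = []
        for i, c in enumerate(codes):
            d = np.linalg.norm(pos - centroids[c], axis=1)
            d[~claims[i][multi]] = np.inf
            dists.append(d)
        winner = np.argmin(np.stack(dists), axis=0)  # first minimum: lowest code
        out[tuple(idx.T)] = np.asarray(codes)[winner]

    vacated = (n_claims == 0) & union
    if vacated.any():
        dstack = np.stack([edt[c][vacated] for c in codes])
        winner = np.argmin(dstack, axis=0)
        out[vacated] = np.asarray(codes)[winner]

    return LabelMap(out, labels.spacing, labels.origin)


def crop_to_bulb(labels: LabelMap, center_mm, radius_mm: float = 20.0) -> LabelMap:
    """Set foreground farther than ``radius_mm`` (Euclidean, physical mm)
    from ``center_mm`` to background.  The centre must lie inside the volume."""
    center = np.asarray(center_mm, dtype=float)
    idx = labels.mm_to_index(center)
    shape = np.asarray(labels.shape)
    if np.any(idx < -0.5) or np.any(idx > shape - 0.5):
        raise ValueError(f"crop centre {tuple(center)} mm (index {tuple(idx)}) "
                         "lies outside the volume")
    spacing = np.asarray(labels.spacing)
    origin = np.asarray(labels.origin)
    grids = np.meshgrid(*(np.arange(n) * s + o - c for n, s, o, c in
                          zip(labels.shape, spacing, origin, center)),
                        indexing="ij")
    dist2 = sum(g * g for g in grids)
    out = labels.labels.copy()
    out[(dist2 > radius_mm**2) & (out > 0)] = 0
    return LabelMap(out, labels.spacing, labels.origin)


def full_postprocess(labels: LabelMap, center_mm, radius_mm: float = 20.0,
                     connectivity: int = 26) -> LabelMap:
    """The complete chain: component cleanup, boundary smoothing, radial crop."""
    out = component_cleanup(labels, connectivity=connectivity)
    out = boundary_smoothing(out)
    out = crop_to_bulb(out, center_mm, radius_mm)
    return out
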