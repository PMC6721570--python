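"""Geometric descriptors of the tumor mask: volume, surface area,
box-counting fractal dimension and porosity."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..volume import ROIMask

__all__ = ["shape_features"]


def _surface_area_faces(mask: np.ndarray, spacing) -> float:
    """Surface area by counting exposed voxel faces.

    A face is exposed when the neighbour across it is background (or out of
    bounds). Each axis contributes faces of area = product of the other two
    spacings.
    """
    m = mask.astype(np.int8)
    area = 0.0
    face_areas = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    for axis, fa in enumerate(face_areas):
        padded = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.abs(np.diff(padded, axis=axis))
        area += fa * diff.sum()
    return float(area)


def _box_count(mask: np.ndarray, size: int) -> int:
    """Number of size³ boxes on a regular grid containing ≥ 1 mask voxel."""
    pads = [(0, (-s) % size) for s in mask.shape]
    m = np.pad(mask, pads)
    sh = (
        m.shape[0] // size, size,
        m.shape[1] // size, size,
        m.shape[2] // size, size,
    )
    blocks = m.reshape(sh).any(axis=(1, 3, 5))
    return int(blocks.sum())


def _fractal_dimension(mask: np.ndarray) -> float:
    """Box-counting dimension: least-squares slope of log N(s) vs log(1/s)
    over dyadic box sizes. Boxes are anchored to the mask bounding box so
    the value is translation invariant."""
    idx = np.nonzero(mask)
    lo = [int(a.min()) for a in idx]
    hi = [int(a.max()) + 1 for a in idx]
    mask = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    max_size = max(1, min(mask.shape) // 2)
    sizes = [s for s in (1, 2, 4, 8, 16, 32) if s <= max_size]
    if len(sizes) < 2:
        sizes = [1, 2]
    counts = np.array([_box_count(mask, s) for s in sizes], dtype=float)
    logs = np.log(1.0 / np.array(sizes, dtype=float))
    slope, _ = np.polyfit(logs, np.log(counts), 1)
    return float(slope)


def shape_features(mask: ROIMask) -> dict[str, float]:
    """Four shape descriptors from the binary mask and its voxel spacing."""
    m = mask.values
    sp = mask.spacing_mm
    voxel_vol = sp[0] * sp[1] * sp[2]
    n = int(m.sum())
    filled = ndimage.binary_fill_holes(m)
    n_filled = int(filled.sum())
    porosity = (n_filled - n) / n_filled if n_filled else 0.0
    return {
        "shape_volume_mm3": n * voxel_vol,
        "shape_surface_area_mm2": _surface_area_faces(m, sp),
        "shape_fractal_dimension": _fractal_dimension(m),
        "shape_porosity": float(porosity),
    }
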