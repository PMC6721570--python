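"""The 45-feature radiomic vector: 4 shape + 6 intensity + 19 GLCM +
11 GLSZM + 5 NGTDM descriptors of a tumor ROI."""

from __future__ import annotations

import numpy as np

from ..volume import ImageVolume, ROIMask, quantize_gray_levels
from .intensity import intensity_features
from .shape import shape_features
from .texture import (
    GLCM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
    compute_glcm,
    compute_glszm,
    compute_ngtdm,
    glcm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "RADIOMIC_FEATURE_NAMES",
    "extract_all",
    "shape_features",
    "intensity_features",
    "compute_glcm",
    "glcm_features",
    "compute_glszm",
    "glszm_features",
    "compute_ngtdm",
    "ngtdm_features",
]

SHAPE_FEATURE_NAMES = [
    "shape_volume_mm3",
    "shape_surface_area_mm2",
    "shape_fractal_dimension",
    "shape_porosity",
]
INTENSITY_FEATURE_NAMES = [
    "intensity_mean",
    "intensity_variance",
    "intensity_skewness",
    "intensity_kurtosis",
    "intensity_energy",
    "intensity_entropy",
]

#: Canonical ordering of the 45 radiomic features.
RADIOMIC_FEATURE_NAMES: list[str] = (
    SHAPE_FEATURE_NAMES
    + INTENSITY_FEATURE_NAMES
    + GLCM_FEATURE_NAMES
    + GLSZM_FEATURE_NAMES
    + NGTDM_FEATURE_NAMES
)
assert len(RADIOMIC_FEATURE_NAMES) == 45


def extract_all(
    volume: ImageVolume, mask: ROIMask, n_gray_levels: int = 32
) -> dict[str, float]:
    """Extract the full 45-feature radiomic vector from a preprocessed
    (resampled, normalized) volume and its ROI mask.

    Returns the features in canonical order. Any non-finite value raises —
    a silent NaN never propagates into the feature table.
    """
    out: dict[str, float] = {}
    out.update(shape_features(mask))
    out.update(intensity_features(volume, mask, n_bins=n_gray_levels))
    q = quantize_gray_levels(volume, mask, n_gray_levels)
    out.update(glcm_features(compute_glcm(q)))
    out.update(glszm_features(compute_glszm(q)))
    out.update(ngtdm_features(compute_ngtdm(q)))
    vec = {name: out[name] for name in RADIOMIC_FEATURE_NAMES}
    bad = [k for k, v in vec.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite radiomic feature(s): {bad}")
    return vec
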