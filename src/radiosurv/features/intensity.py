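"""First-order intensity statistics over the in-mask voxels."""

from __future__ import annotations

import numpy as np

from ..volume import ImageVolume, ROIMask

__all__ = ["intensity_features"]


def intensity_features(
    volume: ImageVolume, mask: ROIMask, n_bins: int = 32
) -> dict[str, float]:
    """Mean, variance, skewness, kurtosis, energy and entropy of the ROI.

    Population-form moments (kurtosis non-excess). Energy is the mean squared
    intensity. Entropy is Shannon entropy (bits) of a ``n_bins``-bin uniform
    histogram over the in-mask intensity range, mirroring the gray-level
    quantization. A constant ROI gets skewness = kurtosis = 0 by convention.
    """
    x = volume.intensities[mask.values].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    if var > 0:
        std = np.sqrt(var)
        z = (x - mean) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew = 0.0
        kurt = 0.0
    energy = float(np.mean(x**2))
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        entropy = 0.0
    else:
        idx = np.minimum(
            np.floor(n_bins * (x - lo) / (hi - lo)).astype(int), n_bins - 1
        )
        h = np.bincount(idx, minlength=n_bins) / n
        nz = h[h > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
    return {
        "intensity_mean": mean,
        "intensity_variance": var,
        "intensity_skewness": skew,
        "intensity_kurtosis": kurt,
        "intensity_energy": energy,
        "intensity_entropy": entropy,
    }
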