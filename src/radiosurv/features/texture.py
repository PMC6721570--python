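"""3D texture matrices and their derived features.

Three classical descriptor families are computed from the quantized ROI:

* **GLCM** — gray-level co-occurrence matrix: normalized counts of level
  pairs at the 13 unique distance-1 3D offsets, accumulated symmetrically
  into a single matrix. Source of the 19 Haralick-family features.
* **GLSZM** — gray-level size-zone matrix: counts ``s(i, j)`` of
  26-connected zones of level ``i`` and size ``j`` voxels.
* **NGTDM** — neighborhood gray-tone difference matrix: per-level summed
  absolute deviation of a voxel's level from the mean of its in-mask
  26-neighbors.

All logarithms are base 2 with the convention ``0 * log 0 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..volume import QuantizedROI

__all__ = [
    "GLCM",
    "GLSZM",
    "NGTDM",
    "compute_glcm",
    "glcm_features",
    "compute_glszm",
    "glszm_features",
    "compute_ngtdm",
    "ngtdm_features",
    "GLCM_FEATURE_NAMES",
    "GLSZM_FEATURE_NAMES",
    "NGTDM_FEATURE_NAMES",
]

# 13 unique 3D direction offsets at Chebyshev distance 1 (half of the 26
# neighbors; the opposite offsets are covered by symmetric accumulation).
OFFSETS_3D = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=np.float64)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

@dataclass
class GLCM:
    """Normalized symmetric co-occurrence table ``p`` of shape (Ng, Ng)."""

    p: np.ndarray

    @property
    def n_levels(self) -> int:
        return self.p.shape[0]


def compute_glcm(
    q: QuantizedROI, offsets: list[tuple[int, int, int]] | None = None
) -> GLCM:
    """Accumulate co-occurrences over all offsets, both orders, then
    normalize. Only pairs with both voxels inside the mask count."""
    if offsets is None:
        offsets = OFFSETS_3D
    lv = q.levels
    mask = q.mask
    ng = q.n_levels
    counts = np.zeros((ng, ng), dtype=np.float64)
    for off in offsets:
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, d in enumerate(off):
            if d > 0:
                src[ax] = slice(0, lv.shape[ax] - d)
                dst[ax] = slice(d, lv.shape[ax])
            elif d < 0:
                src[ax] = slice(-d, lv.shape[ax])
                dst[ax] = slice(0, lv.shape[ax] + d)
        a = lv[tuple(src)]
        b = lv[tuple(dst)]
        ok = mask[tuple(src)] & mask[tuple(dst)]
        ai = a[ok] - 1
        bi = b[ok] - 1
        np.add.at(counts, (ai, bi), 1.0)
    counts = counts + counts.T  # symmetric: each pair in both orders
    total = counts.sum()
    if total == 0:
        raise ValueError("degenerate ROI: no in-mask voxel pair at distance 1")
    return GLCM(counts / total)


GLCM_FEATURE_NAMES = [
    "glcm_autocorrelation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_cluster_tendency",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_entropy",
    "glcm_difference_variance",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_maximum_probability",
    "glcm_sum_average",
    "glcm_sum_entropy",
    "glcm_sum_of_squares_variance",
    "glcm_inverse_difference",
]


def glcm_features(m: GLCM) -> dict[str, float]:
    """The 19 Haralick-family statistics of a normalized symmetric GLCM."""
    p = m.p
    ng = m.n_levels
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)  # equals px by symmetry
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # sum and difference marginals: k = i + j in 2..2Ng; d = |i - j| in 0..Ng-1
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    contrast = float(((ii - jj) ** 2 * p).sum())
    if sig_x > 0 and sig_y > 0:
        correlation = float((((ii - mu_x) * (jj - mu_y) * p).sum()) / (sig_x * sig_y))
    else:
        correlation = 0.0  # degenerate (single occupied level)

    hxy = float(-_xlog2x(p).sum())
    hx = float(-_xlog2x(px).sum())
    hy = float(-_xlog2x(py).sum())
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxy).sum())
    hxy2 = float(-(pxy * log_pxy).sum())
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    mu_diff = float((k_diff * p_diff).sum())
    return {
        "glcm_autocorrelation": float((ii * jj * p).sum()),
        "glcm_cluster_prominence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "glcm_cluster_shade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "glcm_cluster_tendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_difference_entropy": float(-_xlog2x(p_diff).sum()),
        "glcm_difference_variance": float(((k_diff - mu_diff) ** 2 * p_diff).sum()),
        "glcm_dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "glcm_energy": float((p**2).sum()),
        "glcm_entropy": hxy,
        "glcm_homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "glcm_imc1": float(imc1),
        "glcm_imc2": imc2,
        "glcm_maximum_probability": float(p.max()),
        "glcm_sum_average": float((k_sum * p_sum).sum()),
        "glcm_sum_entropy": float(-_xlog2x(p_sum).sum()),
        "glcm_sum_of_squares_variance": float(((ii - mu_x) ** 2 * p).sum()),
        "glcm_inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

@dataclass
class GLSZM:
    """Zone-count table ``s`` of shape (Ng, Zmax): s[i-1, j-1] = number of
    26-connected zones of level i with exactly j voxels."""

    s: np.ndarray

    @property
    def n_zones(self) -> int:
        return int(self.s.sum())


def compute_glszm(q: QuantizedROI) -> GLSZM:
    lv = q.levels
    ng = q.n_levels
    zone_records: list[tuple[int, int]] = []  # (level, size)
    max_size = 1
    for level in range(1, ng + 1):
        binary = lv == level
        if not binary.any():
            continue
        labeled, n_comp = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(labeled.ravel())[1:]
        for sz in sizes:
            zone_records.append((level, int(sz)))
            max_size = max(max_size, int(sz))
    s = np.zeros((ng, max_size), dtype=np.float64)
    for level, sz in zone_records:
        s[level - 1, sz - 1] += 1
    return GLSZM(s)


GLSZM_FEATURE_NAMES = [
    "glszm_small_zone_emphasis",
    "glszm_large_zone_emphasis",
    "glszm_gray_level_nonuniformity",
    "glszm_zone_size_nonuniformity",
    "glszm_zone_percentage",
    "glszm_low_gray_level_zone_emphasis",
    "glszm_high_gray_level_zone_emphasis",
    "glszm_small_zone_low_gray_emphasis",
    "glszm_small_zone_high_gray_emphasis",
    "glszm_large_zone_low_gray_emphasis",
    "glszm_large_zone_high_gray_emphasis",
]


def glszm_features(z: GLSZM) -> dict[str, float]:
    s = z.s
    nz = s.sum()
    ng, zmax = s.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, zmax + 1, dtype=np.float64)[None, :]
    n_voxels = float((s * j).sum())
    si = s.sum(axis=1)  # per gray level
    sj = s.sum(axis=0)  # per zone size
    return {
        "glszm_small_zone_emphasis": float((s / j**2).sum() / nz),
        "glszm_large_zone_emphasis": float((s * j**2).sum() / nz),
        "glszm_gray_level_nonuniformity": float((si**2).sum() / nz),
        "glszm_zone_size_nonuniformity": float((sj**2).sum() / nz),
        "glszm_zone_percentage": float(nz / n_voxels),
        "glszm_low_gray_level_zone_emphasis": float((s / i**2).sum() / nz),
        "glszm_high_gray_level_zone_emphasis": float((s * i**2).sum() / nz),
        "glszm_small_zone_low_gray_emphasis": float((s / (i**2 * j**2)).sum() / nz),
        "glszm_small_zone_high_gray_emphasis": float((s * i**2 / j**2).sum() / nz),
        "glszm_large_zone_low_gray_emphasis": float((s * j**2 / i**2).sum() / nz),
        "glszm_large_zone_high_gray_emphasis": float((s * i**2 * j**2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

@dataclass
class NGTDM:
    """Per-level summed deviations ``s_i`` from the in-mask 26-neighborhood
    mean, occurrence probabilities ``p_i`` and the number of contributing
    voxels."""

    s_i: np.ndarray  # length Ng
    p_i: np.ndarray  # length Ng, sums to 1 over occurring levels
    n_valid: int


def compute_ngtdm(q: QuantizedROI) -> NGTDM:
    lv = q.levels.astype(np.float64)
    mask = q.mask
    ng = q.n_levels
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neigh_sum = ndimage.correlate(lv * mask, kernel, mode="constant", cval=0.0)
    neigh_cnt = ndimage.correlate(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = mask & (neigh_cnt > 0)
    n_valid = int(valid.sum())
    s_i = np.zeros(ng)
    counts = np.zeros(ng)
    if n_valid:
        levels_v = q.levels[valid]
        dev = np.abs(lv[valid] - neigh_sum[valid] / neigh_cnt[valid])
        np.add.at(s_i, levels_v - 1, dev)
        np.add.at(counts, levels_v - 1, 1.0)
    p_i = counts / n_valid if n_valid else counts
    return NGTDM(s_i, p_i, n_valid)


NGTDM_FEATURE_NAMES = [
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
]

_EPS = 1e-6
_COARSENESS_CAP = 1e6


def ngtdm_features(t: NGTDM) -> dict[str, float]:
    p = t.p_i
    s = t.s_i
    n = t.n_valid
    ng = len(p)
    i = np.arange(1, ng + 1, dtype=np.float64)
    occ = p > 0
    ngp = int(occ.sum())
    ps = float((p * s).sum())

    coarseness = min(1.0 / (_EPS + ps), _COARSENESS_CAP)

    if ngp > 1 and n > 0:
        pi_o = p[occ]
        ii_o = i[occ]
        di = ii_o[:, None] - ii_o[None, :]
        contrast = float(
            (pi_o[:, None] * pi_o[None, :] * di**2).sum()
            / (ngp * (ngp - 1))
            * (s.sum() / n)
        )
        denom = float(np.abs(ii_o[:, None] * pi_o[:, None] - ii_o[None, :] * pi_o[None, :]).sum())
        busyness = ps / denom if denom > 0 else 0.0
        s_o = s[occ]
        complexity = float(
            (np.abs(di) * (pi_o[:, None] * s_o[:, None] + pi_o[None, :] * s_o[None, :])
             / (pi_o[:, None] + pi_o[None, :])).sum() / n
        )
        strength = float(
            ((pi_o[:, None] + pi_o[None, :]) * di**2).sum() / (_EPS + s.sum())
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "ngtdm_coarseness": float(coarseness),
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": float(busyness),
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }
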