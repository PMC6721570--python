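"""Naive reference implementations of the texture matrices and features.

Everything here is written as plain per-voxel / per-pair / per-zone Python
loops, independent of the vectorized implementations in the package, so it
can serve as an oracle for equivalence testing.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
HALF_OFFSETS = [o for o in NEIGHBORS_26 if o > (0, 0, 0)]


def _log2(x: float) -> float:
    return math.log(x, 2)


def glcm_naive(levels: np.ndarray, mask: np.ndarray, ng: int,
               offsets=None) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by looping over voxels."""
    if offsets is None:
        offsets = HALF_OFFSETS
    counts = np.zeros((ng, ng))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                a = levels[x, y, z]
                for dx, dy, dz in offsets:
                    u, v, w = x + dx, y + dy, z + dz
                    if not (0 <= u < shape[0] and 0 <= v < shape[1]
                            and 0 <= w < shape[2]):
                        continue
                    if not mask[u, v, w]:
                        continue
                    b = levels[u, v, w]
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total


def glcm_features_naive(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))
    p_sum = [0.0] * (2 * ng + 1)   # index k = i + j, 2..2Ng
    p_diff = [0.0] * ng            # index |i - j|
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    out = {}
    out["glcm_autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
    for power, name in ((4, "glcm_cluster_prominence"),
                        (3, "glcm_cluster_shade"),
                        (2, "glcm_cluster_tendency")):
        out[name] = sum((i + 1 + j + 1 - mu_x - mu_y) ** power * p[i][j]
                        for i in range(ng) for j in range(ng))
    out["glcm_contrast"] = sum((i - j) ** 2 * p[i][j]
                               for i in range(ng) for j in range(ng))
    if sig_x > 0 and sig_y > 0:
        out["glcm_correlation"] = sum(
            (i + 1 - mu_x) * (j + 1 - mu_y) * p[i][j]
            for i in range(ng) for j in range(ng)) / (sig_x * sig_y)
    else:
        out["glcm_correlation"] = 0.0
    out["glcm_difference_entropy"] = -sum(
        q * _log2(q) for q in p_diff if q > 0)
    mu_d = sum(k * p_diff[k] for k in range(ng))
    out["glcm_difference_variance"] = sum(
        (k - mu_d) ** 2 * p_diff[k] for k in range(ng))
    out["glcm_dissimilarity"] = sum(abs(i - j) * p[i][j]
                                    for i in range(ng) for j in range(ng))
    out["glcm_energy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    hxy = -sum(p[i][j] * _log2(p[i][j])
               for i in range(ng) for j in range(ng) if p[i][j] > 0)
    out["glcm_entropy"] = hxy
    out["glcm_homogeneity"] = sum(p[i][j] / (1 + (i - j) ** 2)
                                  for i in range(ng) for j in range(ng))
    hx = -sum(q * _log2(q) for q in px if q > 0)
    hy = -sum(q * _log2(q) for q in py if q > 0)
    hxy1 = -sum(p[i][j] * _log2(px[i] * py[j])
                for i in range(ng) for j in range(ng)
                if p[i][j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * _log2(px[i] * py[j])
                for i in range(ng) for j in range(ng) if px[i] * py[j] > 0)
    out["glcm_imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["glcm_imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    out["glcm_maximum_probability"] = max(
        p[i][j] for i in range(ng) for j in range(ng))
    out["glcm_sum_average"] = sum(k * p_sum[k] for k in range(2, 2 * ng + 1))
    out["glcm_sum_entropy"] = -sum(
        p_sum[k] * _log2(p_sum[k]) for k in range(2, 2 * ng + 1) if p_sum[k] > 0)
    out["glcm_sum_of_squares_variance"] = sum(
        (i + 1 - mu_x) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    out["glcm_inverse_difference"] = sum(
        p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    return out


def glszm_zones_naive(levels: np.ndarray, mask: np.ndarray):
    """All (level, size) zones by breadth-first flood fill, 26-connected."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                level = levels[x, y, z]
                size = 0
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                while queue:
                    cx, cy, cz = queue.popleft()
                    size += 1
                    for dx, dy, dz in NEIGHBORS_26:
                        u, v, w = cx + dx, cy + dy, cz + dz
                        if (0 <= u < shape[0] and 0 <= v < shape[1]
                                and 0 <= w < shape[2] and mask[u, v, w]
                                and not seen[u, v, w]
                                and levels[u, v, w] == level):
                            seen[u, v, w] = True
                            queue.append((u, v, w))
                zones.append((int(level), size))
    return zones


def glszm_features_naive(zones, n_voxels: int) -> dict[str, float]:
    nz = len(zones)
    out = {
        "glszm_small_zone_emphasis": sum(1.0 / j**2 for _, j in zones) / nz,
        "glszm_large_zone_emphasis": sum(j**2 for _, j in zones) / nz,
        "glszm_zone_percentage": nz / n_voxels,
        "glszm_low_gray_level_zone_emphasis": sum(1.0 / i**2 for i, _ in zones) / nz,
        "glszm_high_gray_level_zone_emphasis": sum(i**2 for i, _ in zones) / nz,
        "glszm_small_zone_low_gray_emphasis": sum(
            1.0 / (i**2 * j**2) for i, j in zones) / nz,
        "glszm_small_zone_high_gray_emphasis": sum(
            i**2 / j**2 for i, j in zones) / nz,
        "glszm_large_zone_low_gray_emphasis": sum(
            j**2 / i**2 for i, j in zones) / nz,
        "glszm_large_zone_high_gray_emphasis": sum(
            i**2 * j**2 for i, j in zones) / nz,
    }
    by_level: dict[int, int] = {}
    by_size: dict[int, int] = {}
    for i, j in zones:
        by_level[i] = by_level.get(i, 0) + 1
        by_size[j] = by_size.get(j, 0) + 1
    out["glszm_gray_level_nonuniformity"] = sum(
        c**2 for c in by_level.values()) / nz
    out["glszm_zone_size_nonuniformity"] = sum(
        c**2 for c in by_size.values()) / nz
    return out


def ngtdm_naive(levels: np.ndarray, mask: np.ndarray, ng: int):
    """Per-voxel neighborhood means by explicit looping."""
    shape = levels.shape
    s = [0.0] * (ng + 1)
    counts = [0] * (ng + 1)
    n_valid = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                vals = []
                for dx, dy, dz in NEIGHBORS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if (0 <= u < shape[0] and 0 <= v < shape[1]
                            and 0 <= w < shape[2] and mask[u, v, w]):
                        vals.append(levels[u, v, w])
                if not vals:
                    continue
                n_valid += 1
                lvl = int(levels[x, y, z])
                s[lvl] += abs(lvl - sum(vals) / len(vals))
                counts[lvl] += 1
    p = [c / n_valid if n_valid else 0.0 for c in counts]
    return s, p, n_valid


def ngtdm_features_naive(s, p, n_valid, eps=1e-6, cap=1e6) -> dict[str, float]:
    ng = len(p) - 1
    occ = [i for i in range(1, ng + 1) if p[i] > 0]
    ngp = len(occ)
    ps = sum(p[i] * s[i] for i in occ)
    out = {"ngtdm_coarseness": min(1.0 / (eps + ps), cap)}
    if ngp > 1 and n_valid > 0:
        out["ngtdm_contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ)
            / (ngp * (ngp - 1)) * sum(s[1:]) / n_valid
        )
        denom = sum(abs(i * p[i] - j * p[j]) for i in occ for j in occ)
        out["ngtdm_busyness"] = ps / denom if denom > 0 else 0.0
        out["ngtdm_complexity"] = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in occ for j in occ) / n_valid
        out["ngtdm_strength"] = sum(
            (p[i] + p[j]) * (i - j) ** 2 for i in occ for j in occ
        ) / (eps + sum(s[1:]))
    else:
        out.update(ngtdm_contrast=0.0, ngtdm_busyness=0.0,
                   ngtdm_complexity=0.0, ngtdm_strength=0.0)
    return out


def all_texture_features_naive(levels: np.ndarray, mask: np.ndarray,
                               ng: int) -> dict[str, float]:
    """All 35 texture features of a quantized ROI, by the naive routes."""
    out = {}
    out.update(glcm_features_naive(glcm_naive(levels, mask, ng)))
    zones = glszm_zones_naive(levels, mask)
    out.update(glszm_features_naive(zones, int(mask.sum())))
    s, p, n_valid = ngtdm_naive(levels, mask, ng)
    out.update(ngtdm_features_naive(s, p, n_valid))
    return out
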