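"""Image volumes, ROI masks and intensity preprocessing.

The pipeline harmonizes every scan to a common geometry before feature
extraction: isotropic 1 mm resampling, per-volume min-max normalization to
[0, 1], and uniform quantization of in-mask intensities to 32 gray levels.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "ROIMask",
    "QuantizedROI",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_isotropic",
    "normalize_intensity",
    "quantize_gray_levels",
]


@dataclass
class ImageVolume:
    """A 3D intensity grid with voxel spacing in millimetres."""

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("volume must be 3D")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class ROIMask:
    """Binary tumor mask aligned to an :class:`ImageVolume` grid."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values) > 0.5
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.values.any():
            raise ValueError("mask is empty (no foreground voxel)")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class QuantizedROI:
    """ROI intensities uniformly quantized to integer levels 1..Ng.

    ``levels`` holds 0 outside the mask and a level in [1, Ng] inside.
    """

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        if self.mask is None:
            self.mask = self.levels > 0
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("quantized ROI is empty")
        if inside.min() < 1 or inside.max() > self.n_levels:
            raise ValueError("in-mask levels must lie in [1, Ng]")


def _check_pair(volume_shape, mask) -> None:
    if mask.shape != volume_shape:
        raise ValueError(
            f"mask grid {mask.shape} does not match volume grid {volume_shape}"
        )


def read_volume(path: str | Path) -> ImageVolume:
    """Load a NIfTI volume; spacing is taken from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ImageVolume(data, spacing, origin)


def read_mask(path: str | Path, paired_volume: ImageVolume | None = None) -> ROIMask:
    """Load a NIfTI mask, binarized at > 0.5.

    If ``paired_volume`` is given the grids must match.
    """
    vol = read_volume(path)
    if paired_volume is not None:
        _check_pair(paired_volume.shape, vol.intensities)
    return ROIMask(vol.intensities, vol.spacing_mm)


def _write_nifti(data: np.ndarray, spacing, path: Path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    if path.name.endswith(".nii.gz"):
        # gzip with mtime pinned to 0 so identical content gives identical bytes
        raw = img.to_bytes()
        with open(path, "wb") as fh:
            with gzip.GzipFile(filename="", fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        nib.save(img, str(path))


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    path = Path(path)
    _write_nifti(volume.intensities, volume.spacing_mm, path)
    return path


def write_mask(mask: ROIMask, path: str | Path) -> Path:
    path = Path(path)
    _write_nifti(mask.values.astype(np.uint8), mask.spacing_mm, path)
    return path


def resample_isotropic(
    obj: ImageVolume | ROIMask, target_spacing: float = 1.0
) -> ImageVolume | ROIMask:
    """Resample to isotropic voxels (default 1 mm).

    Images are interpolated trilinearly; masks with nearest-neighbour so
    binarity is preserved. New grid dimensions are
    ``round(old_dim * old_spacing / target)``.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    is_mask = isinstance(obj, ROIMask)
    data = obj.values.astype(np.float64) if is_mask else obj.intensities
    spacing = obj.spacing_mm
    new_shape = tuple(
        max(1, int(round(d * s / target_spacing))) for d, s in zip(data.shape, spacing)
    )
    zoom = [n / o for n, o in zip(new_shape, data.shape)]
    order = 0 if is_mask else 1
    out = ndimage.zoom(data, zoom, order=order, mode="nearest", grid_mode=True)
    out = out[: new_shape[0], : new_shape[1], : new_shape[2]]
    ts = (target_spacing,) * 3
    if is_mask:
        return ROIMask(out > 0.5, ts)
    return ImageVolume(out, ts, obj.origin)


def normalize_intensity(volume: ImageVolume) -> ImageVolume:
    """Min-max rescale the whole volume to [0, 1].

    A constant volume maps to all zeros (defined convention; avoids the
    division by zero).
    """
    x = volume.intensities
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        out = np.zeros_like(x)
    else:
        out = (x - lo) / (hi - lo)
    return ImageVolume(out, volume.spacing_mm, volume.origin)


def quantize_gray_levels(
    volume: ImageVolume, mask: ROIMask, n_levels: int = 32
) -> QuantizedROI:
    """Uniformly rebin in-mask intensities into ``n_levels`` gray levels.

    Bins span the in-mask min..max range (ROI-relative binning);
    ``level = 1 + floor(Ng * (x - min) / (max - min))`` with the maximum
    clipped into level Ng. A constant ROI maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    _check_pair(volume.shape, mask.values)
    m = mask.values
    x = volume.intensities[m]
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        levels[m] = 1
    else:
        lv = 1 + np.floor(n_levels * (x - lo) / (hi - lo)).astype(np.int32)
        levels[m] = np.minimum(lv, n_levels)
    return QuantizedROI(levels, n_levels, m.copy())
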