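"""Reading, writing and validating 3D volumes and ROI masks.

Volumes and masks are stored as NIfTI-1 (plain or gzipped).  Grids are
indexed ``(x, y, z)`` with 0-based indices; the world position of a voxel
centre is ``origin + index * spacing``.  No resampling is applied on read:
features downstream are computed on the native anisotropic grid, in
physical units wherever geometry matters.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "ROIMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_to_isotropic",
]

#: absolute tolerance (mm) when comparing the spacing of a mask to its volume
SPACING_TOL_MM = 1e-3


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    values
        3D array of scalar intensities (HU-like units for CT).
    spacing_mm
        Voxel spacing along (x, y, z), millimetres.
    origin_mm
        World coordinate of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(
                f"volume must be 3D, got shape {values.shape}"
            )
        if values.size == 0:
            raise ValueError("volume grid is empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive scalars, got {self.spacing_mm}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class ROIMask:
    """Binary region-of-interest indicator aligned with an :class:`ImageVolume`."""

    indicator: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator).astype(bool)
        if ind.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {ind.shape}")
        if not ind.any():
            raise ValueError("mask is empty: no voxel inside the ROI")
        object.__setattr__(self, "indicator", ind)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.indicator.shape

    @property
    def voxel_count(self) -> int:
        return int(self.indicator.sum())


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 (float32; lossless round-trip for float32 data)."""
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing_mm, volume.origin_mm))
    nib.save(img, os.fspath(path))


def write_mask(mask: ROIMask, path: str | os.PathLike) -> None:
    """Write a binary mask as NIfTI-1 (uint8, 0/1)."""
    img = nib.Nifti1Image(mask.indicator.astype(np.uint8), _affine(mask.spacing_mm, mask.origin_mm))
    nib.save(img, os.fspath(path))


def _load_nifti(path: str | os.PathLike):
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # corrupt / non-NIfTI
        raise IOError(f"could not parse {path!r} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path!r}: expected a 3D grid, got shape {data.shape}; "
            "4D (multi-frame) images are not supported"
        )
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a 3D scalar volume from NIfTI.

    Spacing is taken from the header zooms and intensities stay in native
    scalar units; anisotropic grids are preserved, not resampled.
    """
    data, spacing, origin = _load_nifti(path)
    return ImageVolume(values=np.asarray(data, dtype=np.float64), spacing_mm=spacing, origin_mm=origin)


def read_mask(path: str | os.PathLike, volume: ImageVolume) -> ROIMask:
    """Read an ROI mask and validate it against its paired volume.

    Any nonzero label counts as inside the ROI.  Shape must match the
    volume exactly and spacing to within :data:`SPACING_TOL_MM`.
    """
    data, spacing, origin = _load_nifti(path)
    if data.shape != volume.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match volume shape {volume.shape}"
        )
    if any(abs(a - b) > SPACING_TOL_MM for a, b in zip(spacing, volume.spacing_mm)):
        raise ValueError(
            f"mask spacing {spacing} does not match volume spacing {volume.spacing_mm} "
            f"(tolerance {SPACING_TOL_MM} mm)"
        )
    indicator = np.asarray(data) != 0
    if not indicator.any():
        raise ValueError("mask file contains no nonzero voxel")
    return ROIMask(indicator=indicator, spacing_mm=volume.spacing_mm, origin_mm=volume.origin_mm)


def resample_to_isotropic(
    volume: ImageVolume, mask: ROIMask, target_mm: float = 1.0
) -> tuple[ImageVolume, ROIMask]:
    """Optionally resample a volume/mask pair to isotropic voxels.

    Off by default everywhere in the pipeline; provided for sensitivity
    analyses.  Volume uses trilinear interpolation, mask nearest-neighbour.
    """
    from scipy.ndimage import zoom

    factors = [s / target_mm for s in volume.spacing_mm]
    vals = zoom(volume.values, factors, order=1)
    ind = zoom(mask.indicator.astype(np.uint8), factors, order=0).astype(bool)
    spacing = (target_mm,) * 3
    return (
        ImageVolume(values=vals, spacing_mm=spacing, origin_mm=volume.origin_mm),
        ROIMask(indicator=ind, spacing_mm=spacing, origin_mm=volume.origin_mm),
    )
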