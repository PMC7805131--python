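"""Grey-level discretisation of ROI intensities for texture matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..image_io import ImageVolume, ROIMask

__all__ = ["DiscretisationScheme", "DiscretisedROI", "discretise"]


@dataclass(frozen=True)
class DiscretisationScheme:
    """How in-mask intensities map to integer grey levels 1..Ng.

    ``fixed_bin_number``: ``level = 1 + floor(N * (v - min) / (max - min))``
    with the maximum clipped into bin N.  ``fixed_bin_width``:
    ``level = 1 + floor((v - min) / w)``.  A constant ROI maps to a single
    level (Ng = 1) under either scheme.
    """

    kind: str = "fixed_bin_number"
    value: float = 32

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_bin_number", "fixed_bin_width"):
            raise ValueError(f"unknown discretisation scheme {self.kind!r}")
        if self.value <= 0:
            raise ValueError(f"scheme parameter must be positive, got {self.value}")
        if self.kind == "fixed_bin_number" and int(self.value) != self.value:
            raise ValueError("fixed_bin_number requires an integer bin count")


@dataclass(frozen=True)
class DiscretisedROI:
    """Integer grey levels on the mask support.

    ``levels`` holds values in 1..Ng inside the mask and 0 outside;
    geometry (spacing) is carried along for texture families that need it.
    """

    levels: np.ndarray  # int grid, 0 outside mask
    mask: np.ndarray  # bool grid
    ng: int
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("discretised ROI is empty")
        if inside.min() < 1 or inside.max() > self.ng:
            raise ValueError("grey levels outside [1, Ng]")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretise(
    volume: ImageVolume, mask: ROIMask, scheme: DiscretisationScheme | None = None
) -> DiscretisedROI:
    """Map in-mask intensities to integer grey levels per the scheme."""
    scheme = scheme or DiscretisationScheme()
    ind = mask.indicator
    vals = volume.values[ind]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if vmax == vmin:
        levels[ind] = 1
        ng = 1
    elif scheme.kind == "fixed_bin_number":
        n = int(scheme.value)
        lv = 1 + np.floor(n * (vals - vmin) / (vmax - vmin)).astype(np.int32)
        np.clip(lv, 1, n, out=lv)
        levels[ind] = lv
        ng = n
    else:  # fixed_bin_width
        w = float(scheme.value)
        lv = 1 + np.floor((vals - vmin) / w).astype(np.int32)
        levels[ind] = lv
        ng = int(lv.max())
    return DiscretisedROI(levels=levels, mask=ind, ng=ng, spacing_mm=volume.spacing_mm)
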