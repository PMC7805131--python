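"""Shared fixtures: tiny discretised ROIs and synthetic tumours."""

from __future__ import annotations

import numpy as np
import pytest

from ctibm.features.discretise import DiscretisedROI
from ctibm.synthetic import TumourParams, generate_tumour


def make_droi(levels: np.ndarray, mask: np.ndarray | None = None,
              ng: int | None = None,
              spacing=(1.0, 1.0, 1.0)) -> DiscretisedROI:
    """Build a DiscretisedROI directly from an integer grid (test helper)."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim == 2:
        levels = levels[..., None]
    if mask is None:
        mask = levels > 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            mask = mask[..., None]
    lv = np.where(mask, levels, 0)
    ng = ng if ng is not None else int(lv.max())
    return DiscretisedROI(levels=lv, mask=mask, ng=ng, spacing_mm=tuple(spacing))


def random_droi(rng: np.random.Generator, max_side: int = 6, max_ng: int = 4) -> DiscretisedROI:
    """Random small ROI: irregular mask, few grey levels."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    ng = int(rng.integers(1, max_ng + 1))
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[0] = True
    return make_droi(levels, mask, ng=ng)


@pytest.fixture(scope="session")
def small_tumour():
    """One deterministic synthetic tumour with anisotropic spacing."""
    params = TumourParams(
        semi_axes_mm=(12.0, 10.0, 8.0),
        mean_intensity=60.0,
        noise_sd=12.0,
        smoothing_sigma_mm=1.5,
        spacing_mm=(1.0, 1.0, 3.0),
    )
    vol, roi, _ = generate_tumour(params, seed=42)
    return vol, roi
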