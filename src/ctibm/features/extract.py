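"""Whole-patient feature extraction: one call, 96 named scalars."""

from __future__ import annotations

import numpy as np

from ..image_io import ImageVolume, ROIMask
from .discretise import DiscretisationScheme, discretise
from .geometry import geometric_features
from .intensity import intensity_features
from .registry import FEATURE_NAMES
from .texture import glcm_features, glrlm_features, glszm_features, ngtdm_features

__all__ = ["extract_all"]


def extract_all(
    volume: ImageVolume,
    mask: ROIMask,
    scheme: DiscretisationScheme | None = None,
) -> dict[str, float]:
    """Compute the full 96-feature vector for one (volume, mask) pair.

    Features depend only on in-mask voxels; the returned dict follows the
    registry order and every value is finite.  Raises with the offending
    feature name if any family produces a non-finite value.
    """
    if mask.shape != volume.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    scheme = scheme or DiscretisationScheme()
    droi = discretise(volume, mask, scheme)

    values: dict[str, float] = {}
    values.update(intensity_features(volume, mask, scheme))
    values.update(geometric_features(mask, volume))
    values.update(glcm_features(droi))
    values.update(glrlm_features(droi))
    values.update(ngtdm_features(droi))
    values.update(glszm_features(droi))

    ordered = {name: float(values[name]) for name in FEATURE_NAMES}
    bad = [name for name, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature value(s): {', '.join(bad)}")
    return ordered
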