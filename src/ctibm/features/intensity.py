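"""First-order intensity statistics of the ROI (24 features).

All statistics are computed on the raw (non-discretised) in-mask
intensities, except ``Histogram_Entropy`` and ``Uniformity`` which use
the discretised grey-level histogram.

Degenerate ROIs (a single voxel, or too few voxels for a moment to be
defined) yield 0 for the undefined dispersion/shape statistics rather
than failing the patient; callers can detect this via the voxel count.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..image_io import ImageVolume, ROIMask
from .discretise import DiscretisationScheme, discretise

__all__ = ["INTENSITY_FEATURES", "intensity_features"]

INTENSITY_FEATURES = [
    "Minimum",
    "Maximum",
    "Range",
    "Mean",
    "Median",
    "Mode",
    "Variance",
    "Standard_Deviation",
    "Skewness",
    "Kurtosis",
    "Energy",
    "Root_Mean_Square",
    "Mean_Absolute_Deviation",
    "Robust_Mean_Absolute_Deviation",
    "Median_Absolute_Deviation",
    "Coefficient_of_Variation",
    "Histogram_Entropy",
    "Uniformity",
    "Q025",
    "Q25",
    "Q75",
    "Q975",
    "Interquartile_Range",
    "Quartile_Coefficient_of_Dispersion",
]


def intensity_features(
    volume: ImageVolume,
    mask: ROIMask,
    scheme: DiscretisationScheme | None = None,
) -> dict[str, float]:
    v = volume.values[mask.indicator].astype(np.float64)
    n = v.size
    out: dict[str, float] = {}

    vmin, vmax = float(v.min()), float(v.max())
    mean = float(v.mean())
    med = float(np.median(v))
    out["Minimum"] = vmin
    out["Maximum"] = vmax
    out["Range"] = vmax - vmin
    out["Mean"] = mean
    out["Median"] = med
    # most frequent raw value; ties resolve to the smallest (scipy convention)
    out["Mode"] = float(stats.mode(v, keepdims=False).mode)

    var = float(v.var()) if n > 1 else 0.0
    out["Variance"] = var
    out["Standard_Deviation"] = float(np.sqrt(var))
    # population moments; excess kurtosis (normal -> 0); undefined on flat input -> 0
    if n > 2 and var > 0:
        out["Skewness"] = float(stats.skew(v, bias=True))
        out["Kurtosis"] = float(stats.kurtosis(v, fisher=True, bias=True))
    else:
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0

    out["Energy"] = float(np.sum(v**2))
    out["Root_Mean_Square"] = float(np.sqrt(np.mean(v**2)))
    out["Mean_Absolute_Deviation"] = float(np.mean(np.abs(v - mean)))

    # robust MAD: mean absolute deviation of values inside [P10, P90],
    # taken around the mean of that trimmed set
    p10, p90 = np.percentile(v, [10, 90])
    trimmed = v[(v >= p10) & (v <= p90)]
    if trimmed.size:
        out["Robust_Mean_Absolute_Deviation"] = float(np.mean(np.abs(trimmed - trimmed.mean())))
    else:
        out["Robust_Mean_Absolute_Deviation"] = 0.0
    out["Median_Absolute_Deviation"] = float(np.mean(np.abs(v - med)))
    out["Coefficient_of_Variation"] = out["Standard_Deviation"] / mean if mean != 0 else 0.0

    droi = discretise(volume, mask, scheme)
    counts = np.bincount(droi.levels[droi.mask], minlength=droi.ng + 1)[1:]
    p = counts[counts > 0] / n
    out["Histogram_Entropy"] = float(-np.sum(p * np.log2(p)))
    out["Uniformity"] = float(np.sum(p**2))

    q025, q25, q75, q975 = np.percentile(v, [2.5, 25, 75, 97.5])
    out["Q025"] = float(q025)
    out["Q25"] = float(q25)
    out["Q75"] = float(q75)
    out["Q975"] = float(q975)
    out["Interquartile_Range"] = float(q75 - q25)
    denom = q75 + q25
    out["Quartile_Coefficient_of_Dispersion"] = float((q75 - q25) / denom) if denom != 0 else 0.0
    return out
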