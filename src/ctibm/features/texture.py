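"""Grey-level texture matrices and their features (52 in total).

Four families are computed on a :class:`~ctibm.features.discretise.DiscretisedROI`:

* GLCM — co-occurrence of grey-level pairs at the 13 unique voxel-grid
  offsets with Chebyshev distance 1 (20 features),
* GLRLM — runs of equal grey level along the same 13 directions
  (16 features),
* NGTDM — per-voxel difference from the mean grey level of the
  26-connected in-mask neighbourhood (5 features),
* GLSZM — 26-connected zones of equal grey level (11 features).

Conventions, fixed for the whole package: GLCM counts are symmetrised
and GLCM/GLRLM counts are pooled over all directions into a single
matrix *before* features are computed; direction weights are all 1, i.e.
grid neighbours are treated alike regardless of physical anisotropy.
Out-of-mask voxels never pair with, extend a run of, or neighbour an
in-mask voxel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretise import DiscretisedROI

__all__ = [
    "OFFSETS_13",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "NGTDM_FEATURES",
    "GLSZM_FEATURES",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "ngtdm_table",
    "ngtdm_features",
    "glszm_matrix",
    "glszm_features",
]

#: the 13 unique 3D offsets at Chebyshev distance 1 (one per ± pair)
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

GLCM_FEATURES = [
    "Maximum_Probability_GLCM",
    "Joint_Average_GLCM",
    "Sum_of_Square_Variance_GLCM",
    "Joint_Entropy_GLCM",
    "Angular_Second_Moment_GLCM",
    "Contrast_GLCM",
    "Dissimilarity_GLCM",
    "Inverse_Difference_GLCM",
    "Inverse_Difference_Normalised_GLCM",
    "Inverse_Difference_Moment_GLCM",
    "Inverse_Difference_Moment_Normalised_GLCM",
    "Inverse_Variance_GLCM",
    "Correlation_GLCM",
    "Autocorrelation_GLCM",
    "Cluster_Tendency_GLCM",
    "Cluster_Shade_GLCM",
    "Cluster_Prominence_GLCM",
    "Sum_Average_GLCM",
    "Sum_Entropy_GLCM",
    "Difference_Entropy_GLCM",
]

GLRLM_FEATURES = [
    "Short_Run_Emphasis_GLRLM",
    "Long_Run_Emphasis_GLRLM",
    "Low_Grey_Level_Run_Emphasis_GLRLM",
    "High_Grey_Level_Run_Emphasis_GLRLM",
    "Short_Run_Low_Grey_Level_Emphasis_GLRLM",
    "Short_Run_High_Grey_Level_Emphasis_GLRLM",
    "Long_Run_Low_Grey_Level_Emphasis_GLRLM",
    "Long_Run_High_Grey_Level_Emphasis_GLRLM",
    "Grey_Level_Non_Uniformity_GLRLM",
    "Grey_Level_Non_Uniformity_Normalised_GLRLM",
    "Run_Length_Non_Uniformity_GLRLM",
    "Run_Length_Non_Uniformity_Normalised_GLRLM",
    "Run_Percentage_GLRLM",
    "Grey_Level_Variance_GLRLM",
    "Run_Length_Variance_GLRLM",
    "Run_Entropy_GLRLM",
]

NGTDM_FEATURES = [
    "Coarseness_NGTDM",
    "Contrast_NGTDM",
    "Busyness_NGTDM",
    "Complexity_NGTDM",
    "Strength_NGTDM",
]

GLSZM_FEATURES = [
    "Small_Zone_Emphasis_GLSZM",
    "Large_Zone_Emphasis_GLSZM",
    "Grey_Level_Non_Uniformity_GLSZM",
    "Zone_Size_Non_Uniformity_GLSZM",
    "Zone_percentage_GLSZM",
    "Low_Grey_Level_Zone_Emphasis_GLSZM",
    "High_Grey_Level_Zone_Emphasis_GLSZM",
    "Small_Zone_Low_Grey_Level_Emphasis_GLSZM",
    "Small_Zone_High_Grey_Level_Emphasis_GLSZM",
    "Large_Zone_Low_Grey_Level_Emphasis_GLSZM",
    "Large_Zone_High_Grey_Level_Emphasis_GLSZM",
]

#: value reported for NGTDM coarseness on a perfectly flat grey field
COARSENESS_CAP = 1e6


def _shifted_views(a: np.ndarray, off: tuple[int, int, int]):
    """Views of `a` at positions v and v+off over the overlap region."""
    sl_a, sl_b = [], []
    for o, dim in zip(off, a.shape):
        if o >= 0:
            sl_a.append(slice(0, dim - o))
            sl_b.append(slice(o, dim))
        else:
            sl_a.append(slice(-o, dim))
            sl_b.append(slice(0, dim + o))
    return a[tuple(sl_a)], a[tuple(sl_b)]


# ---------------------------------------------------------------- GLCM

def glcm_matrix(
    droi: DiscretisedROI, offsets: tuple[tuple[int, int, int], ...] = OFFSETS_13
) -> np.ndarray:
    """Symmetric, normalised co-occurrence matrix pooled over offsets."""
    ng = droi.ng
    counts = np.zeros((ng, ng), dtype=np.float64)
    lv = droi.levels
    m = droi.mask
    for off in offsets:
        la, lb = _shifted_views(lv, off)
        ma, mb = _shifted_views(m, off)
        both = ma & mb
        i = la[both] - 1
        j = lb[both] - 1
        np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T  # symmetrise: count each ordered pair both ways
    total = counts.sum()
    if total == 0:
        # no in-mask neighbouring pair; degenerate single-voxel-like ROI
        counts[:] = 0.0
        counts[0, 0] = 1.0
        total = 1.0
    return counts / total


def glcm_features(
    droi: DiscretisedROI, offsets: tuple[tuple[int, int, int], ...] = OFFSETS_13
) -> dict[str, float]:
    p = glcm_matrix(droi, offsets)
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, ng + 1, dtype=np.float64)[None, :]
    mu = float((p * i).sum())  # joint mean of i (= of j by symmetry)
    var = float((p * (i - mu) ** 2).sum())
    diff = np.abs(i - j)

    out: dict[str, float] = {}
    out["Maximum_Probability_GLCM"] = float(p.max())
    out["Joint_Average_GLCM"] = mu
    out["Sum_of_Square_Variance_GLCM"] = var
    nz = p[p > 0]
    out["Joint_Entropy_GLCM"] = float(-(nz * np.log2(nz)).sum())
    out["Angular_Second_Moment_GLCM"] = float((p**2).sum())
    out["Contrast_GLCM"] = float((p * (i - j) ** 2).sum())
    out["Dissimilarity_GLCM"] = float((p * diff).sum())
    out["Inverse_Difference_GLCM"] = float((p / (1.0 + diff)).sum())
    out["Inverse_Difference_Normalised_GLCM"] = float((p / (1.0 + diff / ng)).sum())
    out["Inverse_Difference_Moment_GLCM"] = float((p / (1.0 + (i - j) ** 2)).sum())
    out["Inverse_Difference_Moment_Normalised_GLCM"] = float(
        (p / (1.0 + (i - j) ** 2 / ng**2)).sum()
    )
    offdiag = diff > 0
    out["Inverse_Variance_GLCM"] = float((p[offdiag] / diff[offdiag] ** 2).sum())
    if var > 0:
        out["Correlation_GLCM"] = float(((p * i * j).sum() - mu**2) / var)
    else:
        out["Correlation_GLCM"] = 1.0  # flat field: degenerate perfect correlation
    out["Autocorrelation_GLCM"] = float((p * i * j).sum())
    s = i + j - 2 * mu
    out["Cluster_Tendency_GLCM"] = float((p * s**2).sum())
    out["Cluster_Shade_GLCM"] = float((p * s**3).sum())
    out["Cluster_Prominence_GLCM"] = float((p * s**4).sum())

    # sum / difference marginal distributions
    ksum = (np.arange(ng)[:, None] + np.arange(ng)[None, :]).ravel()
    psum = np.bincount(ksum, weights=p.ravel(), minlength=2 * ng - 1)
    kvals = np.arange(2, 2 * ng + 1, dtype=np.float64)
    out["Sum_Average_GLCM"] = float((psum * kvals).sum())
    nzs = psum[psum > 0]
    out["Sum_Entropy_GLCM"] = float(-(nzs * np.log2(nzs)).sum())
    kdiff = np.abs(np.arange(ng)[:, None] - np.arange(ng)[None, :]).ravel()
    pdiff = np.bincount(kdiff, weights=p.ravel(), minlength=ng)
    nzd = pdiff[pdiff > 0]
    out["Difference_Entropy_GLCM"] = float(-(nzd * np.log2(nzd)).sum())
    return out


# --------------------------------------------------------------- GLRLM

def glrlm_matrix(
    droi: DiscretisedROI, directions: tuple[tuple[int, int, int], ...] = OFFSETS_13
) -> np.ndarray:
    """Run-length counts R[i, l] pooled over directions (levels × run length)."""
    lv = droi.levels
    m = droi.mask
    max_len = max(lv.shape)
    counts = np.zeros((droi.ng, max_len), dtype=np.float64)
    for d in directions:
        # same[v] True when v and v+d are both in-mask with equal level
        same = np.zeros(lv.shape, dtype=bool)
        la, lb = _shifted_views(lv, d)
        ma, mb = _shifted_views(m, d)
        sa, _ = _shifted_views(same, d)
        sa[...] = ma & mb & (la == lb)
        # run length from each voxel forwards: L[v] = 1 + L[v+d] if same[v]
        length = np.ones(lv.shape, dtype=np.int64)
        while True:
            nxt = np.ones_like(length)
            na, nb = _shifted_views(nxt, d)
            la_, lb_ = _shifted_views(length, d)
            na[...] = np.where(_shifted_views(same, d)[0], 1 + lb_, 1)
            if np.array_equal(nxt, length):
                break
            length = nxt
        # a run starts at v when v-d does not continue into v
        prev_same = np.zeros(lv.shape, dtype=bool)
        _, pb = _shifted_views(prev_same, d)
        pb[...] = _shifted_views(same, d)[0]
        starts = m & ~prev_same
        lv_s = lv[starts] - 1
        ln_s = length[starts] - 1
        np.add.at(counts, (lv_s, ln_s), 1.0)
    # trim trailing all-zero run-length columns
    used = np.nonzero(counts.sum(axis=0))[0]
    if used.size:
        counts = counts[:, : used[-1] + 1]
    return counts


def glrlm_features(
    droi: DiscretisedROI, directions: tuple[tuple[int, int, int], ...] = OFFSETS_13
) -> dict[str, float]:
    r = glrlm_matrix(droi, directions)
    nr = r.sum()
    nv = droi.n_voxels * len(directions)  # one run decomposition per direction
    i = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
    ell = np.arange(1, r.shape[1] + 1, dtype=np.float64)[None, :]
    p = r / nr

    out: dict[str, float] = {}
    out["Short_Run_Emphasis_GLRLM"] = float((r / ell**2).sum() / nr)
    out["Long_Run_Emphasis_GLRLM"] = float((r * ell**2).sum() / nr)
    out["Low_Grey_Level_Run_Emphasis_GLRLM"] = float((r / i**2).sum() / nr)
    out["High_Grey_Level_Run_Emphasis_GLRLM"] = float((r * i**2).sum() / nr)
    out["Short_Run_Low_Grey_Level_Emphasis_GLRLM"] = float((r / (i**2 * ell**2)).sum() / nr)
    out["Short_Run_High_Grey_Level_Emphasis_GLRLM"] = float((r * i**2 / ell**2).sum() / nr)
    out["Long_Run_Low_Grey_Level_Emphasis_GLRLM"] = float((r * ell**2 / i**2).sum() / nr)
    out["Long_Run_High_Grey_Level_Emphasis_GLRLM"] = float((r * i**2 * ell**2).sum() / nr)
    gl_marg = r.sum(axis=1)
    rl_marg = r.sum(axis=0)
    out["Grey_Level_Non_Uniformity_GLRLM"] = float((gl_marg**2).sum() / nr)
    out["Grey_Level_Non_Uniformity_Normalised_GLRLM"] = float((gl_marg**2).sum() / nr**2)
    out["Run_Length_Non_Uniformity_GLRLM"] = float((rl_marg**2).sum() / nr)
    out["Run_Length_Non_Uniformity_Normalised_GLRLM"] = float((rl_marg**2).sum() / nr**2)
    out["Run_Percentage_GLRLM"] = float(nr / nv)
    mu_i = float((p * i).sum())
    mu_l = float((p * ell).sum())
    out["Grey_Level_Variance_GLRLM"] = float((p * (i - mu_i) ** 2).sum())
    out["Run_Length_Variance_GLRLM"] = float((p * (ell - mu_l) ** 2).sum())
    nz = p[p > 0]
    out["Run_Entropy_GLRLM"] = float(-(nz * np.log2(nz)).sum())
    return out


# --------------------------------------------------------------- NGTDM

def ngtdm_table(droi: DiscretisedROI) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts n_i and summed absolute differences s_i.

    Only voxels with at least one 26-connected in-mask neighbour
    contribute; s_i sums |i - mean neighbour level| over those voxels.
    """
    lv = droi.levels.astype(np.float64)
    m = droi.mask
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(lv * m, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(m.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = m & (nb_cnt > 0.5)
    n = np.zeros(droi.ng)
    s = np.zeros(droi.ng)
    if valid.any():
        levels = droi.levels[valid]
        diffs = np.abs(levels - nb_sum[valid] / nb_cnt[valid])
        np.add.at(n, levels - 1, 1.0)
        np.add.at(s, levels - 1, diffs)
    return n, s


def ngtdm_features(droi: DiscretisedROI) -> dict[str, float]:
    n, s = ngtdm_table(droi)
    ntot = n.sum()
    out = {k: 0.0 for k in NGTDM_FEATURES}
    if ntot == 0:
        return out  # no voxel has a neighbour: all five zero by convention
    p = n / ntot
    present = p > 0
    ngp = int(present.sum())
    lv = np.arange(1, droi.ng + 1, dtype=np.float64)

    dens = float((p * s).sum())
    out["Coarseness_NGTDM"] = min(1.0 / dens, COARSENESS_CAP) if dens > 0 else COARSENESS_CAP

    if ngp > 1:
        pi = p[present][:, None]
        pj = p[present][None, :]
        ii = lv[present][:, None]
        jj = lv[present][None, :]
        out["Contrast_NGTDM"] = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * s.sum() / ntot
        )
        denom = np.abs(ii * pi - jj * pj).sum()
        out["Busyness_NGTDM"] = float(dens / denom) if denom > 0 else 0.0
        si = s[present][:, None]
        sj = s[present][None, :]
        out["Complexity_NGTDM"] = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / ntot
        )
        ssum = s.sum()
        out["Strength_NGTDM"] = float(((pi + pj) * (ii - jj) ** 2).sum() / ssum) if ssum > 0 else 0.0
    return out


# --------------------------------------------------------------- GLSZM

def glszm_matrix(droi: DiscretisedROI) -> np.ndarray:
    """Zone counts m[i, s]: 26-connected components of equal level (levels × size)."""
    structure = np.ones((3, 3, 3), dtype=bool)
    records: list[tuple[int, int]] = []
    for level in range(1, droi.ng + 1):
        sel = droi.mask & (droi.levels == level)
        if not sel.any():
            continue
        labelled, nzones = ndimage.label(sel, structure=structure)
        sizes = np.bincount(labelled.ravel())[1:]
        records.extend((level, int(sz)) for sz in sizes)
    max_size = max(sz for _, sz in records)
    m = np.zeros((droi.ng, max_size), dtype=np.float64)
    for level, sz in records:
        m[level - 1, sz - 1] += 1.0
    return m


def glszm_features(droi: DiscretisedROI) -> dict[str, float]:
    m = glszm_matrix(droi)
    nz = m.sum()
    nv = droi.n_voxels
    i = np.arange(1, m.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, m.shape[1] + 1, dtype=np.float64)[None, :]

    out: dict[str, float] = {}
    out["Small_Zone_Emphasis_GLSZM"] = float((m / s**2).sum() / nz)
    out["Large_Zone_Emphasis_GLSZM"] = float((m * s**2).sum() / nz)
    out["Grey_Level_Non_Uniformity_GLSZM"] = float((m.sum(axis=1) ** 2).sum() / nz)
    out["Zone_Size_Non_Uniformity_GLSZM"] = float((m.sum(axis=0) ** 2).sum() / nz)
    out["Zone_percentage_GLSZM"] = float(nz / nv)
    out["Low_Grey_Level_Zone_Emphasis_GLSZM"] = float((m / i**2).sum() / nz)
    out["High_Grey_Level_Zone_Emphasis_GLSZM"] = float((m * i**2).sum() / nz)
    out["Small_Zone_Low_Grey_Level_Emphasis_GLSZM"] = float((m / (i**2 * s**2)).sum() / nz)
    out["Small_Zone_High_Grey_Level_Emphasis_GLSZM"] = float((m * i**2 / s**2).sum() / nz)
    out["Large_Zone_Low_Grey_Level_Emphasis_GLSZM"] = float((m * s**2 / i**2).sum() / nz)
    out["Large_Zone_High_Grey_Level_Emphasis_GLSZM"] = float((m * i**2 * s**2).sum() / nz)
    return out
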