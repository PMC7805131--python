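"""Brute-force enumeration oracles for the texture families.

Everything here is written as plain nested loops over voxels, offsets,
runs, neighbourhoods and zones — deliberately independent of the
vectorised implementations under ``ctibm.features.texture`` — and is
only ever used to cross-check them on tiny ROIs.
"""

from __future__ import annotations

import math

import numpy as np

NEIGHBOURS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, x, y, z):
    return 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]


# ------------------------------------------------------------------ GLCM

def oracle_glcm_matrix(levels, mask, ng, offsets):
    counts = np.zeros((ng, ng))
    shape = mask.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in offsets:
                    for sx, sy, sz in ((dx, dy, dz), (-dx, -dy, -dz)):
                        nx, ny, nz = x + sx, y + sy, z + sz
                        if _inside(shape, nx, ny, nz) and mask[nx, ny, nz]:
                            counts[levels[x, y, z] - 1, levels[nx, ny, nz] - 1] += 1
    total = counts.sum()
    if total == 0:
        counts[0, 0] = 1.0
        total = 1.0
    return counts / total


def oracle_glcm_features(levels, mask, ng, offsets):
    p = oracle_glcm_matrix(levels, mask, ng, offsets)
    mu = sum(p[i, j] * (i + 1) for i in range(ng) for j in range(ng))
    var = sum(p[i, j] * (i + 1 - mu) ** 2 for i in range(ng) for j in range(ng))
    out = {}
    out["Maximum_Probability_GLCM"] = p.max()
    out["Joint_Average_GLCM"] = mu
    out["Sum_of_Square_Variance_GLCM"] = var
    out["Joint_Entropy_GLCM"] = -sum(
        p[i, j] * math.log2(p[i, j]) for i in range(ng) for j in range(ng) if p[i, j] > 0
    )
    out["Angular_Second_Moment_GLCM"] = (p**2).sum()
    out["Contrast_GLCM"] = sum(p[i, j] * (i - j) ** 2 for i in range(ng) for j in range(ng))
    out["Dissimilarity_GLCM"] = sum(p[i, j] * abs(i - j) for i in range(ng) for j in range(ng))
    out["Inverse_Difference_GLCM"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    out["Inverse_Difference_Normalised_GLCM"] = sum(
        p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    out["Inverse_Difference_Moment_GLCM"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    out["Inverse_Difference_Moment_Normalised_GLCM"] = sum(
        p[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )
    out["Inverse_Variance_GLCM"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    if var > 0:
        out["Correlation_GLCM"] = (
            sum(p[i, j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng)) - mu**2
        ) / var
    else:
        out["Correlation_GLCM"] = 1.0
    out["Autocorrelation_GLCM"] = sum(
        p[i, j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng)
    )
    out["Cluster_Tendency_GLCM"] = sum(
        p[i, j] * (i + j + 2 - 2 * mu) ** 2 for i in range(ng) for j in range(ng)
    )
    out["Cluster_Shade_GLCM"] = sum(
        p[i, j] * (i + j + 2 - 2 * mu) ** 3 for i in range(ng) for j in range(ng)
    )
    out["Cluster_Prominence_GLCM"] = sum(
        p[i, j] * (i + j + 2 - 2 * mu) ** 4 for i in range(ng) for j in range(ng)
    )
    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]
    out["Sum_Average_GLCM"] = sum(k * v for k, v in psum.items())
    out["Sum_Entropy_GLCM"] = -sum(v * math.log2(v) for v in psum.values() if v > 0)
    out["Difference_Entropy_GLCM"] = -sum(v * math.log2(v) for v in pdiff.values() if v > 0)
    return out


# ----------------------------------------------------------------- GLRLM

def oracle_glrlm_runs(levels, mask, directions):
    """Explicit run scanning: list of (level, length) pooled over directions."""
    shape = mask.shape
    runs = []
    for d in directions:
        dx, dy, dz = d
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if not mask[x, y, z]:
                        continue
                    px, py, pz = x - dx, y - dy, z - dz
                    # run starts where the predecessor does not continue it
                    if (
                        _inside(shape, px, py, pz)
                        and mask[px, py, pz]
                        and levels[px, py, pz] == levels[x, y, z]
                    ):
                        continue
                    length = 1
                    cx, cy, cz = x + dx, y + dy, z + dz
                    while (
                        _inside(shape, cx, cy, cz)
                        and mask[cx, cy, cz]
                        and levels[cx, cy, cz] == levels[x, y, z]
                    ):
                        length += 1
                        cx, cy, cz = cx + dx, cy + dy, cz + dz
                    runs.append((int(levels[x, y, z]), length))
    return runs


def oracle_glrlm_features(levels, mask, ng, directions):
    runs = oracle_glrlm_runs(levels, mask, directions)
    nr = len(runs)
    nv = int(mask.sum()) * len(directions)
    out = {}
    out["Short_Run_Emphasis_GLRLM"] = sum(1 / l**2 for _, l in runs) / nr
    out["Long_Run_Emphasis_GLRLM"] = sum(l**2 for _, l in runs) / nr
    out["Low_Grey_Level_Run_Emphasis_GLRLM"] = sum(1 / g**2 for g, _ in runs) / nr
    out["High_Grey_Level_Run_Emphasis_GLRLM"] = sum(g**2 for g, _ in runs) / nr
    out["Short_Run_Low_Grey_Level_Emphasis_GLRLM"] = sum(
        1 / (g**2 * l**2) for g, l in runs
    ) / nr
    out["Short_Run_High_Grey_Level_Emphasis_GLRLM"] = sum(g**2 / l**2 for g, l in runs) / nr
    out["Long_Run_Low_Grey_Level_Emphasis_GLRLM"] = sum(l**2 / g**2 for g, l in runs) / nr
    out["Long_Run_High_Grey_Level_Emphasis_GLRLM"] = sum(
        g**2 * l**2 for g, l in runs
    ) / nr
    by_level = {}
    by_length = {}
    for g, l in runs:
        by_level[g] = by_level.get(g, 0) + 1
        by_length[l] = by_length.get(l, 0) + 1
    out["Grey_Level_Non_Uniformity_GLRLM"] = sum(v**2 for v in by_level.values()) / nr
    out["Grey_Level_Non_Uniformity_Normalised_GLRLM"] = (
        sum(v**2 for v in by_level.values()) / nr**2
    )
    out["Run_Length_Non_Uniformity_GLRLM"] = sum(v**2 for v in by_length.values()) / nr
    out["Run_Length_Non_Uniformity_Normalised_GLRLM"] = (
        sum(v**2 for v in by_length.values()) / nr**2
    )
    out["Run_Percentage_GLRLM"] = nr / nv
    mu_g = sum(g for g, _ in runs) / nr
    mu_l = sum(l for _, l in runs) / nr
    out["Grey_Level_Variance_GLRLM"] = sum((g - mu_g) ** 2 for g, _ in runs) / nr
    out["Run_Length_Variance_GLRLM"] = sum((l - mu_l) ** 2 for _, l in runs) / nr
    cell = {}
    for g, l in runs:
        cell[(g, l)] = cell.get((g, l), 0) + 1
    out["Run_Entropy_GLRLM"] = -sum(
        (v / nr) * math.log2(v / nr) for v in cell.values()
    )
    return out


# ----------------------------------------------------------------- NGTDM

def oracle_ngtdm_features(levels, mask, ng):
    shape = mask.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                nb = [
                    levels[x + dx, y + dy, z + dz]
                    for dx, dy, dz in NEIGHBOURS_26
                    if _inside(shape, x + dx, y + dy, z + dz) and mask[x + dx, y + dy, z + dz]
                ]
                if not nb:
                    continue
                g = levels[x, y, z]
                n[g - 1] += 1
                s[g - 1] += abs(g - sum(nb) / len(nb))
    ntot = n.sum()
    out = {k: 0.0 for k in (
        "Coarseness_NGTDM", "Contrast_NGTDM", "Busyness_NGTDM",
        "Complexity_NGTDM", "Strength_NGTDM")}
    if ntot == 0:
        return out
    p = n / ntot
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    dens = sum(p[i] * s[i] for i in range(ng))
    out["Coarseness_NGTDM"] = min(1.0 / dens, 1e6) if dens > 0 else 1e6
    if ngp > 1:
        out["Contrast_NGTDM"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
            * (s.sum() / ntot)
        )
        denom = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        out["Busyness_NGTDM"] = dens / denom if denom > 0 else 0.0
        out["Complexity_NGTDM"] = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in present
                for j in present
            )
            / ntot
        )
        ssum = s.sum()
        out["Strength_NGTDM"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / ssum
            if ssum > 0
            else 0.0
        )
    return out


# ----------------------------------------------------------------- GLSZM

def oracle_glszm_zones(levels, mask):
    """Flood-fill 26-connected zones of equal level: list of (level, size)."""
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                g = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in NEIGHBOURS_26:
                        nx, ny, nz = cx + dx, cy + dy, cz + dz
                        if (
                            _inside(shape, nx, ny, nz)
                            and mask[nx, ny, nz]
                            and not seen[nx, ny, nz]
                            and levels[nx, ny, nz] == g
                        ):
                            seen[nx, ny, nz] = True
                            stack.append((nx, ny, nz))
                zones.append((int(g), size))
    return zones


def oracle_glszm_features(levels, mask, ng):
    zones = oracle_glszm_zones(levels, mask)
    nz = len(zones)
    nv = int(mask.sum())
    out = {}
    out["Small_Zone_Emphasis_GLSZM"] = sum(1 / sz**2 for _, sz in zones) / nz
    out["Large_Zone_Emphasis_GLSZM"] = sum(sz**2 for _, sz in zones) / nz
    by_level = {}
    by_size = {}
    for g, sz in zones:
        by_level[g] = by_level.get(g, 0) + 1
        by_size[sz] = by_size.get(sz, 0) + 1
    out["Grey_Level_Non_Uniformity_GLSZM"] = sum(v**2 for v in by_level.values()) / nz
    out["Zone_Size_Non_Uniformity_GLSZM"] = sum(v**2 for v in by_size.values()) / nz
    out["Zone_percentage_GLSZM"] = nz / nv
    out["Low_Grey_Level_Zone_Emphasis_GLSZM"] = sum(1 / g**2 for g, _ in zones) / nz
    out["High_Grey_Level_Zone_Emphasis_GLSZM"] = sum(g**2 for g, _ in zones) / nz
    out["Small_Zone_Low_Grey_Level_Emphasis_GLSZM"] = sum(
        1 / (g**2 * sz**2) for g, sz in zones
    ) / nz
    out["Small_Zone_High_Grey_Level_Emphasis_GLSZM"] = sum(
        g**2 / sz**2 for g, sz in zones
    ) / nz
    out["Large_Zone_Low_Grey_Level_Emphasis_GLSZM"] = sum(
        sz**2 / g**2 for g, sz in zones
    ) / nz
    out["Large_Zone_High_Grey_Level_Emphasis_GLSZM"] = sum(
        g**2 * sz**2 for g, sz in zones
    ) / nz
    return out
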