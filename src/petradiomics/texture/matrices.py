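"""Texture matrix builders on the quantized tumor lattice.

All matrices use the 3D lattice neighborhood conventions standard in PET
radiomics: 26 co-occurrence offsets aggregated into one symmetric GLCM,
runs along the 13 unique lattice directions summed into one GLRLM,
26-connected zones for the GLSZM, and the 26-neighborhood (truncated at
the mask boundary — only in-mask neighbors count) for the NGTDM and
NGLDM.  Everything operates in index space; voxel spacing never enters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..quantize import QuantizedROI

#: all 26 nonzero offsets of the 3x3x3 neighborhood
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

#: the 13 unique (up to sign) lattice directions
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in OFFSETS_26 if d > (0, 0, 0)
)

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _offset_slices(shape, d):
    """Slices (src, dst) such that dst = src + d, both inside the grid."""
    src = tuple(slice(max(0, -di), min(n, n - di)) for di, n in zip(d, shape))
    dst = tuple(slice(max(0, di), min(n, n + di)) for di, n in zip(d, shape))
    return src, dst


def _shift(arr: np.ndarray, d, fill) -> np.ndarray:
    """out[v] = arr[v - d], filled with ``fill`` where v - d leaves the grid."""
    out = np.full(arr.shape, fill, dtype=arr.dtype)
    src, dst = _offset_slices(arr.shape, d)
    out[dst] = arr[src]
    return out


def _crop(q: QuantizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Levels and mask cropped to the mask bounding box."""
    idx = np.argwhere(q.mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return q.levels[sl], q.mask[sl]


@dataclass
class GLCM:
    p: np.ndarray  # Ng x Ng probabilities, symmetric, sums to 1
    distance: int
    n_pairs: int


@dataclass
class GLRLM:
    r: np.ndarray  # Ng x Rmax run counts, aggregated over directions
    n_voxels: int
    n_directions: int


@dataclass
class GLSZM:
    z: np.ndarray  # Ng x Zmax zone counts
    n_zones: int
    n_voxels: int


@dataclass
class NGTDM:
    p: np.ndarray  # occurrence probability per level (index 0 = level 1)
    s: np.ndarray  # summed |level - neighborhood mean| per level
    n_valid: int  # voxels with >= 1 in-mask neighbor
    Ng: int


@dataclass
class NGLDM:
    d: np.ndarray  # Ng x 27 counts: level i with k dependent neighbors
    n_voxels: int  # voxels with >= 1 valid neighbor
    tolerance: int


def compute_glcm(q: QuantizedROI, distance: int = 1) -> GLCM:
    """Gray level co-occurrence matrix over all 26 offsets at ``distance``.

    Pairs are counted in both orientations, which makes the matrix
    symmetric; counts are normalized to probabilities.
    """
    lev, mask = _crop(q)
    Ng = q.Ng
    counts = np.zeros((Ng + 1) * (Ng + 1), dtype=np.int64)
    for d in OFFSETS_13:
        dd = tuple(int(distance) * di for di in d)
        src, dst = _offset_slices(lev.shape, dd)
        both = mask[src] & mask[dst]
        if not both.any():
            continue
        a = lev[src][both]
        b = lev[dst][both]
        counts += np.bincount(a * (Ng + 1) + b, minlength=(Ng + 1) ** 2)
        counts += np.bincount(b * (Ng + 1) + a, minlength=(Ng + 1) ** 2)
    full = counts.reshape(Ng + 1, Ng + 1)[1:, 1:]
    n_pairs = int(full.sum())
    if n_pairs == 0:
        raise ValueError("no in-mask voxel pairs at the requested distance")
    return GLCM(p=full / n_pairs, distance=int(distance), n_pairs=n_pairs)


def compute_glrlm(
    q: QuantizedROI, directions: tuple[tuple[int, int, int], ...] = OFFSETS_13
) -> GLRLM:
    """Gray level run-length matrix, runs summed over ``directions``.

    A run is a maximal set of collinear, consecutive in-mask voxels
    sharing one gray level.
    """
    lev, mask = _crop(q)
    n_vox = int(mask.sum())
    Ng = q.Ng
    max_len = max(lev.shape)
    counts = np.zeros((Ng + 1, max_len + 1), dtype=np.int64)
    for d in directions:
        # link[v]: run continues from v to v + d
        nxt_lev = _shift(lev, tuple(-di for di in d), fill=0)
        nxt_mask = _shift(mask, tuple(-di for di in d), fill=False)
        link = mask & nxt_mask & (lev == nxt_lev)
        # start[v]: no identical in-mask predecessor at v - d
        prev_link = _shift(link, d, fill=False)
        start = mask & ~prev_link
        # extra[v] = number of consecutive links ahead of v:
        # ahead_k[v] = link[v] & link[v+d] & ... & link[v+(k-1)d]
        extra = np.zeros(lev.shape, dtype=np.int64)
        ahead = link.copy()
        k = 1
        while ahead.any():
            extra += ahead
            ahead = ahead & _shift(link, tuple(-k * di for di in d), fill=False)
            k += 1
        run_lev = lev[start]
        run_len = 1 + extra[start]
        counts_d = np.bincount(
            run_lev * (max_len + 1) + run_len, minlength=(Ng + 1) * (max_len + 1)
        ).reshape(Ng + 1, max_len + 1)
        counts += counts_d
    r = counts[1:, 1:]
    rmax = max(int(np.argwhere(r.any(axis=0)).max()) + 1, 1) if r.any() else 1
    return GLRLM(r=r[:, :rmax], n_voxels=n_vox, n_directions=len(directions))


def compute_glszm(q: QuantizedROI) -> GLSZM:
    """Gray level size zone matrix; zones are maximal 26-connected sets."""
    lev, mask = _crop(q)
    n_vox = int(mask.sum())
    Ng = q.Ng
    zone_counts: dict[tuple[int, int], int] = {}
    max_size = 1
    for lvl in np.unique(lev[mask]):
        lab, n_lab = ndimage.label(lev == lvl, structure=STRUCT_26)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zone_counts[(int(lvl), int(s))] = zone_counts.get((int(lvl), int(s)), 0) + 1
            max_size = max(max_size, int(s))
    z = np.zeros((Ng, max_size), dtype=np.int64)
    for (lvl, s), c in zone_counts.items():
        z[lvl - 1, s - 1] = c
    return GLSZM(z=z, n_zones=int(z.sum()), n_voxels=n_vox)


def _neighbor_sums(lev: np.ndarray, mask: np.ndarray):
    """Per voxel: sum of in-mask 26-neighbor levels and their count."""
    nsum = np.zeros(lev.shape, dtype=np.float64)
    ncnt = np.zeros(lev.shape, dtype=np.int64)
    for d in OFFSETS_26:
        nl = _shift(lev, d, fill=0)
        nm = _shift(mask, d, fill=False)
        nsum += np.where(nm, nl, 0)
        ncnt += nm.astype(np.int64)
    return nsum, ncnt


def compute_ngtdm(q: QuantizedROI) -> NGTDM:
    """Neighborhood gray tone difference matrix (Amadasun-King form).

    Neighborhood means use only in-mask neighbors; voxels with no
    in-mask neighbor are excluded.
    """
    lev, mask = _crop(q)
    nsum, ncnt = _neighbor_sums(lev, mask)
    valid = mask & (ncnt > 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no voxel has an in-mask neighbor")
    li = lev[valid].astype(np.float64)
    abar = nsum[valid] / ncnt[valid]
    dev = np.abs(li - abar)
    Ng = q.Ng
    s = np.zeros(Ng, dtype=np.float64)
    n_i = np.zeros(Ng, dtype=np.float64)
    np.add.at(s, lev[valid] - 1, dev)
    np.add.at(n_i, lev[valid] - 1, 1.0)
    return NGTDM(p=n_i / n_valid, s=s, n_valid=n_valid, Ng=Ng)


def compute_ngldm(q: QuantizedROI, tolerance: int = 0) -> NGLDM:
    """Neighboring gray level dependence matrix.

    A 26-neighbor is *dependent* when its level differs from the center
    by at most ``tolerance``.  Rows are gray levels, columns the number
    of dependent neighbors (0..26); voxels with no in-mask neighbor are
    excluded.
    """
    lev, mask = _crop(q)
    dep = np.zeros(lev.shape, dtype=np.int64)
    ncnt = np.zeros(lev.shape, dtype=np.int64)
    for doff in OFFSETS_26:
        nl = _shift(lev, doff, fill=0)
        nm = _shift(mask, doff, fill=False)
        dep += (nm & (np.abs(lev - nl) <= tolerance)).astype(np.int64)
        ncnt += nm.astype(np.int64)
    valid = mask & (ncnt > 0)
    if not valid.any():
        raise ValueError("no voxel has an in-mask neighbor")
    Ng = q.Ng
    mat = np.zeros((Ng, 27), dtype=np.int64)
    np.add.at(mat, (lev[valid] - 1, dep[valid]), 1)
    return NGLDM(d=mat, n_voxels=int(valid.sum()), tolerance=int(tolerance))
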