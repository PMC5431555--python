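"""Independent brute-force enumerators for every texture matrix family.

Everything here is written as plain per-voxel loops against the
documented neighborhood definitions, deliberately sharing no code with
the package implementation beyond the offset-ordering convention.
"""

from __future__ import annotations

from collections import Counter, deque

import numpy as np

# same generation rule as the package: all nonzero offsets of the 3x3x3
# neighborhood in lexicographic order, positive half for directions
OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
OFFSETS_13 = [d for d in OFFSETS_26 if d > (0, 0, 0)]


def _inb(idx, shape) -> bool:
    return all(0 <= i < n for i, n in zip(idx, shape))


def _add(v, d, k=1):
    return tuple(i + k * di for i, di in zip(v, d))


def _voxels(mask):
    return [tuple(v) for v in np.argwhere(mask)]


def oracle_glcm(levels, mask, Ng, distance=1):
    """Directed pair counts over all 26 offsets, normalized."""
    counts = np.zeros((Ng, Ng), dtype=np.int64)
    shape = mask.shape
    for v in _voxels(mask):
        for d in OFFSETS_26:
            w = _add(v, d, distance)
            if _inb(w, shape) and mask[w]:
                counts[levels[v] - 1, levels[w] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def oracle_glrlm(levels, mask, Ng, directions=None):
    """Run counts per direction, summed; rows are levels, cols run length."""
    if directions is None:
        directions = OFFSETS_13
    shape = mask.shape
    max_len = max(shape)
    r = np.zeros((Ng, max_len), dtype=np.int64)
    for d in directions:
        for v in _voxels(mask):
            prev = _add(v, d, -1)
            if _inb(prev, shape) and mask[prev] and levels[prev] == levels[v]:
                continue  # not a run start
            length = 1
            w = _add(v, d)
            while _inb(w, shape) and mask[w] and levels[w] == levels[v]:
                length += 1
                w = _add(w, d)
            r[levels[v] - 1, length - 1] += 1
    return r


def oracle_glszm(levels, mask, Ng):
    """Zone counts by flood fill over the 26-neighborhood."""
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for v in _voxels(mask):
        if seen[v]:
            continue
        lvl = levels[v]
        size = 0
        queue = deque([v])
        seen[v] = True
        while queue:
            u = queue.popleft()
            size += 1
            for d in OFFSETS_26:
                w = _add(u, d)
                if _inb(w, shape) and mask[w] and not seen[w] and levels[w] == lvl:
                    seen[w] = True
                    queue.append(w)
        zones.append((lvl, size))
    max_size = max(s for _, s in zones)
    z = np.zeros((Ng, max_size), dtype=np.int64)
    for lvl, s in zones:
        z[lvl - 1, s - 1] += 1
    return z


def oracle_ngtdm(levels, mask, Ng):
    """Per-level probability and summed deviation from neighborhood mean."""
    shape = mask.shape
    s = np.zeros(Ng)
    n_i = np.zeros(Ng)
    n_valid = 0
    for v in _voxels(mask):
        nb = [
            levels[_add(v, d)]
            for d in OFFSETS_26
            if _inb(_add(v, d), shape) and mask[_add(v, d)]
        ]
        if not nb:
            continue
        n_valid += 1
        dev = abs(levels[v] - sum(nb) / len(nb))
        s[levels[v] - 1] += dev
        n_i[levels[v] - 1] += 1
    return n_i / n_valid, s, n_valid


def oracle_ngldm(levels, mask, Ng, tolerance=0):
    """Counts of voxels at level i with k dependent neighbors."""
    shape = mask.shape
    d_mat = np.zeros((Ng, 27), dtype=np.int64)
    for v in _voxels(mask):
        nb = [
            levels[_add(v, d)]
            for d in OFFSETS_26
            if _inb(_add(v, d), shape) and mask[_add(v, d)]
        ]
        if not nb:
            continue
        k = sum(abs(levels[v] - b) <= tolerance for b in nb)
        d_mat[levels[v] - 1, k] += 1
    return d_mat


def oracle_texture_spectrum(levels, mask):
    """Counter of texture units (26-tuples of ternary codes).

    Interior voxels (full neighborhood in-mask) if any exist, otherwise
    all voxels with at least one in-mask neighbor, missing neighbors
    coded 1 ("equal").
    """
    shape = mask.shape
    units_interior: Counter = Counter()
    units_fallback: Counter = Counter()
    for v in _voxels(mask):
        codes = []
        n_valid = 0
        for d in OFFSETS_26:
            w = _add(v, d)
            if _inb(w, shape) and mask[w]:
                n_valid += 1
                diff = levels[w] - levels[v]
                codes.append(0 if diff < 0 else (1 if diff == 0 else 2))
            else:
                codes.append(1)
        if n_valid == len(OFFSETS_26):
            units_interior[tuple(codes)] += 1
        if n_valid > 0:
            units_fallback[tuple(codes)] += 1
    return units_interior if units_interior else units_fallback


def oracle_tfc_codes(levels, mask):
    """Per-voxel TFC code: sum of gradient classes over valid pairs.

    For each opposite-offset pair with both neighbors in-mask the two
    first differences g1 = lev(v+d) - lev(v), g2 = lev(v) - lev(v-d)
    grade as: 0 both zero, 1 exactly one zero, 2 same sign, 3 opposite.
    """
    shape = mask.shape
    codes = {}
    for v in _voxels(mask):
        total = 0
        any_pair = False
        for d in OFFSETS_13:
            p, m = _add(v, d), _add(v, d, -1)
            if not (_inb(p, shape) and mask[p] and _inb(m, shape) and mask[m]):
                continue
            any_pair = True
            g1 = np.sign(levels[p] - levels[v])
            g2 = np.sign(levels[v] - levels[m])
            if g1 == 0 and g2 == 0:
                cls = 0
            elif g1 == 0 or g2 == 0:
                cls = 1
            elif g1 == g2:
                cls = 2
            else:
                cls = 3
            total += cls
        if any_pair:
            codes[v] = total
    return codes


def oracle_tfccm(levels, mask, n_codes=40):
    """Symmetric co-occurrence of TFC codes at distance 1, normalized."""
    codes = oracle_tfc_codes(levels, mask)
    counts = np.zeros((n_codes, n_codes), dtype=np.int64)
    shape = mask.shape
    for v, cv in codes.items():
        for d in OFFSETS_26:
            w = _add(v, d)
            if _inb(w, shape) and w in codes:
                counts[cv, codes[w]] += 1
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def oracle_connected_components(hot):
    """26-connected component labelling by flood fill; returns label array."""
    shape = hot.shape
    labels = np.zeros(shape, dtype=int)
    nxt = 0
    for v in [tuple(x) for x in np.argwhere(hot)]:
        if labels[v]:
            continue
        nxt += 1
        queue = deque([v])
        labels[v] = nxt
        while queue:
            u = queue.popleft()
            for d in OFFSETS_26:
                w = _add(u, d)
                if _inb(w, shape) and hot[w] and not labels[w]:
                    labels[w] = nxt
                    queue.append(w)
    return labels, nxt


def random_quantized_roi(seed, max_shape=6, Ng=6):
    """Random small quantized ROI for oracle-equivalence checks.

    Two full rows along the last axis are always masked so that every
    matrix family (including the opposite-offset TFC coding and its
    co-occurrence) has at least one valid construction.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, max_shape + 1, size=2)) + (
        int(rng.integers(3, max_shape + 1)),
    )
    levels = rng.integers(1, Ng + 1, size=shape)
    mask = rng.random(shape) < 0.7
    mask[0, 0, :] = mask[0, 1, :] = True
    levels[~mask] = 0
    return levels, mask
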