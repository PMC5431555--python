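"""Neighborhood-ordering texture descriptors: texture spectrum, texture
feature coding (TFC), and the TFC co-occurrence matrix.

These are 3D analogues of the classical 2D schemes:

* **Texture spectrum** — each voxel's 26 neighbors are coded ternary
  (0 less, 1 equal, 2 greater than the center); the ordered 26-vector is
  the voxel's *texture unit* and the spectrum is the frequency
  distribution of units.  Units are formed on interior voxels (full
  neighborhood in-mask); if the ROI has no interior voxel, voxels with
  at least one in-mask neighbor are used with missing neighbors coded
  "equal".
* **TFC** — for each of the 13 opposite-offset pairs through a voxel the
  two first differences are graded into a connection class (0 both flat,
  1 one-sided gradient, 2 monotone ramp, 3 local extremum); the voxel's
  code is the sum of classes over its valid pairs (0..39).  Pairs with a
  missing neighbor are skipped; voxels with no valid pair are excluded.
* **TFCCM** — symmetric co-occurrence of TFC codes between 26-neighbor
  voxel pairs, normalized to probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..quantize import QuantizedROI
from .matrices import OFFSETS_13, OFFSETS_26, _crop, _offset_slices, _shift

#: permutation sending each offset index to the index of its opposite
_OPPOSITE = tuple(OFFSETS_26.index(tuple(-c for c in d)) for d in OFFSETS_26)

#: maximal TFC code: 13 pairs x class 3
MAX_TFC_CODE = 39


@dataclass
class TextureSpectrum:
    units: np.ndarray  # U x 26 int8, distinct texture units
    counts: np.ndarray  # occurrences per distinct unit
    n: int  # total voxels contributing
    interior_only: bool


@dataclass
class TFCVolume:
    codes: np.ndarray  # per-voxel code, -1 where undefined
    valid: np.ndarray  # bool, voxels with >= 1 valid pair
    class_counts: np.ndarray  # totals of pair classes 0..3
    n: int


@dataclass
class TFCCM:
    p: np.ndarray  # (MAX_TFC_CODE+1)^2 symmetric probabilities
    n_pairs: int


def _neighbor_codes(lev: np.ndarray, mask: np.ndarray):
    """Ternary codes and validity per voxel per 26-offset."""
    n_off = len(OFFSETS_26)
    codes = np.ones(lev.shape + (n_off,), dtype=np.int8)
    valid = np.zeros(lev.shape + (n_off,), dtype=bool)
    for k, d in enumerate(OFFSETS_26):
        neg = tuple(-c for c in d)
        nl = _shift(lev, neg, fill=0)  # nl[v] = lev[v + d]
        nm = _shift(mask, neg, fill=False)
        codes[..., k] = np.sign(nl - lev) + 1
        valid[..., k] = nm
    return codes, valid


def compute_texture_spectrum(q: QuantizedROI) -> TextureSpectrum:
    """Texture-unit spectrum of the quantized ROI."""
    lev, mask = _crop(q)
    codes, valid = _neighbor_codes(lev, mask)
    n_valid = valid.sum(axis=-1)
    interior = mask & (n_valid == len(OFFSETS_26))
    if interior.any():
        units = codes[interior]
        interior_only = True
    else:
        some = mask & (n_valid > 0)
        if not some.any():
            raise ValueError("no voxel has an in-mask neighbor")
        # missing neighbors already carry the neutral code 1 ("equal")
        units = np.where(valid[some], codes[some], 1).astype(np.int8)
        interior_only = False
    uniq, counts = np.unique(units, axis=0, return_counts=True)
    return TextureSpectrum(
        units=uniq, counts=counts, n=int(counts.sum()), interior_only=interior_only
    )


def spectrum_overlap_deficit(ts: TextureSpectrum, transform) -> float:
    """Sum over units of |S(u) - S(T(u))| / (2 n), in [0, 1].

    ``transform`` maps a unit row to its transformed row; used for the
    black-white and geometric symmetry features.
    """
    orig: dict[bytes, int] = {}
    for u, c in zip(ts.units, ts.counts):
        orig[u.tobytes()] = orig.get(u.tobytes(), 0) + int(c)
    trans: dict[bytes, int] = {}
    for u, c in zip(ts.units, ts.counts):
        key = transform(u).astype(np.int8).tobytes()
        trans[key] = trans.get(key, 0) + int(c)
    keys = set(orig) | set(trans)
    diff = sum(abs(orig.get(k, 0) - trans.get(k, 0)) for k in keys)
    return diff / (2.0 * ts.n)


def complement_unit(u: np.ndarray) -> np.ndarray:
    """Gray-level inversion: less <-> greater."""
    return 2 - u


def invert_unit(u: np.ndarray) -> np.ndarray:
    """Point reflection of the neighborhood about the center voxel."""
    return u[list(_OPPOSITE)]


def compute_tfc(q: QuantizedROI) -> TFCVolume:
    """Per-voxel texture feature codes."""
    lev, mask = _crop(q)
    code = np.zeros(lev.shape, dtype=np.int64)
    n_pairs = np.zeros(lev.shape, dtype=np.int64)
    class_counts = np.zeros(4, dtype=np.int64)
    for d in OFFSETS_13:
        neg = tuple(-c for c in d)
        lp = _shift(lev, neg, fill=0)  # lp[v] = lev[v + d]
        mp = _shift(mask, neg, fill=False)
        lm = _shift(lev, d, fill=0)  # lm[v] = lev[v - d]
        mm = _shift(mask, d, fill=False)
        ok = mask & mp & mm
        g1 = np.sign(lp - lev)
        g2 = np.sign(lev - lm)
        cls = np.where(
            (g1 == 0) & (g2 == 0),
            0,
            np.where((g1 == 0) | (g2 == 0), 1, np.where(g1 == g2, 2, 3)),
        )
        code += np.where(ok, cls, 0)
        n_pairs += ok.astype(np.int64)
        if ok.any():
            class_counts += np.bincount(cls[ok], minlength=4)
    valid = mask & (n_pairs > 0)
    if not valid.any():
        raise ValueError("no voxel has an opposite-offset pair inside the mask")
    codes = np.where(valid, code, -1)
    return TFCVolume(
        codes=codes, valid=valid, class_counts=class_counts, n=int(valid.sum())
    )


def compute_tfccm(tfc: TFCVolume) -> TFCCM:
    """Symmetric co-occurrence matrix of TFC codes at distance 1."""
    nc = MAX_TFC_CODE + 1
    counts = np.zeros(nc * nc, dtype=np.int64)
    codes, valid = tfc.codes, tfc.valid
    for d in OFFSETS_13:
        src, dst = _offset_slices(codes.shape, d)
        both = valid[src] & valid[dst]
        if not both.any():
            continue
        a = codes[src][both]
        b = codes[dst][both]
        counts += np.bincount(a * nc + b, minlength=nc * nc)
        counts += np.bincount(b * nc + a, minlength=nc * nc)
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise ValueError("no co-occurring TFC code pairs")
    return TFCCM(p=counts.reshape(nc, nc) / n_pairs, n_pairs=n_pairs)
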