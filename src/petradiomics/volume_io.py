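"""SUV volume and ROI mask containers plus NIfTI I/O.

Texture computation is purely lattice-based; voxel spacing enters only
through the volumetric indices (MTV, TLG), so orientation metadata in the
NIfTI affine is passed through untouched and world coordinates are never
needed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class VolumeError(ValueError):
    """Invalid volumetric data (shape, spacing, or voxel values)."""


class VolumeReadError(VolumeError):
    """File could not be read as a 3D SUV volume."""


@dataclass
class SUVVolume:
    """A 3D grid of non-negative SUV values with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise VolumeError(f"non-3D data: got {self.values.ndim} dimensions")
        if min(self.values.shape) < 1:
            raise VolumeError("every axis must have at least one voxel")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            raise VolumeError(f"non-finite voxel at index {tuple(int(i) for i in bad[0])}")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            raise VolumeError(f"negative SUV at index {tuple(int(i) for i in neg[0])}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]


@dataclass
class ROIMask:
    """Binary mask congruent with an :class:`SUVVolume`."""

    flags: np.ndarray
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        arr = np.asarray(self.flags)
        if arr.ndim != 3:
            raise VolumeError(f"non-3D mask: got {arr.ndim} dimensions")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise VolumeError("mask values must be 0/1")
        self.flags = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> SUVVolume:
    """Read a 3D SUV volume from NIfTI (.nii / .nii.gz).

    Raises :class:`VolumeReadError` for unreadable files or non-3D data
    and :class:`VolumeError` for NaN/negative voxels.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeReadError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeReadError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeReadError(f"non-3D data in {path}: {data.ndim} dimensions")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeReadError(f"missing or invalid voxel spacing in {path}: {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return SUVVolume(values=data.astype(np.float64), spacing=tuple(float(z) for z in zooms), origin=origin)


def read_mask(path: str | Path) -> ROIMask:
    vol = read_volume(path)
    return ROIMask(flags=(vol.values > 0.5).astype(np.uint8), spacing=vol.spacing)


def write_volume(volume: SUVVolume, path: str | Path) -> Path:
    """Write a volume to NIfTI; round-trips through :func:`read_volume`."""
    path = Path(path)
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def write_mask(mask: ROIMask, path: str | Path, origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> Path:
    """Write a mask as a 0/1 uint8 NIfTI volume."""
    path = Path(path)
    img = nib.Nifti1Image(mask.flags.astype(np.uint8), _affine(mask.spacing, origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path
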