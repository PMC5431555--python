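"""Fixed-threshold tumor delineation and volumetric indices.

The primary tumor is the 26-connected component of voxels with
SUV >= cutoff (default 2.5) containing an optional seed point, or the
largest such component when no seed is given.  MTV is the delineated
volume in cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import ROIMask, SUVVolume

#: 26-connectivity structuring element
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class UndelineableTumorError(ValueError):
    """No voxel reaches the SUV cutoff: the tumor cannot be delineated."""


@dataclass
class SegmentationResult:
    mask: ROIMask
    n_voxels: int
    mtv_cm3: float
    component_count: int
    cutoff: float


def segment_fixed_threshold(
    volume: SUVVolume,
    cutoff: float = 2.5,
    seed_point: tuple[int, int, int] | None = None,
) -> SegmentationResult:
    """Delineate the tumor by a fixed SUV threshold (closed: SUV >= cutoff).

    Raises :class:`UndelineableTumorError` when no voxel reaches the
    cutoff, and ``ValueError`` when a seed point falls outside the
    thresholded region.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    hot = volume.values >= cutoff
    if not hot.any():
        raise UndelineableTumorError(
            f"no voxel has SUV >= {cutoff}: tumor cannot be delineated"
        )
    labels, n_comp = ndimage.label(hot, structure=STRUCT_26)
    if seed_point is not None:
        seed_point = tuple(int(i) for i in seed_point)
        lab = labels[seed_point]
        if lab == 0:
            raise ValueError(f"seed point {seed_point} is below the cutoff {cutoff}")
    else:
        sizes = np.bincount(labels.ravel())[1:]
        lab = int(np.argmax(sizes)) + 1  # ties -> lowest label, deterministic
    flags = labels == lab
    mask = ROIMask(flags=flags.astype(np.uint8), spacing=volume.spacing)
    result = SegmentationResult(
        mask=mask,
        n_voxels=int(flags.sum()),
        mtv_cm3=compute_mtv_from_count(int(flags.sum()), volume.spacing),
        component_count=int(n_comp),
        cutoff=float(cutoff),
    )
    return result


def compute_mtv_from_count(n_voxels: int, spacing: tuple[float, float, float]) -> float:
    """MTV in cm^3 = voxel count x voxel volume (mm^3) / 1000."""
    if n_voxels < 1:
        raise ValueError("empty mask has no metabolic tumor volume")
    return n_voxels * spacing[0] * spacing[1] * spacing[2] / 1000.0


def compute_mtv(result: SegmentationResult, spacing: tuple[float, float, float] | None = None) -> float:
    """MTV of a segmentation, in cm^3."""
    if spacing is None:
        spacing = result.mask.spacing
    return compute_mtv_from_count(result.n_voxels, spacing)
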