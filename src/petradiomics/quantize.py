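"""Fixed-bin-width SUV discretization.

Masked SUVs are resampled to integer gray levels with a constant bin
width (default 0.4 SUV over the window 0-25, 64 levels), keeping the
intensity resolution identical across tumors:

    level = floor((SUV - range_min) / bin_width) + 1, clipped to [1, Ng].

Bins are left-closed/right-open; SUVs at or above the window top fall in
the highest level (a clip, logged when it occurs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume_io import ROIMask, SUVVolume

logger = logging.getLogger(__name__)


@dataclass
class QuantizedROI:
    """Integer gray levels (1..Ng) on the masked lattice; 0 outside."""

    levels: np.ndarray  # int array, 0 = unmasked
    mask: np.ndarray  # bool
    Ng: int
    bin_width: float
    range_min: float
    range_max: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def quantize_fixed_bin_width(
    volume: SUVVolume,
    mask: ROIMask,
    bin_width: float = 0.4,
    range_min: float = 0.0,
    range_max: float = 25.0,
    n_levels: int = 64,
) -> QuantizedROI:
    """Quantize masked SUVs to ``n_levels`` gray levels of ``bin_width`` SUV."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if range_max <= range_min:
        raise ValueError("range_max must exceed range_min")
    if mask.flags.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    flags = mask.flags
    if not flags.any():
        raise ValueError("empty mask cannot be quantized")
    suv = volume.values[flags]
    if (suv < range_min).any():
        idx = tuple(np.argwhere(flags)[np.argmax(suv < range_min)])
        raise ValueError(f"masked voxel {idx} has SUV below range_min {range_min}")
    levels_in = np.floor((suv - range_min) / bin_width).astype(np.int64) + 1
    n_clipped = int((levels_in > n_levels).sum())
    if n_clipped:
        logger.info("clipping %d voxel(s) above level %d to the top bin", n_clipped, n_levels)
    levels_in = np.clip(levels_in, 1, n_levels)
    levels = np.zeros(volume.shape, dtype=np.int64)
    levels[flags] = levels_in
    return QuantizedROI(
        levels=levels,
        mask=flags.copy(),
        Ng=int(n_levels),
        bin_width=float(bin_width),
        range_min=float(range_min),
        range_max=float(range_max),
    )
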