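"""Construction of dS/S0 maps from matched flip-angle cine pairs.

The normalized signal change between a high-flip-angle (MT/T1/T2-weighted)
and a low-flip-angle (proton-density reference) bSSFP image is computed per
voxel as

    dS/S0 = (S_high - S_low) / S_low * 100  (%)

Maps from several quiescent diastolic phases are averaged to suppress
random noise, and a small median filter can be applied for display and
analysis.  Voxels whose reference signal falls below a configurable floor
are marked invalid rather than producing unstable ratios; they are excluded
from every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InputError

__all__ = ["ParametricMap", "CineSlicePair", "delta_s_map", "average_phase_maps",
           "median_filter_map", "delta_s_from_pair"]


@dataclass
class ParametricMap:
    """A per-voxel 2-D scalar field with a validity mask.

    Used for dS/S0 (%), T1 (ms), GPC (dimensionless) and LGE intensity
    maps.  ``values`` must be finite wherever ``valid_mask`` is true.
    """

    values: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError(f"ParametricMap expects a 2-D field, got shape {self.values.shape}")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise InputError(
                f"valid_mask shape {self.valid_mask.shape} != values shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise InputError("ParametricMap values must be finite wherever valid")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def valid_values(self, where: np.ndarray | None = None) -> np.ndarray:
        """Valid voxel values, optionally restricted to a boolean mask."""
        m = self.valid_mask if where is None else (self.valid_mask & np.asarray(where, bool))
        return self.values[m]


@dataclass
class CineSlicePair:
    """Matched low/high flip-angle magnitude cine phase stacks of one slice."""

    low_phases: list
    high_phases: list
    low_angle: float
    high_angle: float
    phase_indices: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.low_phases = [np.asarray(p, dtype=float) for p in self.low_phases]
        self.high_phases = [np.asarray(p, dtype=float) for p in self.high_phases]
        if len(self.low_phases) != len(self.high_phases) or not self.low_phases:
            raise InputError("low/high phase counts must match and be >= 1")
        shapes = {p.shape for p in self.low_phases} | {p.shape for p in self.high_phases}
        if len(shapes) != 1:
            raise InputError(f"all phases must share one image shape, got {shapes}")
        if not self.low_angle < self.high_angle:
            raise InputError(
                f"low_angle must be < high_angle (got {self.low_angle}, {self.high_angle})"
            )
        if not self.phase_indices:
            self.phase_indices = list(range(len(self.low_phases)))

    @property
    def n_phases(self) -> int:
        return len(self.low_phases)


def delta_s_map(high_phase, low_phase, s5_floor: float) -> ParametricMap:
    """Per-voxel normalized signal change (S_high - S_low)/S_low * 100 (%).

    Voxels whose reference (low-flip-angle) intensity falls below
    ``s5_floor`` are marked invalid and excluded from downstream
    statistics; the division is never evaluated there.
    """
    high = np.asarray(high_phase, dtype=float)
    low = np.asarray(low_phase, dtype=float)
    if high.shape != low.shape:
        raise InputError(f"shape mismatch: high {high.shape} vs low {low.shape}")
    if not s5_floor > 0:
        raise InputError(f"s5_floor must be positive, got {s5_floor}")
    valid = low >= s5_floor
    values = np.zeros_like(low)
    values[valid] = (high[valid] - low[valid]) / low[valid] * 100.0
    values[~valid] = np.nan
    return ParametricMap(values=values, valid_mask=valid, units="%")


def average_phase_maps(maps: Sequence[ParametricMap]) -> ParametricMap:
    """Voxel-wise mean of phase maps; valid only where all inputs are valid."""
    if len(maps) == 0:
        raise InputError("need at least one map to average")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise InputError(f"maps must share one shape, got {shapes}")
    valid = np.logical_and.reduce([m.valid_mask for m in maps])
    stack = np.stack([m.values for m in maps])
    values = np.full(maps[0].shape, np.nan)
    values[valid] = stack[:, valid].mean(axis=0)
    return ParametricMap(values=values, valid_mask=valid, units=maps[0].units)


def median_filter_map(
    pmap: ParametricMap, kernel_rows: int = 3, kernel_cols: int = 2
) -> ParametricMap:
    """Sliding-window median filter, mask-aware.

    Invalid voxels are excluded from every window (the median is taken over
    the valid members only); windows with an even number of valid members
    use the mean of the two middle order statistics.  Edges are handled by
    reflection.  Output voxels stay invalid where the input was invalid, or
    where a window contains no valid member.
    """
    if kernel_rows < 1 or kernel_cols < 1:
        raise InputError("kernel dimensions must be >= 1")
    nr, nc = pmap.shape
    if kernel_rows > nr or kernel_cols > nc:
        raise InputError(
            f"kernel {kernel_rows}x{kernel_cols} larger than image {nr}x{nc}"
        )
    # Centered window; for even kernel sizes the extra voxel trails.
    pad_r = ((kernel_rows - 1) // 2, kernel_rows // 2)
    pad_c = ((kernel_cols - 1) // 2, kernel_cols // 2)
    work = np.where(pmap.valid_mask, pmap.values, np.nan)
    padded = np.pad(work, (pad_r, pad_c), mode="reflect")
    windows = sliding_window_view(padded, (kernel_rows, kernel_cols))
    flat = windows.reshape(nr, nc, -1)
    all_nan = np.all(np.isnan(flat), axis=-1)
    values = np.full((nr, nc), np.nan)
    ok = ~all_nan
    with np.errstate(all="ignore"):
        values[ok] = np.nanmedian(flat[ok], axis=-1)
    valid = pmap.valid_mask & ok
    values[~valid] = np.nan
    return ParametricMap(values=values, valid_mask=valid, units=pmap.units)


def delta_s_from_pair(
    pair: CineSlicePair,
    s5_floor: float,
    filter_kernel: tuple | None = None,
) -> ParametricMap:
    """Full map construction for one slice: per-phase dS/S0, phase average,
    optional median filter.

    ``filter_kernel`` is a (rows, cols) tuple, e.g. ``(3, 2)``; ``None``
    skips filtering.
    """
    per_phase = [
        delta_s_map(h, l, s5_floor=s5_floor)
        for h, l in zip(pair.high_phases, pair.low_phases)
    ]
    avg = average_phase_maps(per_phase)
    if filter_kernel is not None:
        avg = median_filter_map(avg, *filter_kernel)
    return avg
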