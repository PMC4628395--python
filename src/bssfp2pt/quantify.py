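"""Scalar quantification of enhancement and contrast-agent distribution.

Given a labelled myocardium this module computes the enhanced area (% of
myocardial voxels), the transmurality of enhancement (% of wall thickness
covered along a radial ray through the center of the enhanced region),
per-voxel gadolinium partition coefficient maps

    GPC = dR1_myocardium / dR1_blood,   R1 = 1/T1,

from pre/post-contrast T1 maps, and the DICE overlap coefficient between
binary masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, InputError, NoEnhancementError
from .mapping import ParametricMap
from .segmentation import LABEL_ENHANCED, LABEL_MYOCARDIUM, RoiSet

__all__ = [
    "LesionReport",
    "GpcInputs",
    "enhanced_area",
    "transmurality",
    "gpc_map",
    "gpc_inputs_from_maps",
    "dice_coefficient",
]


@dataclass(frozen=True)
class LesionReport:
    """Enhancement extent for one slice and one classification method."""

    enhanced_area_pct: float
    transmurality_pct: float | None
    n_enhanced: int
    n_myocardium: int
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.enhanced_area_pct <= 100:
            raise InputError("enhanced_area_pct must be within [0, 100]")
        if self.transmurality_pct is not None and not 0 <= self.transmurality_pct <= 100:
            raise InputError("transmurality_pct must be within [0, 100]")


@dataclass(frozen=True)
class GpcInputs:
    """Pre/post-contrast T1 maps plus scalar blood T1 values (ms)."""

    t1_pre_map: ParametricMap
    t1_post_map: ParametricMap
    blood_t1_pre: float
    blood_t1_post: float

    def __post_init__(self) -> None:
        if self.t1_pre_map.shape != self.t1_post_map.shape:
            raise InputError("pre/post T1 map shapes differ")
        if not (self.blood_t1_pre > 0 and self.blood_t1_post > 0):
            raise InputError("blood T1 values must be positive")
        if not self.blood_t1_post < self.blood_t1_pre:
            raise InputError(
                "post-contrast blood T1 must be shorter than pre-contrast "
                f"(got {self.blood_t1_post} >= {self.blood_t1_pre})"
            )


def enhanced_area(rois: RoiSet, method: str = "deltaS",
                  transmurality_pct: float | None = None) -> LesionReport:
    """Enhanced area as the percentage of labelled myocardial voxels
    classified enhanced.

    Only voxels carrying a myocardial or enhanced label enter the
    denominator, so voxels invalidated upstream (e.g. below the reference
    signal floor) are excluded from both numerator and denominator.
    """
    if rois.labels is None:
        raise InputError("RoiSet has no labels; run a classification first")
    n_enh = int(np.count_nonzero(rois.labels == LABEL_ENHANCED))
    n_myo = n_enh + int(np.count_nonzero(rois.labels == LABEL_MYOCARDIUM))
    if n_myo == 0:
        raise EmptyMaskError("no labelled myocardial voxels")
    return LesionReport(
        enhanced_area_pct=100.0 * n_enh / n_myo,
        transmurality_pct=transmurality_pct,
        n_enhanced=n_enh,
        n_myocardium=n_myo,
        method=method,
    )


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    rad = np.radians(angles_deg)
    return math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0


def transmurality(rois: RoiSet, step: float = 0.25) -> float:
    """Transmurality (%) of the enhanced region.

    The center of the area of enhancement is taken as the circular mean of
    the enhanced voxels' angles about the LV center (robust to the 0/360
    wrap).  A single ray from the LV center at that angle is sampled every
    ``step`` voxels with nearest-voxel label lookup; transmurality is the
    percentage of myocardium-classified samples on the ray that are
    enhanced-classified.

    Raises
    ------
    NoEnhancementError
        If no voxel is labelled enhanced — transmurality is then undefined,
        which is distinct from a measured 0 %.
    """
    if rois.labels is None:
        raise InputError("RoiSet has no labels; run a classification first")
    enhanced = rois.labels == LABEL_ENHANCED
    if not enhanced.any():
        raise NoEnhancementError("no enhanced voxels; transmurality undefined")
    rr, cc = np.nonzero(enhanced)
    angles = np.degrees(np.arctan2(rois.lv_center[0] - rr, cc - rois.lv_center[1])) % 360.0
    theta = math.radians(_circular_mean_deg(angles))
    dr, dc = -math.sin(theta), math.cos(theta)  # row decreases with +y

    nrows, ncols = rois.myocardium.shape
    max_radius = math.hypot(nrows, ncols)
    n_myo_samples = 0
    n_enh_samples = 0
    r = 0.0
    while r <= max_radius:
        row = int(round(rois.lv_center[0] + dr * r))
        col = int(round(rois.lv_center[1] + dc * r))
        r += step
        if not (0 <= row < nrows and 0 <= col < ncols):
            break
        label = rois.labels[row, col]
        if label == LABEL_MYOCARDIUM or label == LABEL_ENHANCED:
            n_myo_samples += 1
            if label == LABEL_ENHANCED:
                n_enh_samples += 1
    if n_myo_samples == 0:
        raise NoEnhancementError(
            "central ray crossed no myocardium-labelled voxels; transmurality undefined"
        )
    return 100.0 * n_enh_samples / n_myo_samples


def gpc_map(inputs: GpcInputs, myocardium: np.ndarray) -> ParametricMap:
    """Per-voxel gadolinium partition coefficient over the myocardium.

    GPC = (1/T1_post - 1/T1_pre) / (1/blood_T1_post - 1/blood_T1_pre).
    Voxels with non-positive myocardial dR1 (or invalid in either T1 map)
    are marked invalid.  The map is dimensionless and invariant under a
    common rescaling of all four T1 inputs (ms vs s).
    """
    myocardium = np.asarray(myocardium, dtype=bool)
    if myocardium.shape != inputs.t1_pre_map.shape:
        raise InputError("myocardium mask and T1 map shapes differ")
    blood_dr1 = 1.0 / inputs.blood_t1_post - 1.0 / inputs.blood_t1_pre
    if not blood_dr1 > 0:
        raise InputError(f"blood dR1 must be positive, got {blood_dr1}")
    pre, post = inputs.t1_pre_map, inputs.t1_post_map
    base = myocardium & pre.valid_mask & post.valid_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        dr1 = 1.0 / post.values - 1.0 / pre.values
    ok = base & (pre.values > 0) & (post.values > 0) & (dr1 > 0)
    values = np.full(pre.shape, np.nan)
    values[ok] = dr1[ok] / blood_dr1
    return ParametricMap(values=values, valid_mask=ok, units="")


def gpc_inputs_from_maps(
    t1_pre_map: ParametricMap, t1_post_map: ParametricMap, blood_roi: np.ndarray
) -> GpcInputs:
    """Build GPC inputs taking blood T1 scalars as medians over the blood ROI."""
    blood_roi = np.asarray(blood_roi, dtype=bool)
    pre_vals = t1_pre_map.valid_values(blood_roi)
    post_vals = t1_post_map.valid_values(blood_roi)
    if pre_vals.size == 0 or post_vals.size == 0:
        raise EmptyMaskError("blood ROI contains no valid T1 voxels")
    return GpcInputs(
        t1_pre_map=t1_pre_map,
        t1_post_map=t1_post_map,
        blood_t1_pre=float(np.median(pre_vals)),
        blood_t1_post=float(np.median(post_vals)),
    )


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """DICE overlap 2|A & B| / (|A| + |B|) between two binary masks.

    Two empty masks are defined to agree perfectly (1.0).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / denom
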