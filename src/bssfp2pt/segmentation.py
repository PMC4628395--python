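"""Myocardial ROI handling and voxel classification.

Two classification rules are implemented, mirroring clinical practice:

* LGE rule — myocardial voxels with intensity strictly greater than
  mean + n*SD (default n = 5) of a reader-defined non-enhanced remote ROI
  are classified as enhanced.
* dS/S0 rule — valid myocardial voxels strictly above a fixed percentage
  threshold are classified as enhanced.  The default threshold of 197 %
  corresponds to mean + 3 SD of per-subject mean dS/S0 across a healthy
  control cohort; :func:`derive_delta_s_threshold` recomputes it from any
  cohort of per-subject means.

Sample standard deviations (n-1 denominator) are used throughout, and both
thresholds are strict inequalities, so raising a threshold never adds
enhanced voxels.  The module also provides border erosion (to exclude
partial-volume voxels at the blood pool and epicardial boundary) and
division of the myocardium into equal circumferential sectors about the LV
center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

from .errors import EmptyMaskError, InputError, StatisticsError
from .mapping import ParametricMap

__all__ = [
    "RoiSet",
    "ThresholdSpec",
    "LABEL_BACKGROUND",
    "LABEL_MYOCARDIUM",
    "LABEL_ENHANCED",
    "DEFAULT_DELTA_S_THRESHOLD_PCT",
    "classify_lge",
    "derive_delta_s_threshold",
    "default_delta_s_threshold",
    "classify_delta_s",
    "erode_borders",
    "sector_partition",
]

LABEL_BACKGROUND = 0
LABEL_MYOCARDIUM = 1
LABEL_ENHANCED = 2

#: Fixed dS/S0 enhancement threshold (%), the published healthy-control
#: mean + 3 SD value, used when no control cohort is supplied.
DEFAULT_DELTA_S_THRESHOLD_PCT = 197.0


@dataclass
class RoiSet:
    """Myocardial mask, remote (non-enhanced) ROI, blood-pool sample, LV
    center and the derived label map.

    Labels: 0 background, 1 non-enhanced myocardium, 2 enhanced.
    """

    myocardium: np.ndarray
    remote_roi: np.ndarray
    blood_roi: np.ndarray
    lv_center: tuple
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.myocardium = np.asarray(self.myocardium, dtype=bool)
        self.remote_roi = np.asarray(self.remote_roi, dtype=bool)
        self.blood_roi = np.asarray(self.blood_roi, dtype=bool)
        for name in ("remote_roi", "blood_roi"):
            if getattr(self, name).shape != self.myocardium.shape:
                raise InputError(f"{name} shape differs from myocardium mask")
        if np.any(self.remote_roi & ~self.myocardium):
            raise InputError("remote_roi must be a subset of the myocardial mask")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.myocardium.shape:
                raise InputError("labels shape differs from myocardium mask")
            if np.any((self.labels == LABEL_ENHANCED) & ~self.myocardium):
                raise InputError("enhanced labels must lie inside the myocardium")

    @property
    def enhanced_mask(self) -> np.ndarray:
        if self.labels is None:
            return np.zeros_like(self.myocardium)
        return self.labels == LABEL_ENHANCED

    def with_labels(self, labels: np.ndarray) -> "RoiSet":
        return replace(self, labels=labels)


@dataclass(frozen=True)
class ThresholdSpec:
    """An enhancement threshold together with the rule that produced it.

    ``rule`` is one of "mean+3SD controls", "mean+5SD remote" (with the
    actual n recorded in provenance) or "fixed"; ``provenance`` records the
    statistics or cohort values the threshold was derived from.
    """

    value: float
    rule: str
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise InputError(f"threshold value must be finite, got {self.value}")


def classify_lge(
    lge: ParametricMap, rois: RoiSet, n_sd: float = 5.0
) -> tuple[RoiSet, ThresholdSpec]:
    """Classify enhanced myocardium on an LGE image by the n-SD remote rule.

    The threshold is mean + ``n_sd`` * sample SD of the remote ROI; voxels
    strictly above it (and valid) are labelled enhanced.  Returns the
    labelled ROI set and the threshold actually applied.
    """
    remote_vals = lge.valid_values(rois.remote_roi)
    if remote_vals.size < 2:
        raise StatisticsError(
            f"remote ROI must contain >= 2 valid voxels, got {remote_vals.size}"
        )
    mean = float(np.mean(remote_vals))
    sd = float(np.std(remote_vals, ddof=1))
    threshold = ThresholdSpec(
        value=mean + n_sd * sd,
        rule=f"mean+{n_sd:g}SD remote",
        provenance={"remote_mean": mean, "remote_sd": sd, "n_remote": int(remote_vals.size)},
    )
    labels = _apply_threshold(lge, rois, threshold.value)
    return rois.with_labels(labels), threshold


def derive_delta_s_threshold(control_subject_means: Sequence[float]) -> ThresholdSpec:
    """Control-cohort dS/S0 threshold: mean + 3 * sample SD of per-subject
    mean dS/S0 values (%) across healthy controls."""
    means = np.asarray(list(control_subject_means), dtype=float)
    if means.size < 2:
        raise StatisticsError(f"need >= 2 control subjects, got {means.size}")
    if not np.all(np.isfinite(means)):
        raise InputError("control subject means must be finite")
    mean = float(np.mean(means))
    sd = float(np.std(means, ddof=1))
    return ThresholdSpec(
        value=mean + 3.0 * sd,
        rule="mean+3SD controls",
        provenance={"cohort_mean": mean, "cohort_sd": sd, "n_subjects": int(means.size)},
    )


def default_delta_s_threshold() -> ThresholdSpec:
    """The fixed fallback threshold used when no control cohort is supplied."""
    return ThresholdSpec(
        value=DEFAULT_DELTA_S_THRESHOLD_PCT,
        rule="fixed",
        provenance={"note": "published healthy-control mean+3SD default"},
    )


def classify_delta_s(
    dsmap: ParametricMap, rois: RoiSet, threshold: ThresholdSpec
) -> RoiSet:
    """Label valid myocardial voxels strictly above the dS/S0 threshold as
    enhanced.  Invalid voxels stay background-labelled and are excluded from
    both numerator and denominator downstream."""
    if not np.any(dsmap.valid_mask & rois.myocardium):
        raise EmptyMaskError("no valid myocardial voxels in dS/S0 map")
    labels = _apply_threshold(dsmap, rois, threshold.value)
    return rois.with_labels(labels)


def _apply_threshold(pmap: ParametricMap, rois: RoiSet, value: float) -> np.ndarray:
    if pmap.shape != rois.myocardium.shape:
        raise InputError("map and ROI shapes differ")
    labels = np.full(pmap.shape, LABEL_BACKGROUND, dtype=np.int8)
    valid_myo = rois.myocardium & pmap.valid_mask
    labels[valid_myo] = LABEL_MYOCARDIUM
    with np.errstate(invalid="ignore"):
        enhanced = valid_myo & (pmap.values > value)
    labels[enhanced] = LABEL_ENHANCED
    return labels


def erode_borders(rois: RoiSet, n_voxels: int = 1) -> RoiSet:
    """Erode the myocardial mask by ``n_voxels`` to drop partial-volume
    voxels at the endocardial (blood pool) and epicardial borders.

    Labels and the remote ROI are restricted to the eroded mask;
    ``n_voxels = 0`` is the identity.
    """
    if n_voxels < 0:
        raise InputError(f"n_voxels must be >= 0, got {n_voxels}")
    if n_voxels == 0:
        return rois
    eroded = binary_erosion(rois.myocardium, iterations=n_voxels)
    if not eroded.any():
        raise EmptyMaskError(f"erosion by {n_voxels} voxels emptied the myocardial mask")
    labels = None
    if rois.labels is not None:
        labels = np.where(eroded, rois.labels, LABEL_BACKGROUND).astype(rois.labels.dtype)
    return RoiSet(
        myocardium=eroded,
        remote_roi=rois.remote_roi & eroded,
        blood_roi=rois.blood_roi,
        lv_center=rois.lv_center,
        labels=labels,
    )


def voxel_angles_deg(shape: tuple, center: tuple) -> np.ndarray:
    """Angle (degrees, [0, 360)) of each voxel about ``center``, measured
    counter-clockwise from the image +x (column) axis with +y pointing from
    the center towards decreasing row index."""
    rows, cols = np.indices(shape)
    x = cols - center[1]
    y = center[0] - rows
    return np.degrees(np.arctan2(y, x)) % 360.0


def sector_partition(
    rois: RoiSet, pmap: ParametricMap, n_sectors: int = 12
) -> tuple[np.ndarray, pd.DataFrame]:
    """Divide the myocardium into equal circumferential sectors and
    summarize a map per sector.

    Each myocardial voxel is assigned sector ``floor(theta / (360/n))`` by
    its angle about the LV center (sector 0 starts at the +x axis,
    counter-clockwise).  Returns the sector label map (-1 outside the
    myocardium) and a table of per-sector mean/SD/count over valid voxels;
    sectors without valid voxels appear with NaN statistics.
    """
    if n_sectors < 1:
        raise InputError(f"n_sectors must be >= 1, got {n_sectors}")
    if rois.lv_center is None:
        raise InputError("sector partition requires lv_center")
    theta = voxel_angles_deg(rois.myocardium.shape, rois.lv_center)
    width = 360.0 / n_sectors
    sector_map = np.where(
        rois.myocardium, np.minimum((theta // width).astype(int), n_sectors - 1), -1
    )
    rows = []
    for k in range(n_sectors):
        vals = pmap.valid_values(sector_map == k)
        rows.append(
            {
                "sector": k,
                "theta_start_deg": k * width,
                "n_voxels": int(vals.size),
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
            }
        )
    return sector_map, pd.DataFrame(rows)
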