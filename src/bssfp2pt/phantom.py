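"""Synthetic mid-ventricular short-axis slice phantom.

Generates a complete, seeded dataset for exercising the 2-point bSSFP
pipeline with known ground truth: an annular myocardium around a circular
blood pool, an optional wedge-shaped lesion of prescribed angular extent
and transmurality growing radially outward from the endocardial border
(sub-endocardial pattern), paired 5/45-degree cine phase stacks whose
noise-free intensities come from the two-pool MT-bSSFP signal model,
an LGE-like image (bright lesion, dark remote myocardium, intermediate
blood), and pre/post-contrast T1 maps with a known per-tissue gadolinium
partition coefficient.

Magnitude-image noise is Rician: each voxel v becomes
sqrt((v + n1)^2 + n2^2) with n1, n2 ~ Normal(0, sigma^2), the modulus of a
complex Gaussian.  Identical spec and seed reproduce the dataset
bit-for-bit.

Default tissue parameters are literature-plausible values chosen so the
phantom reproduces the contrast regime the method relies on clinically
(remote myocardium dS/S0 well below the 197 % enhancement threshold, an
edema-like lesion well above it); they are not fitted to any study data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .errors import ParameterError
from .mapping import CineSlicePair, ParametricMap
from .segmentation import RoiSet, voxel_angles_deg
from .signal_model import AcquisitionParams, TissueParams, bssfp_signal_two_pool

__all__ = ["PhantomSpec", "PhantomTruth", "PhantomDataset", "generate_phantom",
           "add_rician_noise", "default_tissues", "default_t1_post"]


def default_tissues() -> dict:
    """Default tissue parameter set (T1/T2 in ms, F dimensionless).

    Remote myocardium is healthy muscle with a substantial macromolecular
    bound pool; the lesion emulates strongly edematous enhancing tissue
    (long T2, depleted matrix hence minimal MT); blood has long relaxation
    times and no bound pool.
    """
    return {
        "remote": TissueParams(t1=950.0, t2=46.0, bound_fraction=0.12),
        "lesion": TissueParams(t1=1200.0, t2=130.0, bound_fraction=0.01),
        "blood": TissueParams(t1=1600.0, t2=250.0, bound_fraction=0.0),
    }


def default_t1_post() -> dict:
    """Default post-contrast T1 (ms) per tissue, gadolinium-shortened."""
    return {"remote": 500.0, "lesion": 350.0, "blood": 400.0}


@dataclass
class PhantomSpec:
    """Geometry, tissue, noise and acquisition settings of one phantom."""

    image_shape: tuple = (128, 128)
    center: tuple = (64.0, 64.0)
    endo_radius: float = 20.0
    epi_radius: float = 30.0
    tissues: dict = field(default_factory=default_tissues)
    lesion_theta: tuple = (30.0, 90.0)
    lesion_transmurality: float = 1.0
    noise_sigma: float = 0.0018
    n_phases: int = 3
    seed: int = 0
    t1_post: dict = field(default_factory=default_t1_post)
    t1_noise_sigma: float = 0.0
    lge_levels: dict = field(
        default_factory=lambda: {"remote": 10.0, "blood": 45.0, "lesion": 100.0}
    )
    lge_noise_sigma: float = 1.0
    acq_low: AcquisitionParams = field(
        default_factory=lambda: AcquisitionParams(tr=3.2, te=1.2, flip_angle=5.0)
    )
    acq_high: AcquisitionParams = field(
        default_factory=lambda: AcquisitionParams(tr=3.2, te=1.2, flip_angle=45.0)
    )

    def __post_init__(self) -> None:
        if not 0 < self.endo_radius < self.epi_radius < min(self.image_shape) / 2:
            raise ParameterError(
                "need 0 < endo_radius < epi_radius < min(image_shape)/2, got "
                f"{self.endo_radius}, {self.epi_radius}, shape {self.image_shape}"
            )
        if not 0 <= self.lesion_transmurality <= 1:
            raise ParameterError(
                f"lesion_transmurality must be in [0, 1], got {self.lesion_transmurality}"
            )
        if self.n_phases < 1:
            raise ParameterError(f"n_phases must be >= 1, got {self.n_phases}")
        if self.noise_sigma < 0 or self.t1_noise_sigma < 0 or self.lge_noise_sigma < 0:
            raise ParameterError("noise scales must be >= 0")
        for name in ("remote", "lesion", "blood"):
            if name not in self.tissues:
                raise ParameterError(f"tissues must define '{name}'")
            if name not in self.t1_post:
                raise ParameterError(f"t1_post must define '{name}'")


@dataclass
class PhantomTruth:
    """Ground truth carried alongside the generated images."""

    enhanced_mask: np.ndarray
    enhanced_area_pct: float
    transmurality_pct: float | None
    gpc: dict


@dataclass
class PhantomDataset:
    """All images, masks and truth for one synthetic slice."""

    cine_pair: CineSlicePair
    lge_image: ParametricMap
    t1_pre: ParametricMap
    t1_post: ParametricMap
    rois: RoiSet
    truth: PhantomTruth
    spec: PhantomSpec
    signals: dict  # noise-free two-pool signal per (tissue, flip angle)

    def __post_init__(self) -> None:
        if np.any(self.truth.enhanced_mask & ~self.rois.myocardium):
            raise ParameterError("truth enhanced mask must lie inside the myocardium")


def add_rician_noise(image, sigma: float, seed=None, rng=None):
    """Corrupt a magnitude image with Rician noise.

    Each voxel v becomes sqrt((v + n1)^2 + n2^2), n1, n2 ~ Normal(0,
    sigma^2).  ``sigma = 0`` returns the input values unchanged.  Accepts a
    plain array or a :class:`ParametricMap` (noise is applied to valid
    voxels; the mask is preserved).
    """
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    if isinstance(image, ParametricMap):
        noisy = add_rician_noise(
            np.where(image.valid_mask, image.values, 0.0), sigma, seed=seed, rng=rng
        )
        values = np.where(image.valid_mask, noisy, np.nan)
        return ParametricMap(values=values, valid_mask=image.valid_mask.copy(),
                             units=image.units)
    arr = np.asarray(image, dtype=float)
    if sigma == 0:
        return arr.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=arr.shape)
    n2 = rng.normal(0.0, sigma, size=arr.shape)
    return np.hypot(arr + n1, n2)


def _gpc(t1_pre: float, t1_post: float, blood_pre: float, blood_post: float) -> float:
    return (1.0 / t1_post - 1.0 / t1_pre) / (1.0 / blood_post - 1.0 / blood_pre)


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Build the full synthetic dataset for one spec (deterministic in
    ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    rows, cols = np.indices(shape)
    radius = np.hypot(rows - spec.center[0], cols - spec.center[1])
    theta = voxel_angles_deg(shape, spec.center)

    blood_mask = radius < spec.endo_radius
    myocardium = (radius >= spec.endo_radius) & (radius < spec.epi_radius)

    # Wedge lesion grown radially outward from the endocardial border;
    # clipped to the annulus by construction.
    t1_ang, t2_ang = (a % 360.0 for a in spec.lesion_theta)
    if t1_ang <= t2_ang:
        in_wedge = (theta >= t1_ang) & (theta < t2_ang)
    else:  # interval wraps through 0 degrees
        in_wedge = (theta >= t1_ang) | (theta < t2_ang)
    lesion_outer = spec.endo_radius + spec.lesion_transmurality * (
        spec.epi_radius - spec.endo_radius
    )
    lesion = myocardium & in_wedge & (radius < lesion_outer)
    if spec.lesion_transmurality == 0:
        lesion &= False

    # Remote ROI: myocardium away from the lesion (2-voxel guard band).
    if lesion.any():
        remote_roi = myocardium & ~binary_dilation(lesion, iterations=2)
    else:
        remote_roi = myocardium.copy()
    blood_roi = radius < max(spec.endo_radius - 2.0, 1.0)

    # Noise-free two-pool signal per tissue and flip angle.
    signals = {}
    for name, tissue in spec.tissues.items():
        for acq in (spec.acq_low, spec.acq_high):
            signals[(name, acq.flip_angle)] = bssfp_signal_two_pool(acq, tissue)

    def tissue_field(level_for) -> np.ndarray:
        img = np.zeros(shape)
        img[blood_mask] = level_for("blood")
        img[myocardium] = level_for("remote")
        img[lesion] = level_for("lesion")
        return img

    clean_low = tissue_field(lambda n: signals[(n, spec.acq_low.flip_angle)])
    clean_high = tissue_field(lambda n: signals[(n, spec.acq_high.flip_angle)])
    low_phases = [add_rician_noise(clean_low, spec.noise_sigma, rng=rng)
                  for _ in range(spec.n_phases)]
    high_phases = [add_rician_noise(clean_high, spec.noise_sigma, rng=rng)
                   for _ in range(spec.n_phases)]
    cine_pair = CineSlicePair(
        low_phases=low_phases,
        high_phases=high_phases,
        low_angle=spec.acq_low.flip_angle,
        high_angle=spec.acq_high.flip_angle,
    )

    lge_values = add_rician_noise(
        tissue_field(lambda n: spec.lge_levels[n]), spec.lge_noise_sigma, rng=rng
    )
    lge_image = ParametricMap(values=lge_values, valid_mask=np.ones(shape, bool),
                              units="a.u.")

    body = myocardium | blood_mask
    t1_pre_vals = tissue_field(lambda n: spec.tissues[n].t1)
    t1_post_vals = tissue_field(lambda n: spec.t1_post[n])
    if spec.t1_noise_sigma > 0:
        t1_pre_vals = t1_pre_vals + rng.normal(0, spec.t1_noise_sigma, shape)
        t1_post_vals = t1_post_vals + rng.normal(0, spec.t1_noise_sigma, shape)
    t1_pre = ParametricMap(
        values=np.where(body, t1_pre_vals, np.nan), valid_mask=body, units="ms"
    )
    t1_post = ParametricMap(
        values=np.where(body, t1_post_vals, np.nan), valid_mask=body, units="ms"
    )

    rois = RoiSet(
        myocardium=myocardium,
        remote_roi=remote_roi,
        blood_roi=blood_roi,
        lv_center=tuple(spec.center),
    )

    blood_pre, blood_post = spec.tissues["blood"].t1, spec.t1_post["blood"]
    truth = PhantomTruth(
        enhanced_mask=lesion,
        enhanced_area_pct=100.0 * lesion.sum() / myocardium.sum(),
        transmurality_pct=(100.0 * spec.lesion_transmurality if lesion.any() else None),
        gpc={
            name: _gpc(spec.tissues[name].t1, spec.t1_post[name], blood_pre, blood_post)
            for name in ("remote", "lesion", "blood")
        },
    )
    return PhantomDataset(
        cine_pair=cine_pair,
        lge_image=lge_image,
        t1_pre=t1_pre,
        t1_post=t1_post,
        rois=rois,
        truth=truth,
        spec=spec,
        signals=signals,
    )
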