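"""Reading and writing images, masks and phantom datasets.

NIfTI (via nibabel) is the canonical interchange format: cine phase stacks
are 3-D volumes with the phase along the last axis, parametric maps are
2-D volumes with NaN at invalid voxels and a JSON sidecar recording units
and processing history.  A DICOM series directory can be read as an
optional input adapter; any metadata a file does not carry is reported as
an explicit ``None``, never silently defaulted.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError
from .mapping import ParametricMap

__all__ = [
    "read_image_volume",
    "write_image_volume",
    "read_map",
    "write_map",
    "read_mask",
    "write_mask",
    "read_dicom_series",
    "write_phantom_dataset",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_image_volume(path) -> tuple[np.ndarray, dict]:
    """Read a NIfTI volume (or DICOM series directory) with its metadata.

    Returns ``(data, metadata)`` where metadata holds ``voxel_spacing``
    plus any ``flip_angle_deg`` / ``tr_ms`` found in a JSON sidecar or the
    DICOM headers; missing entries are explicit ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if path.is_dir():
        return read_dicom_series(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    meta = {
        "voxel_spacing": tuple(float(z) for z in img.header.get_zooms()),
        "flip_angle_deg": None,
        "tr_ms": None,
    }
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta.update(json.load(fh))
    return data, meta


def write_image_volume(data: np.ndarray, path, sidecar: dict | None = None) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4)), str(path))
    if sidecar is not None:
        with open(_sidecar_path(path), "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)


def write_map(pmap: ParametricMap, path, history: dict | None = None) -> None:
    """Write a parametric map with NaN at invalid voxels plus a JSON
    sidecar recording units and processing history."""
    values = np.where(pmap.valid_mask, pmap.values, np.nan)
    sidecar = {"units": pmap.units, "history": history or {}}
    write_image_volume(values, path, sidecar=sidecar)


def read_map(path) -> ParametricMap:
    data, meta = read_image_volume(path)
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    return ParametricMap(values=data, valid_mask=np.isfinite(data),
                         units=meta.get("units", ""))


def write_mask(mask: np.ndarray, path) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(mask).astype(np.uint8), affine=np.eye(4)), str(Path(path))
    )


def read_mask(path) -> np.ndarray:
    data, _ = read_image_volume(path)
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    return data.astype(np.uint8)


def read_dicom_series(directory) -> tuple[np.ndarray, dict]:
    """Read a single-series DICOM directory into a (rows, cols, n) stack.

    Slices are ordered by InstanceNumber.  FlipAngle and RepetitionTime
    are taken from the first file when present, else ``None``.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file()
    )
    if not files:
        raise FormatError(f"no DICOM files found in {directory}")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception as exc:
            raise FormatError(f"could not read DICOM file {f}: {exc}") from exc
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    try:
        stack = np.stack([d.pixel_array.astype(float) for d in datasets], axis=-1)
    except Exception as exc:
        raise FormatError(f"could not assemble pixel data from {directory}: {exc}") from exc
    first = datasets[0]
    spacing = getattr(first, "PixelSpacing", None)
    meta = {
        "voxel_spacing": tuple(float(s) for s in spacing) if spacing is not None else None,
        "flip_angle_deg": float(first.FlipAngle) if hasattr(first, "FlipAngle") else None,
        "tr_ms": float(first.RepetitionTime) if hasattr(first, "RepetitionTime") else None,
    }
    return stack, meta


def write_phantom_dataset(dataset, out_dir) -> dict:
    """Write a phantom dataset to a directory as NIfTI + JSON truth record.

    Returns the mapping of logical names to file paths.
    """
    from .segmentation import LABEL_ENHANCED  # noqa: F401  (labels written raw)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = dataset.spec
    paths = {}

    def _p(name: str) -> Path:
        paths[name] = out_dir / name
        return paths[name]

    cine_low = np.stack(dataset.cine_pair.low_phases, axis=-1)
    cine_high = np.stack(dataset.cine_pair.high_phases, axis=-1)
    write_image_volume(cine_low, _p("cine_low.nii.gz"),
                       sidecar={"flip_angle_deg": dataset.cine_pair.low_angle,
                                "tr_ms": spec.acq_low.tr})
    write_image_volume(cine_high, _p("cine_high.nii.gz"),
                       sidecar={"flip_angle_deg": dataset.cine_pair.high_angle,
                                "tr_ms": spec.acq_high.tr})
    write_map(dataset.lge_image, _p("lge.nii.gz"))
    write_map(dataset.t1_pre, _p("t1_pre.nii.gz"))
    write_map(dataset.t1_post, _p("t1_post.nii.gz"))
    write_mask(dataset.rois.myocardium, _p("myocardium.nii.gz"))
    write_mask(dataset.rois.remote_roi, _p("remote_roi.nii.gz"))
    write_mask(dataset.rois.blood_roi, _p("blood_roi.nii.gz"))
    write_mask(dataset.truth.enhanced_mask, _p("truth_enhanced.nii.gz"))
    truth = {
        "enhanced_area_pct": dataset.truth.enhanced_area_pct,
        "transmurality_pct": dataset.truth.transmurality_pct,
        "gpc": dataset.truth.gpc,
        "lv_center": list(dataset.rois.lv_center),
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
        "lesion_theta": list(spec.lesion_theta),
        "lesion_transmurality": spec.lesion_transmurality,
    }
    with open(_p("truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths
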