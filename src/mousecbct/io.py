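"""Reading and writing scan volumes (NIfTI, DICOM series) and sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .voxcore import BinaryMask, ScanVolume

__all__ = [
    "load_nifti",
    "save_nifti",
    "save_mask_nifti",
    "load_dicom_series",
    "save_phantom",
]


def save_nifti(vol: ScanVolume, path) -> None:
    affine = np.diag([vol.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = vol.origin_mm
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine), str(path))


def save_mask_nifti(mask: BinaryMask, origin_mm, path) -> None:
    affine = np.diag([mask.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = np.asarray(origin_mm, dtype=float)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def load_nifti(path) -> ScanVolume:
    """Load a NIfTI volume; requires isotropic spacing within 1%."""
    img = nib.load(str(path))
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if zooms.max() / zooms.min() > 1.01:
        raise ValueError(f"anisotropic voxels {zooms} not supported")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return ScanVolume(data, float(zooms.mean()), origin)


def load_dicom_series(directory) -> ScanVolume:
    """Load a DICOM series as one volume.

    Slices are sorted by position along the slice normal; in-plane and
    inter-slice spacing must agree within 1% (the scanner's isotropic
    reconstruction).  Array axes follow the package convention
    (x = columns, y = rows, z = slices).
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ""))
    datasets = []
    for p in files:
        if not p.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"no DICOM files in {directory}")
    d0 = datasets[0]
    orient = np.asarray(getattr(d0, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    normal = np.cross(orient[:3], orient[3:])
    datasets.sort(key=lambda d: float(np.dot(np.asarray(d.ImagePositionPatient, float), normal)))
    positions = [float(np.dot(np.asarray(d.ImagePositionPatient, float), normal)) for d in datasets]
    dz = np.diff(positions)
    px = np.asarray(d0.PixelSpacing, dtype=float)
    spacings = np.array([px[0], px[1], float(np.mean(dz))])
    if spacings.max() / spacings.min() > 1.01:
        raise ValueError(f"anisotropic DICOM spacing {spacings} not supported")
    # pixel_array is (rows, cols); package order is (x=cols, y=rows, z=slice)
    data = np.stack([d.pixel_array.T for d in datasets], axis=-1).astype(np.float32)
    slope = float(getattr(d0, "RescaleSlope", 1.0))
    intercept = float(getattr(d0, "RescaleIntercept", 0.0))
    data = data * slope + intercept
    origin = np.asarray(d0.ImagePositionPatient, dtype=float)
    return ScanVolume(data, float(spacings.mean()), origin)


def save_head_volume(head, directory, stem: str = "head") -> None:
    """Write a resampled head and its per-voxel volume map as a NIfTI pair."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    s = head.lattice_spacing_mm
    affine = np.diag([s, s, s, 1.0])
    nib.save(
        nib.Nifti1Image(head.data.astype(np.float32), affine),
        str(directory / f"{stem}.nii.gz"),
    )
    nib.save(
        nib.Nifti1Image(head.voxel_volumes.astype(np.float32), affine),
        str(directory / f"{stem}_voxel_volumes.nii.gz"),
    )


def save_phantom(vol: ScanVolume, truth, directory) -> None:
    """Write a phantom as NIfTI plus a JSON ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_nifti(vol, directory / "phantom.nii.gz")
    doc = {
        "layout": truth.layout,
        "spacing_mm": truth.spacing_mm,
        "noise_sigma": truth.noise_sigma,
        "platform_heights_mm": list(truth.platform_heights_mm),
        "water": truth.water,
        "mice": [
            {
                "mouse_id": m.mouse_id,
                "slot": m.slot,
                "occupied": m.occupied,
                "head_center_mm": list(map(float, m.head_center_mm)),
                "bend_deg": m.bend_deg,
                "tumor_volume_mm3": m.tumor_volume_mm3,
                "tumor_analytic_mm3": m.tumor_analytic_mm3,
                "landmarks": {k: list(map(float, v)) for k, v in m.landmarks.items()},
            }
            for m in truth.mice
        ],
    }
    (directory / "truth.json").write_text(json.dumps(doc, indent=2))
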