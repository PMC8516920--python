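"""CT volumes and file I/O.

A volume is a 3D array of Hounsfield units with the axial slice axis last,
slices ordered cranial to caudal, and 0-based voxel coordinates.  All modules
in this package share that convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass
class CTVolume:
    """A 3D HU array with voxel spacing (mm) and optional anatomical masks."""

    hu: np.ndarray
    spacing: tuple[float, float, float]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float32)
        if self.hu.ndim != 3:
            raise ValueError(f"expected a 3D HU array, got shape {self.hu.shape}")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU array contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        for name, m in self.masks.items():
            if m.shape != self.hu.shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != volume {self.hu.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.hu.shape[2]


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: CTVolume, path: str | os.PathLike, dtype=np.int16) -> None:
    """Write a volume as NIfTI; HU are rounded to integers for integer dtypes."""
    import nibabel as nib

    data = volume.hu
    if np.issubdtype(np.dtype(dtype), np.integer):
        data = np.rint(data).astype(dtype)
    else:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, _affine_from_spacing(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, os.fspath(path))


def _read_nifti(path: str) -> CTVolume:
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    zooms = img.header.get_zooms()[:3]
    return CTVolume(hu=data, spacing=tuple(float(z) for z in zooms))


def _read_dicom_series(directory: str) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    if not files:
        raise ValueError(f"no files in DICOM directory {directory!r}")
    slices = [pydicom.dcmread(f) for f in files]

    def z_pos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(ds.InstanceNumber)

    slices.sort(key=z_pos)

    rows = {(int(ds.Rows), int(ds.Columns)) for ds in slices}
    if len(rows) != 1:
        raise ValueError(f"mixed slice dimensions in series: {sorted(rows)}")
    px = {tuple(float(v) for v in ds.PixelSpacing) for ds in slices}
    if len(px) != 1:
        raise ValueError(f"inconsistent PixelSpacing across slices: {sorted(px)}")
    (dy, dx) = px.pop()

    zs = [z_pos(ds) for ds in slices]
    dz_all = np.diff(zs)
    if len(dz_all) > 0:
        if np.any(dz_all <= 0):
            raise ValueError("non-monotone slice positions after sorting")
        if not np.allclose(dz_all, dz_all[0], rtol=1e-3):
            raise ValueError("non-uniform slice spacing in series")
        dz = float(dz_all[0])
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(slope * arr + intercept)
    # pixel_array is (row, col) = (y, x); store as (x, y, z)
    hu = np.stack([p.T for p in planes], axis=-1)
    return CTVolume(hu=hu, spacing=(dx, dy, dz))


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a NIfTI file or a directory of single-series DICOM axial slices.

    DICOM rescale slope/intercept is applied and slices are sorted by
    cranio-caudal position, so a shuffled series reads identically to a
    sorted one.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        return _read_dicom_series(path)
    return _read_nifti(path)
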