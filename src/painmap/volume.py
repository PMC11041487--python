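"""CT volumes in Hounsfield units and their coordinate geometry.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)`` = (slice, row, column);
* ``spacing_mm`` and ``origin_mm`` are stored in the same ``(z, y, x)``
  axis order;
* world coordinates are axis-aligned millimetres with the origin at the
  world position of voxel ``(0, 0, 0)`` — a deliberate simplification of
  full DICOM geometry (no direction cosines).

External tables (center-point CSVs) use ``x_mm, y_mm, z_mm`` columns,
where ``x`` is the column axis; :func:`world_xyz_to_zyx` converts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk

__all__ = [
    "CTVolume",
    "CenterPoint",
    "read_ct",
    "write_nrrd",
    "write_dicom_series",
    "world_to_voxel",
    "voxel_to_world",
    "world_xyz_to_zyx",
    "world_zyx_to_xyz",
]


@dataclass
class CTVolume:
    """A 3D scalar grid of Hounsfield units with geometry metadata."""

    values: np.ndarray                      # (z, y, x), HU
    spacing_mm: np.ndarray                  # (z, y, x), > 0
    origin_mm: np.ndarray = None            # (z, y, x) world mm of voxel (0,0,0)
    patient_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("CT volume must be a 3D array")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be 3 positive values (z, y, x)")
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinate grids (z, y, x) of every voxel center."""
        axes = [
            self.origin_mm[a] + np.arange(self.shape[a]) * self.spacing_mm[a]
            for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")

    def contains_world(self, p_zyx) -> bool:
        idx = world_to_voxel(p_zyx, self)
        return bool(np.all(idx > -0.5) and np.all(idx < np.array(self.shape) - 0.5))


@dataclass(frozen=True)
class CenterPoint:
    """An expert-identified lesion center, world mm in (z, y, x) order."""

    patient_id: str
    lesion_id: str
    position_mm: tuple  # (z, y, x)

    def __post_init__(self):
        object.__setattr__(self, "position_mm", tuple(float(v) for v in self.position_mm))
        if len(self.position_mm) != 3:
            raise ValueError("position_mm must have 3 components (z, y, x)")


def world_xyz_to_zyx(p_xyz) -> tuple:
    x, y, z = p_xyz
    return (float(z), float(y), float(x))


def world_zyx_to_xyz(p_zyx) -> tuple:
    z, y, x = p_zyx
    return (float(x), float(y), float(z))


def world_to_voxel(p_zyx, volume: CTVolume) -> np.ndarray:
    """Fractional voxel index of a world point: ``(p - origin) / spacing``."""
    p = np.asarray(p_zyx, dtype=float)
    return (p - volume.origin_mm) / volume.spacing_mm


def voxel_to_world(idx_zyx, volume: CTVolume) -> np.ndarray:
    idx = np.asarray(idx_zyx, dtype=float)
    return volume.origin_mm + idx * volume.spacing_mm


# ---------------------------------------------------------------------------
# I/O


def write_nrrd(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as an uncompressed NRRD file (HU, float or int)."""
    img = sitk.GetImageFromArray(volume.values)
    img.SetSpacing(tuple(volume.spacing_mm[::-1]))   # sitk wants (x, y, z)
    img.SetOrigin(tuple(volume.origin_mm[::-1]))
    writer = sitk.ImageFileWriter()
    writer.SetFileName(str(path))
    writer.SetUseCompression(False)
    writer.Execute(img)


def write_dicom_series(volume: CTVolume, directory: str | os.PathLike) -> list[str]:
    """Write one CT DICOM file per slice, HU stored with rescale -1024."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    intercept = -1024.0
    stored = np.round(volume.values - intercept).astype(np.int16)
    if stored.min() < 0:
        raise ValueError("HU below -1024 cannot be stored with this rescale")
    paths = []
    for k in range(volume.shape[0]):
        ds = pydicom.Dataset()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = pydicom.uid.generate_uid()
        ds.Modality = "CT"
        ds.PatientID = volume.patient_id or "anon"
        ds.SeriesInstanceUID = pydicom.uid.generate_uid() if k == 0 else ds0.SeriesInstanceUID
        if k == 0:
            ds0 = ds
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            float(volume.origin_mm[2]),
            float(volume.origin_mm[1]),
            float(volume.origin_mm[0] + k * volume.spacing_mm[0]),
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [float(volume.spacing_mm[1]), float(volume.spacing_mm[2])]
        ds.SliceThickness = float(volume.spacing_mm[0])
        ds.Rows, ds.Columns = stored.shape[1], stored.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = intercept
        ds.RescaleSlope = 1.0
        ds.PixelData = stored[k].tobytes()
        ds.file_meta = pydicom.dataset.FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(str(path))
    return paths


def _read_dicom_series(directory: Path) -> CTVolume:
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    orientations = {tuple(np.round(np.asarray(s.ImageOrientationPatient, float), 6))
                    for s in slices}
    if len(orientations) != 1:
        raise ValueError("mixed-orientation DICOM series")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    dz = np.diff(zs)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-3):
        raise ValueError("missing or unevenly spaced slices in DICOM series")
    hu = np.stack([
        s.pixel_array.astype(float) * float(s.RescaleSlope) + float(s.RescaleIntercept)
        for s in slices
    ])
    s0 = slices[0]
    spacing = np.array([
        dz[0] if len(dz) else float(getattr(s0, "SliceThickness", 1.0)),
        float(s0.PixelSpacing[0]),
        float(s0.PixelSpacing[1]),
    ])
    origin = np.array([
        float(s0.ImagePositionPatient[2]),
        float(s0.ImagePositionPatient[1]),
        float(s0.ImagePositionPatient[0]),
    ])
    return CTVolume(hu, spacing, origin, patient_id=str(getattr(s0, "PatientID", "")))


def read_ct(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from an NRRD file or a DICOM series directory.

    DICOM pixel data are mapped to HU via rescale slope/intercept; a
    mixed-orientation or gappy series raises ``ValueError``.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img)
    return CTVolume(
        values=np.asarray(values, dtype=float),
        spacing_mm=np.asarray(img.GetSpacing())[::-1],
        origin_mm=np.asarray(img.GetOrigin())[::-1],
    )
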