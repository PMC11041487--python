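"""Center-point-based nested spherical ROIs with HU thresholding.

A lesion is represented only by its expert-identified center point; the
ROI is a sphere of nominal diameter around that point, voxelized by the
voxel-center inclusion rule (a voxel belongs to the sphere iff the world
distance from its center to the lesion center is at most the radius,
measured in mm so anisotropic spacing is respected).  Fat and air are
excluded by removing voxels whose Gaussian-smoothed HU falls below a
threshold (default 0 HU); raw HU values are never modified, so feature
extraction downstream sees the original intensities.

Two ensembles of nested spheres are predefined:

* ``EN3`` — diameters 7, 10, 15 mm
* ``EN6`` — diameters 7, 10, 15, 20, 30, 50 mm
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
import SimpleITK as sitk

from .volume import CTVolume, CenterPoint, world_to_voxel

__all__ = [
    "ROIMask",
    "EnsembleSpec",
    "EN3",
    "EN6",
    "EmptyROIError",
    "make_sphere_mask",
    "apply_hu_threshold",
    "build_nested",
    "write_mask_nrrd",
    "read_mask_nrrd",
]


class EmptyROIError(ValueError):
    """Raised when thresholding removes every voxel of an ROI."""


@dataclass
class ROIMask:
    mask: np.ndarray                 # bool, co-shaped with the CT volume
    diameter_mm: float
    center: CenterPoint
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    thresholded: bool = False
    clipped: bool = False            # sphere extended past the grid edge
    warnings: list = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class EnsembleSpec:
    name: str
    diameters_mm: tuple

    def __post_init__(self):
        object.__setattr__(self, "diameters_mm", tuple(float(d) for d in self.diameters_mm))
        if any(d <= 0 for d in self.diameters_mm):
            raise ValueError("diameters must be positive")
        if list(self.diameters_mm) != sorted(self.diameters_mm):
            raise ValueError("diameters must be in increasing order")


EN3 = EnsembleSpec("EN3", (7.0, 10.0, 15.0))
EN6 = EnsembleSpec("EN6", (7.0, 10.0, 15.0, 20.0, 30.0, 50.0))

ENSEMBLES = {"EN3": EN3, "EN6": EN6}


def make_sphere_mask(volume: CTVolume, center: CenterPoint, diameter_mm: float) -> ROIMask:
    """Voxelize a sphere of ``diameter_mm`` around ``center``.

    A voxel is included iff its center's world distance to the lesion
    center is <= ``diameter_mm / 2``.  Spheres that extend beyond the
    grid are clipped, with a warning recorded on the mask.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be positive")
    c = np.asarray(center.position_mm, dtype=float)
    if not volume.contains_world(c):
        raise ValueError(
            f"center point {center.patient_id}/{center.lesion_id} lies outside the volume"
        )
    r = diameter_mm / 2.0
    shape = np.array(volume.shape)
    # bounding box of the sphere in voxel indices
    lo = np.floor(world_to_voxel(c - r, volume)).astype(int)
    hi = np.ceil(world_to_voxel(c + r, volume)).astype(int) + 1
    clipped = bool(np.any(lo < 0) or np.any(hi > shape))
    lo_c = np.clip(lo, 0, shape)
    hi_c = np.clip(hi, 0, shape)

    mask = np.zeros(volume.shape, dtype=bool)
    axes = [
        volume.origin_mm[a] + np.arange(lo_c[a], hi_c[a]) * volume.spacing_mm[a] - c[a]
        for a in range(3)
    ]
    dz, dy, dx = np.meshgrid(*axes, indexing="ij", sparse=True)
    inside = dz * dz + dy * dy + dx * dx <= r * r
    mask[lo_c[0]:hi_c[0], lo_c[1]:hi_c[1], lo_c[2]:hi_c[2]] = inside

    roi = ROIMask(
        mask=mask,
        diameter_mm=float(diameter_mm),
        center=center,
        spacing_mm=volume.spacing_mm.copy(),
        origin_mm=volume.origin_mm.copy(),
        clipped=clipped,
    )
    if clipped:
        roi.warnings.append(
            f"sphere d={diameter_mm} mm at {center.lesion_id} clipped at grid edge"
        )
    return roi


def smoothed_hu(volume: CTVolume, sigma_mm: float) -> np.ndarray:
    """Gaussian-smoothed copy of the HU grid (kernel width in mm)."""
    if sigma_mm <= 0:
        return volume.values.astype(float)
    sigma_vox = sigma_mm / volume.spacing_mm
    return gaussian_filter(volume.values.astype(float), sigma=sigma_vox)


def apply_hu_threshold(
    volume: CTVolume,
    roi: ROIMask,
    sigma_mm: float = 1.0,
    hu_min: float = 0.0,
    smoothed: np.ndarray | None = None,
) -> ROIMask:
    """Remove fat/air voxels: keep voxels whose smoothed HU is >= ``hu_min``.

    The threshold is decided on a Gaussian-smoothed copy of the volume;
    the raw HU grid is untouched.  ``smoothed`` may be passed to reuse
    one smoothed field across the nested diameters (this also preserves
    nesting under thresholding).  Raises :class:`EmptyROIError` if no
    voxel survives.
    """
    if roi.thresholded:
        raise ValueError("ROI is already thresholded")
    if smoothed is None:
        smoothed = smoothed_hu(volume, sigma_mm)
    keep = roi.mask & (smoothed >= hu_min)
    if not keep.any():
        raise EmptyROIError(
            f"ROI {roi.center.patient_id}/{roi.center.lesion_id} d={roi.diameter_mm} "
            f"is empty after HU>={hu_min} threshold"
        )
    out = ROIMask(
        mask=keep,
        diameter_mm=roi.diameter_mm,
        center=roi.center,
        spacing_mm=roi.spacing_mm,
        origin_mm=roi.origin_mm,
        thresholded=True,
        clipped=roi.clipped,
        warnings=list(roi.warnings),
    )
    return out


def build_nested(
    volume: CTVolume,
    center: CenterPoint,
    spec: EnsembleSpec = EN6,
    sigma_mm: float = 1.0,
    hu_min: float = 0.0,
    threshold: bool = True,
) -> list[ROIMask]:
    """One (optionally thresholded) sphere mask per ensemble diameter.

    The same smoothed HU field is used for every diameter, so nesting
    ``mask(d1) ⊆ mask(d2)`` for d1 <= d2 survives thresholding.
    """
    field_ = smoothed_hu(volume, sigma_mm) if threshold else None
    out = []
    for d in spec.diameters_mm:
        m = make_sphere_mask(volume, center, d)
        if threshold:
            m = apply_hu_threshold(volume, m, sigma_mm, hu_min, smoothed=field_)
        out.append(m)
    return out


def write_mask_nrrd(roi: ROIMask, path: str | os.PathLike) -> None:
    """Store a binary mask as uncompressed NRRD with spacing/origin metadata."""
    img = sitk.GetImageFromArray(roi.mask.astype(np.uint8))
    img.SetSpacing(tuple(np.asarray(roi.spacing_mm, float)[::-1]))
    img.SetOrigin(tuple(np.asarray(roi.origin_mm, float)[::-1]))
    writer = sitk.ImageFileWriter()
    writer.SetFileName(str(path))
    writer.SetUseCompression(False)
    writer.Execute(img)


def read_mask_nrrd(path: str | os.PathLike, center: CenterPoint | None = None,
                   diameter_mm: float = float("nan")) -> ROIMask:
    img = sitk.ReadImage(str(path))
    return ROIMask(
        mask=sitk.GetArrayFromImage(img).astype(bool),
        diameter_mm=diameter_mm,
        center=center or CenterPoint("", "", (0.0, 0.0, 0.0)),
        spacing_mm=np.asarray(img.GetSpacing())[::-1],
        origin_mm=np.asarray(img.GetOrigin())[::-1],
        thresholded=True,
    )
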