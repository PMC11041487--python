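"""Phantom CT volumes with planted bone-metastasis lesions.

The phantom emulates a thoracic-spine simulation CT at the level of HU
statistics, not anatomy: a bright bone cylinder (vertebral body) runs
along the slice axis, surrounded by a negative-HU fat/air shell so the
HU>0 threshold has something nontrivial to remove.  Lesions are spheres
whose interior HU offset depends on class (lytic below background,
blastic above, mixed spatially mixed), and painful lesions additionally
carry a planted signal: an HU offset inside the lesion, a second offset
in a surrounding shell (so ensembles that reach beyond the lesion see
extra signal), and spatially correlated texture noise with a
configurable correlation length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ..volume import CTVolume, CenterPoint

__all__ = [
    "TextureParams",
    "LesionSpec",
    "PhantomSpec",
    "PlantedLesion",
    "generate_phantom",
    "LESION_CLASSES",
    "CLASS_HU_OFFSET",
]

LESION_CLASSES = ("lytic", "blastic", "mixed")

# interior HU offset relative to background bone, by lesion class
CLASS_HU_OFFSET = {"lytic": -150.0, "blastic": 200.0}

FAT_SHELL_HU = -100.0


@dataclass(frozen=True)
class TextureParams:
    """Planted painful-vs-painless signal.

    ``pain_hu_offset`` is added inside the lesion sphere of painful
    lesions; ``shell_hu_offset`` in the shell between the lesion surface
    and ``shell_outer_radius_mm`` (putting part of the signal outside
    the small ROIs); ``correlation_mm`` sets the length scale of extra
    correlated texture noise (SD ``texture_sd_hu``) applied over lesion
    plus shell of painful lesions.
    """

    pain_hu_offset: float = 20.0
    shell_hu_offset: float = 30.0
    shell_outer_radius_mm: float = 22.0
    correlation_mm: float = 4.0
    texture_sd_hu: float = 25.0


@dataclass(frozen=True)
class LesionSpec:
    center_mm: tuple              # (z, y, x) world mm
    diameter_mm: float
    lesion_class: str
    painful: bool
    texture_params: TextureParams = field(default_factory=TextureParams)

    def __post_init__(self):
        object.__setattr__(self, "center_mm", tuple(float(v) for v in self.center_mm))
        if not 0 < self.diameter_mm <= 50:
            raise ValueError("diameter_mm must be in (0, 50]")
        if self.lesion_class not in LESION_CLASSES:
            raise ValueError(f"lesion_class must be one of {LESION_CLASSES}")


@dataclass
class PhantomSpec:
    grid_shape: tuple = (48, 56, 56)          # (z, y, x) voxels
    spacing_mm: tuple = (2.5, 2.0, 2.0)
    background_hu: float = 300.0              # simulated trabecular bone
    noise_sd_hu: float = 35.0
    lesion_specs: list = field(default_factory=list)
    seed: int = 0
    bone_radius_fraction: float = 0.42        # of the smaller in-plane half-extent

    def __post_init__(self):
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.spacing_mm = tuple(float(v) for v in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive on every axis")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        extent = np.array(self.grid_shape) * np.array(self.spacing_mm)
        for i, les in enumerate(self.lesion_specs):
            c = np.asarray(les.center_mm)
            # every lesion must fit its 50 mm ROI bounding sphere
            if np.any(c - 25.0 < -1e-9) or np.any(c + 25.0 > extent + 1e-9):
                raise ValueError(
                    f"lesion {i} at {les.center_mm} mm: 50 mm bounding sphere "
                    f"exceeds the grid extent {tuple(extent)} mm"
                )


@dataclass(frozen=True)
class PlantedLesion:
    center: CenterPoint
    spec: LesionSpec


def _distance_field(shape, spacing, center_mm) -> np.ndarray:
    axes = [np.arange(shape[a]) * spacing[a] - center_mm[a] for a in range(3)]
    dz, dy, dx = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(dz * dz + dy * dy + dx * dx)


def _correlated_noise(rng, shape, spacing, correlation_mm, sd) -> np.ndarray:
    raw = rng.standard_normal(shape)
    sigma_vox = np.maximum(correlation_mm / np.asarray(spacing), 1e-6)
    sm = gaussian_filter(raw, sigma=sigma_vox)
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def generate_phantom(spec: PhantomSpec, patient_id: str = "P000") -> tuple[CTVolume, list[PlantedLesion]]:
    """Render a phantom volume and return it with its planted lesions.

    Deterministic given ``spec.seed``; with zero lesions the volume is
    pure background (bone cylinder + fat shell + noise).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing_mm)
    extent = np.array(shape) * spacing

    hu = np.full(shape, FAT_SHELL_HU, dtype=float)
    # bone cylinder along z, centered in-plane
    cy, cx = extent[1] / 2, extent[2] / 2
    yy = np.arange(shape[1]) * spacing[1] - cy
    xx = np.arange(shape[2]) * spacing[2] - cx
    ry, rx = np.meshgrid(yy, xx, indexing="ij")
    bone_r = spec.bone_radius_fraction * min(extent[1], extent[2]) / 2
    bone = (ry * ry + rx * rx) <= bone_r * bone_r
    hu[:, bone] = spec.background_hu

    planted: list[PlantedLesion] = []
    for i, les in enumerate(spec.lesion_specs):
        dist = _distance_field(shape, spacing, les.center_mm)
        inside = dist <= les.diameter_mm / 2.0
        if les.lesion_class == "mixed":
            # spatially mixed lytic/blastic compartments from a smoothed field
            fieldn = _correlated_noise(rng, shape, spacing, 4.0, 1.0)
            hu[inside] += np.where(fieldn[inside] > 0,
                                   CLASS_HU_OFFSET["blastic"],
                                   CLASS_HU_OFFSET["lytic"])
        else:
            hu[inside] += CLASS_HU_OFFSET[les.lesion_class]
        tp = les.texture_params
        if les.painful:
            shell = (dist > les.diameter_mm / 2.0) & (dist <= tp.shell_outer_radius_mm)
            hu[inside] += tp.pain_hu_offset
            hu[shell] += tp.shell_hu_offset
            if tp.texture_sd_hu > 0:
                tex = _correlated_noise(rng, shape, spacing, tp.correlation_mm,
                                        tp.texture_sd_hu)
                region = inside | shell
                hu[region] += tex[region]
        planted.append(
            PlantedLesion(
                center=CenterPoint(patient_id, f"L{i:02d}", les.center_mm),
                spec=les,
            )
        )

    if spec.noise_sd_hu > 0:
        hu += rng.normal(0.0, spec.noise_sd_hu, size=shape)

    vol = CTVolume(values=hu, spacing_mm=spacing, origin_mm=np.zeros(3),
                   patient_id=patient_id, image_id=patient_id)
    return vol, planted
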