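"""On-disk synthetic study cohorts.

A cohort is a set of patient "note-image pairs": one phantom CT volume
(NRRD), one consultation note (UTF-8 text), a center-point table and a
ground-truth label table.  All lesions of one image share one pain
status — the note's pain status — mirroring how a single note-level
label propagates to every lesion of the paired image.

The default parameters emulate the study conditions: ~84%/16%
painful/painless lesion imbalance, lytic/blastic/mixed lesion mix of
roughly 50/31/19 percent, and about 3.3 lesions per image.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..volume import world_zyx_to_xyz, write_nrrd, write_dicom_series
from .notes import generate_note
from .phantom import (
    LesionSpec,
    PhantomSpec,
    PlantedLesion,
    TextureParams,
    generate_phantom,
)

__all__ = ["CohortSpec", "CohortPaths", "generate_cohort"]

# lesion-class frequencies pooled over the study cohort (lytic/blastic/mixed)
CLASS_PROBS = {"lytic": 0.505, "blastic": 0.306, "mixed": 0.189}

CANCER_TYPES = {"lung": 0.26, "breast": 0.19, "prostate": 0.14,
                "myeloma": 0.07, "renal": 0.05, "other": 0.29}


@dataclass
class CohortSpec:
    n_patients: int = 60
    mean_extra_lesions: float = 2.3          # lesions ~ 1 + Poisson(mean_extra)
    pain_fraction: float = 0.84
    train_fraction: float = 0.7
    seed: int = 0
    grid_shape: tuple = (48, 56, 56)
    spacing_mm: tuple = (2.5, 2.0, 2.0)
    background_hu: float = 300.0
    noise_sd_hu: float = 35.0
    lesion_diameter_mm: tuple = (8.0, 16.0)  # uniform range
    texture_params: TextureParams = field(default_factory=TextureParams)
    write_dicom: bool = False

    def __post_init__(self):
        if not 0 < self.pain_fraction <= 1:
            raise ValueError("pain_fraction must be in (0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class CohortPaths:
    root: Path
    volumes_dir: Path
    notes_dir: Path
    points_csv: Path
    truth_csv: Path
    patients_csv: Path


def _assign_pain_by_image(lesion_counts: list[int], pain_fraction: float,
                          rng: np.random.Generator) -> list[bool]:
    """Choose painful images so the lesion-level fraction hits the target.

    Images are visited in random order and marked painful until the
    painful-lesion count reaches the target, so the achieved fraction is
    within one image's lesion count of the target.
    """
    total = sum(lesion_counts)
    target = pain_fraction * total
    order = rng.permutation(len(lesion_counts))
    painful = [False] * len(lesion_counts)
    acc = 0
    for i in order:
        if acc >= target:
            break
        painful[i] = True
        acc += lesion_counts[i]
    return painful


def generate_cohort(spec: CohortSpec, out_dir) -> CohortPaths:
    """Generate and write a full synthetic cohort.

    Writes ``volumes/<patient>.nrrd``, ``notes/<patient>.txt``,
    ``points.csv`` (columns ``patient_id,lesion_id,x_mm,y_mm,z_mm``),
    ``truth.csv`` (``patient_id,lesion_id,painful,lesion_class``) and
    ``patients.csv`` (demographic covariates + note-level truth).
    Deterministic given ``spec.seed``.
    """
    root = Path(out_dir)
    volumes_dir = root / "volumes"
    notes_dir = root / "notes"
    for d in (volumes_dir, notes_dir):
        d.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    lesion_counts = (1 + rng.poisson(spec.mean_extra_lesions, size=n)).tolist()
    painful_img = _assign_pain_by_image(lesion_counts, spec.pain_fraction, rng)

    extent = np.array(spec.grid_shape) * np.array(spec.spacing_mm)
    classes = list(CLASS_PROBS)
    class_p = np.array([CLASS_PROBS[c] for c in classes])
    # lesion centers live inside the bone cylinder (lesions arise in bone);
    # geometry mirrors PhantomSpec's default bone_radius_fraction
    bone_r = PhantomSpec().bone_radius_fraction * min(extent[1], extent[2]) / 2
    cy, cx = extent[1] / 2, extent[2] / 2

    point_rows, truth_rows, patient_rows = [], [], []
    for i in range(n):
        pid = f"P{i:03d}"
        n_les = lesion_counts[i]
        painful = painful_img[i]
        lesions = []
        for _ in range(n_les):
            d = rng.uniform(*spec.lesion_diameter_mm)
            r_max = max(bone_r - d / 2 - 2.0, 3.0)
            rr = r_max * np.sqrt(rng.random())
            theta = rng.uniform(0, 2 * np.pi)
            center = np.array([
                rng.uniform(25.0, extent[0] - 25.0),
                cy + rr * np.sin(theta),
                cx + rr * np.cos(theta),
            ])
            lesions.append(LesionSpec(
                center_mm=tuple(center),
                diameter_mm=float(d),
                lesion_class=classes[rng.choice(len(classes), p=class_p)],
                painful=painful,
                texture_params=spec.texture_params,
            ))
        phantom = PhantomSpec(
            grid_shape=spec.grid_shape,
            spacing_mm=spec.spacing_mm,
            background_hu=spec.background_hu,
            noise_sd_hu=spec.noise_sd_hu,
            lesion_specs=lesions,
            seed=int(rng.integers(2 ** 31)),
        )
        vol, planted = generate_phantom(phantom, patient_id=pid)
        write_nrrd(vol, volumes_dir / f"{pid}.nrrd")
        if spec.write_dicom:
            write_dicom_series(vol, volumes_dir / pid)

        severity = "none"
        if painful:
            severity = ("mild", "moderate", "severe")[rng.integers(3)]
        note = generate_note(painful, severity,
                             distractors=int(rng.integers(0, 4)),
                             seed=int(rng.integers(2 ** 31)))
        (notes_dir / f"{pid}.txt").write_text(note, encoding="utf-8")

        for pl in planted:
            x, y, z = world_zyx_to_xyz(pl.center.position_mm)
            point_rows.append({"patient_id": pid, "lesion_id": pl.center.lesion_id,
                               "x_mm": x, "y_mm": y, "z_mm": z})
            truth_rows.append({"patient_id": pid, "lesion_id": pl.center.lesion_id,
                               "painful": int(pl.spec.painful),
                               "lesion_class": pl.spec.lesion_class})
        patient_rows.append({
            "patient_id": pid,
            "age": float(np.clip(rng.normal(66.0, 14.0), 25, 95)),
            "sex": "male" if rng.random() < 0.54 else "female",
            "cancer_type": list(CANCER_TYPES)[rng.choice(
                len(CANCER_TYPES), p=np.array(list(CANCER_TYPES.values())))],
            "painful": int(painful),
            "n_lesions": n_les,
        })

    paths = CohortPaths(
        root=root,
        volumes_dir=volumes_dir,
        notes_dir=notes_dir,
        points_csv=root / "points.csv",
        truth_csv=root / "truth.csv",
        patients_csv=root / "patients.csv",
    )
    pd.DataFrame(point_rows).to_csv(paths.points_csv, index=False,
                                    quoting=csv.QUOTE_MINIMAL)
    pd.DataFrame(truth_rows).to_csv(paths.truth_csv, index=False)
    pd.DataFrame(patient_rows).to_csv(paths.patients_csv, index=False)
    return paths
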