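"""107-feature radiomics extraction from spherical ROIs.

Seven families are computed per ROI: 18 first-order, 14 shape, 24 GLCM,
16 GLRLM, 16 GLSZM, 14 GLDM and 5 NGTDM features — 107 in total.  For an
ensemble of nested ROIs the per-ROI vectors are concatenated with an
``SP<diameter>`` prefix, giving 321 (EN3) or 642 (EN6) named features
per lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..roi import ROIMask, EnsembleSpec, make_sphere_mask
from ..volume import CTVolume
from .discretize import DiscretizedROI, discretize
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "FeatureVector",
    "discretize",
    "DiscretizedROI",
    "extract_all",
    "ensemble_features",
    "feature_table",
    "N_FEATURES_PER_ROI",
    "firstorder_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

N_FEATURES_PER_ROI = 107


@dataclass
class FeatureVector:
    """Ordered named feature values with provenance."""

    names: list
    values: np.ndarray
    patient_id: str = ""
    lesion_id: str = ""
    roi_label: str = ""
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")

    def __len__(self) -> int:
        return len(self.names)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def extract_all(
    volume: CTVolume,
    roi: ROIMask,
    bin_width_hu: float = 25.0,
    shape_on: str = "geometric",
) -> FeatureVector:
    """Extract the full 107-feature vector from one ROI.

    Intensity and texture features are computed on the (possibly
    thresholded) ROI mask using raw HU; shape features are computed by
    default on the geometric pre-threshold sphere (``shape_on =
    "geometric"``), so that "shape" describes the ROI geometry rather
    than tissue composition; pass ``shape_on="thresholded"`` to use the
    thresholded mask instead.
    """
    if not roi.mask.any():
        raise ValueError("empty ROI mask")
    flags: list = []
    d = discretize(volume.values, roi.mask, bin_width_hu)

    if shape_on == "geometric" and roi.thresholded and np.isfinite(roi.diameter_mm):
        shape_mask = make_sphere_mask(volume, roi.center, roi.diameter_mm).mask
    elif shape_on in ("geometric", "thresholded"):
        shape_mask = roi.mask
    else:
        raise ValueError("shape_on must be 'geometric' or 'thresholded'")

    families = [
        ("firstorder", firstorder_features(volume.values, roi.mask,
                                           roi.spacing_mm, d, flags)),
        ("shape", shape_features(shape_mask, roi.spacing_mm, flags)),
        ("glcm", glcm_features(d)),
        ("glrlm", glrlm_features(d)),
        ("glszm", glszm_features(d)),
        ("gldm", gldm_features(d)),
        ("ngtdm", ngtdm_features(d)),
    ]
    names, values = [], []
    for fam, feats in families:
        for k, v in feats.items():
            names.append(f"{fam}_{k}")
            values.append(v)
    if len(names) != N_FEATURES_PER_ROI:
        raise AssertionError(f"expected {N_FEATURES_PER_ROI} features, got {len(names)}")
    if not np.all(np.isfinite(values)):
        bad = [n for n, v in zip(names, values) if not np.isfinite(v)]
        raise AssertionError(f"non-finite features: {bad}")
    return FeatureVector(
        names=names,
        values=np.array(values),
        patient_id=roi.center.patient_id,
        lesion_id=roi.center.lesion_id,
        roi_label=f"SP{roi.diameter_mm:g}",
        flags=flags,
    )


def ensemble_features(per_roi: list[FeatureVector], spec: EnsembleSpec) -> FeatureVector:
    """Concatenate per-ROI vectors into one ensemble vector (321/642)."""
    if len(per_roi) != len(spec.diameters_mm):
        raise ValueError(
            f"{spec.name} expects {len(spec.diameters_mm)} ROI vectors, got {len(per_roi)}"
        )
    names, values, flags = [], [], []
    for fv, diam in zip(per_roi, spec.diameters_mm):
        prefix = f"SP{diam:g}"
        names.extend(f"{prefix}_{n}" for n in fv.names)
        values.append(fv.values)
        flags.extend(fv.flags)
    first = per_roi[0]
    return FeatureVector(
        names=names,
        values=np.concatenate(values),
        patient_id=first.patient_id,
        lesion_id=first.lesion_id,
        roi_label=spec.name,
        flags=flags,
    )


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """One row per lesion: patient_id, lesion_id, then feature columns."""
    rows = []
    for fv in vectors:
        row = {"patient_id": fv.patient_id, "lesion_id": fv.lesion_id}
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
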