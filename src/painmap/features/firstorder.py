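"""First-order (intensity histogram) features, computed on raw HU."""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedROI

EPS = np.spacing(1.0)

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]


def firstorder_features(
    values: np.ndarray,
    mask: np.ndarray,
    spacing_mm,
    discretized: DiscretizedROI,
    flags: list | None = None,
) -> dict:
    """The 18 first-order features of the masked raw-HU values.

    ``Entropy`` and ``Uniformity`` are the only two computed on the
    discretized histogram; everything else uses raw HU.  For a constant
    ROI, Skewness and Kurtosis are defined as 0 and flagged.
    """
    x = np.asarray(values, dtype=float)[np.asarray(mask, bool)]
    if x.size == 0:
        raise ValueError("mask is empty")
    vv = float(np.prod(np.asarray(spacing_mm, float)))
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if robust.size:
        rmad = float(np.abs(robust - robust.mean()).mean())
    else:
        # tiny ROIs can leave the 10-90 percentile band empty
        rmad = 0.0
        if flags is not None:
            flags.append("empty 10-90 percentile band: RobustMAD set to 0")
    hist = discretized.histogram()

    if m2 > 0:
        skew = float(((x - mean) ** 3).mean() / m2 ** 1.5)
        kurt = float(((x - mean) ** 4).mean() / m2 ** 2)
    else:
        skew = kurt = 0.0
        if flags is not None:
            flags.append("constant ROI: Skewness/Kurtosis set to 0")

    return {
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": float(vv * (x ** 2).sum()),
        "Entropy": float(-np.sum(hist * np.log2(hist + EPS))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": float((hist ** 2).sum()),
    }
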