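"""Texture features from gray-level matrices.

Each family function returns an ordered ``dict`` name -> float.  Features
defined per direction (GLCM, GLRLM) are computed on each direction's
matrix and averaged.  Degenerate ROIs (a single gray level, or a single
voxel) produce defined sentinel values so the feature matrix stays
rectangular; the caller can detect them via the ``flags`` mechanism in
:mod:`painmap.features`.
"""

from __future__ import annotations

import numpy as np

from .matrices import (
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)

EPS = np.spacing(1.0)

GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
]

GLRLM_NAMES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]

GLSZM_NAMES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
]

GLDM_NAMES = [
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]

NGTDM_NAMES = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]


# ---------------------------------------------------------------------------
# GLCM


def _glcm_single(p: np.ndarray) -> dict:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (px * i).sum()
    mu_y = (py * i).sum()
    sig_x = np.sqrt((px * (i - mu_x) ** 2).sum())
    sig_y = np.sqrt((py * (i - mu_y) ** 2).sum())

    # diagonal / cross-diagonal marginals
    k_diff = np.arange(ng)                 # |i-j| in 0..ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1)       # i+j in 2..2ng
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())

    hx = -np.sum(px * np.log2(px + EPS))
    hy = -np.sum(py * np.log2(py + EPS))
    hxy = -np.sum(p * np.log2(p + EPS))
    pxpy = np.outer(px, py)
    hxy1 = -np.sum(p * np.log2(pxpy + EPS))
    hxy2 = -np.sum(pxpy * np.log2(pxpy + EPS))

    out = {}
    out["Autocorrelation"] = float((p * ii * jj).sum())
    ct = (p * (ii + jj - mu_x - mu_y) ** 2).sum()
    out["ClusterProminence"] = float((p * (ii + jj - mu_x - mu_y) ** 4).sum())
    out["ClusterShade"] = float((p * (ii + jj - mu_x - mu_y) ** 3).sum())
    out["ClusterTendency"] = float(ct)
    out["Contrast"] = float((p * (ii - jj) ** 2).sum())
    if sig_x * sig_y > 0:
        out["Correlation"] = float(((p * ii * jj).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        out["Correlation"] = 1.0
    da = (p_diff * k_diff).sum()
    out["DifferenceAverage"] = float(da)
    out["DifferenceEntropy"] = float(-np.sum(p_diff * np.log2(p_diff + EPS)))
    out["DifferenceVariance"] = float((p_diff * (k_diff - da) ** 2).sum())
    absd = np.abs(ii - jj)
    out["Id"] = float((p / (1.0 + absd)).sum())
    out["Idm"] = float((p / (1.0 + absd ** 2)).sum())
    out["Idmn"] = float((p / (1.0 + absd ** 2 / ng ** 2)).sum())
    out["Idn"] = float((p / (1.0 + absd / ng)).sum())
    div = max(hx, hy)
    out["Imc1"] = float((hxy - hxy1) / div) if div > 0 else 0.0
    out["Imc2"] = float(np.sqrt(1 - np.exp(-2.0 * (hxy2 - hxy)))) if hxy2 > hxy else 0.0
    off = absd > 0
    out["InverseVariance"] = float((p[off] / absd[off] ** 2).sum()) if off.any() else 0.0
    out["JointAverage"] = float(mu_x)
    out["JointEnergy"] = float((p ** 2).sum())
    out["JointEntropy"] = float(hxy)
    out["MaximumProbability"] = float(p.max())
    out["MCC"] = _glcm_mcc(p, px, py)
    out["SumAverage"] = float((p_sum * k_sum).sum())
    out["SumEntropy"] = float(-np.sum(p_sum * np.log2(p_sum + EPS)))
    out["SumSquares"] = float((p * (ii - mu_x) ** 2).sum())
    return out


def _glcm_mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    present = px > 0
    if present.sum() <= 1:
        return 1.0
    pr = p[np.ix_(present, present)]
    pxr = px[present]
    pyr = py[present]
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    q = (pr / pxr[:, None]) @ (pr / pyr[:, None]).T
    ev = np.linalg.eigvals(q)
    ev = np.sort(np.real(ev))[::-1]
    if len(ev) < 2:
        return 1.0
    return float(np.sqrt(max(ev[1], 0.0)))


def glcm_features(d) -> dict:
    """24 GLCM features, averaged over the 13 symmetric offsets."""
    mats = glcm_matrices(d)
    if not mats:
        # single-voxel ROI: no co-occurring pair along any offset
        vals = {n: 0.0 for n in GLCM_NAMES}
        vals.update({"Correlation": 1.0, "MCC": 1.0, "JointEnergy": 1.0,
                     "MaximumProbability": 1.0, "Id": 1.0, "Idm": 1.0,
                     "Idmn": 1.0, "Idn": 1.0, "Imc2": 0.0})
        return {n: vals[n] for n in GLCM_NAMES}
    per = [_glcm_single(p) for p in mats.values()]
    return {n: float(np.mean([f[n] for f in per])) for n in GLCM_NAMES}


# ---------------------------------------------------------------------------
# run / zone / dependence families share one algebra


def _rlm_style(P: np.ndarray, n_vox: int) -> dict:
    """The 16 emphasis/nonuniformity statistics of a (level x size) matrix."""
    ns = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pg = P.sum(axis=1)       # per gray level
    ps = P.sum(axis=0)       # per size/run length
    p = P / ns
    mu_i = (p * ii).sum()
    mu_j = (p * jj).sum()
    return {
        "GrayLevelNonUniformity": float((pg ** 2).sum() / ns),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum() / ns ** 2),
        "GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((P * ii ** 2).sum() / ns),
        "LargeEmphasis": float((P * jj ** 2).sum() / ns),
        "LargeHighGrayLevelEmphasis": float((P * ii ** 2 * jj ** 2).sum() / ns),
        "LargeLowGrayLevelEmphasis": float((P * jj ** 2 / ii ** 2).sum() / ns),
        "LowGrayLevelEmphasis": float((P / ii ** 2).sum() / ns),
        "Entropy": float(-np.sum(p * np.log2(p + EPS))),
        "SizeNonUniformity": float((ps ** 2).sum() / ns),
        "SizeNonUniformityNormalized": float((ps ** 2).sum() / ns ** 2),
        "Percentage": float(ns / n_vox),
        "SizeVariance": float((p * (jj - mu_j) ** 2).sum()),
        "SmallEmphasis": float((P / jj ** 2).sum() / ns),
        "SmallHighGrayLevelEmphasis": float((P * ii ** 2 / jj ** 2).sum() / ns),
        "SmallLowGrayLevelEmphasis": float((P / (ii ** 2 * jj ** 2)).sum() / ns),
    }


def glrlm_features(d) -> dict:
    """16 run-length features averaged over the 13 directions."""
    mats, n_vox = glrlm_matrices(d)
    rename = {
        "GrayLevelNonUniformity": "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance": "GrayLevelVariance",
        "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
        "LargeEmphasis": "LongRunEmphasis",
        "LargeHighGrayLevelEmphasis": "LongRunHighGrayLevelEmphasis",
        "LargeLowGrayLevelEmphasis": "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
        "Entropy": "RunEntropy",
        "SizeNonUniformity": "RunLengthNonUniformity",
        "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
        "Percentage": "RunPercentage",
        "SizeVariance": "RunVariance",
        "SmallEmphasis": "ShortRunEmphasis",
        "SmallHighGrayLevelEmphasis": "ShortRunHighGrayLevelEmphasis",
        "SmallLowGrayLevelEmphasis": "ShortRunLowGrayLevelEmphasis",
    }
    per = [{rename[k]: v for k, v in _rlm_style(P, n_vox).items()}
           for P in mats.values()]
    return {n: float(np.mean([f[n] for f in per])) for n in GLRLM_NAMES}


def glszm_features(d) -> dict:
    """16 size-zone features (26-connected zones, single matrix)."""
    P, n_vox = glszm_matrix(d)
    raw = _rlm_style(P, n_vox)
    rename = {
        "GrayLevelNonUniformity": "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance": "GrayLevelVariance",
        "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
        "LargeEmphasis": "LargeAreaEmphasis",
        "LargeHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
        "LargeLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
        "Entropy": "ZoneEntropy",
        "SizeNonUniformity": "SizeZoneNonUniformity",
        "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
        "Percentage": "ZonePercentage",
        "SizeVariance": "ZoneVariance",
        "SmallEmphasis": "SmallAreaEmphasis",
        "SmallHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
        "SmallLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
    }
    out = {rename[k]: v for k, v in raw.items()}
    return {n: out[n] for n in GLSZM_NAMES}


def gldm_features(d, alpha: float = 0.0) -> dict:
    """14 dependence features (distance 1, dependence tolerance ``alpha``)."""
    P, n_vox = gldm_matrix(d, alpha=alpha)
    raw = _rlm_style(P, n_vox)
    out = {
        "DependenceEntropy": raw["Entropy"],
        "DependenceNonUniformity": raw["SizeNonUniformity"],
        "DependenceNonUniformityNormalized": raw["SizeNonUniformityNormalized"],
        "DependenceVariance": raw["SizeVariance"],
        "GrayLevelNonUniformity": raw["GrayLevelNonUniformity"],
        "GrayLevelVariance": raw["GrayLevelVariance"],
        "HighGrayLevelEmphasis": raw["HighGrayLevelEmphasis"],
        "LargeDependenceEmphasis": raw["LargeEmphasis"],
        "LargeDependenceHighGrayLevelEmphasis": raw["LargeHighGrayLevelEmphasis"],
        "LargeDependenceLowGrayLevelEmphasis": raw["LargeLowGrayLevelEmphasis"],
        "LowGrayLevelEmphasis": raw["LowGrayLevelEmphasis"],
        "SmallDependenceEmphasis": raw["SmallEmphasis"],
        "SmallDependenceHighGrayLevelEmphasis": raw["SmallHighGrayLevelEmphasis"],
        "SmallDependenceLowGrayLevelEmphasis": raw["SmallLowGrayLevelEmphasis"],
    }
    return {n: out[n] for n in GLDM_NAMES}


def ngtdm_features(d) -> dict:
    """5 neighborhood gray-tone difference features."""
    n, s, n_vox = ngtdm_table(d)
    present = n > 0
    p = n / n_vox
    i = np.arange(1, len(n) + 1, dtype=float)
    ngp = int(present.sum())

    ip = i[present]
    pp = p[present]
    sp = s[present]

    denom_coarse = float((pp * sp).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        contrast = float(
            (pp[:, None] * pp[None, :] * di ** 2).sum() / (ngp * (ngp - 1))
            * (sp.sum() / n_vox)
        )
        ipi = ip * pp
        busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = denom_coarse / busy_den if busy_den > 0 else 0.0
        pd = pp[:, None] + pp[None, :]
        complexity = float(
            (np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / pd).sum()
            / n_vox
        )
        s_sum = float(sp.sum())
        strength = float((pd * di ** 2).sum()) / s_sum if s_sum > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
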