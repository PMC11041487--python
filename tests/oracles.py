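"""Independent brute-force oracles for texture matrices and features.

Everything here is written as plain nested loops over voxels, pairs and
neighborhoods — no vectorization, no code shared with the package's
builders — so agreement with the package is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np

# the 13 canonical direction vectors (z, y, x): first nonzero component
# positive; written out literally on purpose
DIRECTIONS = [
    (0, 0, 1),
    (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]

NEIGHBORS26 = [
    (a, b, c)
    for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def _in(shape, v):
    return all(0 <= v[k] < shape[k] for k in range(3))


def naive_glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Symmetric normalized co-occurrence matrix per direction (dict)."""
    shape = levels.shape
    out = {}
    for d in DIRECTIONS:
        P = np.zeros((n_levels, n_levels))
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if not mask[z, y, x]:
                        continue
                    w = (z + d[0], y + d[1], x + d[2])
                    if _in(shape, w) and mask[w]:
                        i = levels[z, y, x] - 1
                        j = levels[w] - 1
                        P[i, j] += 1
                        P[j, i] += 1
        if P.sum() > 0:
            out[d] = P / P.sum()
    return out


def naive_glcm_features(p: np.ndarray) -> dict:
    """All 24 co-occurrence features of one normalized matrix, by loops."""
    ng = p.shape[0]
    eps = np.spacing(1.0)
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum(px[i] * ((i + 1) - mux) ** 2 for i in range(ng)))
    sigy = math.sqrt(sum(py[j] * ((j + 1) - muy) ** 2 for j in range(ng)))
    pdiff = [0.0] * ng
    psum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            pdiff[abs(i - j)] += p[i][j]
            psum[i + j] += p[i][j]
    f = {}
    f["Autocorrelation"] = sum(p[i][j] * (i + 1) * (j + 1)
                               for i in range(ng) for j in range(ng))
    for power, name in ((2, "ClusterTendency"), (3, "ClusterShade"),
                        (4, "ClusterProminence")):
        f[name] = sum(p[i][j] * ((i + 1) + (j + 1) - mux - muy) ** power
                      for i in range(ng) for j in range(ng))
    f["Contrast"] = sum(p[i][j] * (i - j) ** 2 for i in range(ng) for j in range(ng))
    if sigx * sigy > 0:
        f["Correlation"] = (f["Autocorrelation"] - mux * muy) / (sigx * sigy)
    else:
        f["Correlation"] = 1.0
    da = sum(k * pdiff[k] for k in range(ng))
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(pdiff[k] * math.log2(pdiff[k] + eps)
                                  for k in range(ng))
    f["DifferenceVariance"] = sum(pdiff[k] * (k - da) ** 2 for k in range(ng))
    f["Id"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["Idm"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["Idmn"] = sum(p[i][j] / (1 + (i - j) ** 2 / ng ** 2)
                    for i in range(ng) for j in range(ng))
    f["Idn"] = sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    hx = -sum(px[i] * math.log2(px[i] + eps) for i in range(ng))
    hy = -sum(py[j] * math.log2(py[j] + eps) for j in range(ng))
    hxy = -sum(p[i][j] * math.log2(p[i][j] + eps) for i in range(ng) for j in range(ng))
    hxy1 = -sum(p[i][j] * math.log2(px[i] * py[j] + eps)
                for i in range(ng) for j in range(ng))
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j] + eps)
                for i in range(ng) for j in range(ng))
    f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f["Imc2"] = math.sqrt(1 - math.exp(-2 * (hxy2 - hxy))) if hxy2 > hxy else 0.0
    f["InverseVariance"] = sum(p[i][j] / (i - j) ** 2
                               for i in range(ng) for j in range(ng) if i != j)
    f["JointAverage"] = mux
    f["JointEnergy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    f["JointEntropy"] = hxy
    f["MaximumProbability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    present = [i for i in range(ng) if px[i] > 0]
    if len(present) <= 1:
        f["MCC"] = 1.0
    else:
        q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(p[i][k] * p[j][k] / (px[i] * py[k])
                              for k in range(ng) if py[k] > 0)
        ev = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
        f["MCC"] = math.sqrt(max(ev[1], 0.0)) if len(ev) > 1 else 1.0
    f["SumAverage"] = sum((k + 2) * psum[k] for k in range(2 * ng - 1))
    f["SumEntropy"] = -sum(psum[k] * math.log2(psum[k] + eps)
                           for k in range(2 * ng - 1))
    f["SumSquares"] = sum(p[i][j] * ((i + 1) - mux) ** 2
                          for i in range(ng) for j in range(ng))
    return f


def naive_glrlm(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Run-length count matrix per direction, by walking each line."""
    shape = levels.shape
    out = {}
    for d in DIRECTIONS:
        runs = []  # (gray level, length)
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    prev = (z - d[0], y - d[1], x - d[2])
                    if _in(shape, prev):
                        continue  # not the start of a line
                    # walk the full line, collecting runs of in-mask voxels
                    v = (z, y, x)
                    cur_level, cur_len = None, 0
                    while _in(shape, v):
                        if mask[v]:
                            g = levels[v]
                            if g == cur_level:
                                cur_len += 1
                            else:
                                if cur_level is not None:
                                    runs.append((cur_level, cur_len))
                                cur_level, cur_len = g, 1
                        else:
                            if cur_level is not None:
                                runs.append((cur_level, cur_len))
                            cur_level, cur_len = None, 0
                        v = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                    if cur_level is not None:
                        runs.append((cur_level, cur_len))
        if runs:
            max_len = max(r[1] for r in runs)
            P = np.zeros((n_levels, max_len))
            for g, ln in runs:
                P[g - 1, ln - 1] += 1
            out[d] = P
    return out


def naive_glszm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix via flood fill with 26-connectivity."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                g = levels[z, y, x]
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    v = stack.pop()
                    size += 1
                    for d in NEIGHBORS26:
                        w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                        if _in(shape, w) and mask[w] and not seen[w] and levels[w] == g:
                            seen[w] = True
                            stack.append(w)
                zones.append((g, size))
    max_size = max(s for _, s in zones)
    P = np.zeros((n_levels, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def naive_gldm(levels: np.ndarray, mask: np.ndarray, n_levels: int,
               alpha: float = 0.0) -> np.ndarray:
    """Dependence count matrix: 1 + dependent 26-neighbors per voxel."""
    shape = levels.shape
    entries = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                dep = 1
                for d in NEIGHBORS26:
                    w = (z + d[0], y + d[1], x + d[2])
                    if _in(shape, w) and mask[w] and abs(int(levels[w]) - int(levels[z, y, x])) <= alpha:
                        dep += 1
                entries.append((levels[z, y, x], dep))
    max_dep = max(dp for _, dp in entries)
    P = np.zeros((n_levels, max_dep))
    for g, dp in entries:
        P[g - 1, dp - 1] += 1
    return P


def naive_ngtdm(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level count n_i and summed neighborhood difference s_i."""
    shape = levels.shape
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                g = levels[z, y, x]
                vals = []
                for d in NEIGHBORS26:
                    w = (z + d[0], y + d[1], x + d[2])
                    if _in(shape, w) and mask[w]:
                        vals.append(levels[w])
                n[g - 1] += 1
                if vals:
                    s[g - 1] += abs(g - sum(vals) / len(vals))
    return n, s


def naive_firstorder(values: np.ndarray, mask: np.ndarray, spacing,
                     hist: np.ndarray) -> dict:
    """The 18 first-order features by straightforward one-pass formulas."""
    x = np.sort(np.asarray(values, float)[np.asarray(mask, bool)])
    n = len(x)
    eps = np.spacing(1.0)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    p10, p25, p50, p75, p90 = (np.percentile(x, q) for q in (10, 25, 50, 75, 90))
    robust = [v for v in x if p10 <= v <= p90]
    if robust:
        rmean = sum(robust) / len(robust)
        rmad = sum(abs(v - rmean) for v in robust) / len(robust)
    else:
        rmad = 0.0
    energy = sum(v ** 2 for v in x)
    out = {
        "Energy": energy,
        "TotalEnergy": float(np.prod(spacing)) * energy,
        "Entropy": -sum(p * math.log2(p + eps) for p in hist),
        "Minimum": x[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": (sum((v - mean) ** 3 for v in x) / n) / var ** 1.5 if var > 0 else 0.0,
        "Kurtosis": (sum((v - mean) ** 4 for v in x) / n) / var ** 2 if var > 0 else 0.0,
        "Variance": var,
        "Uniformity": sum(p ** 2 for p in hist),
    }
    return {k: float(v) for k, v in out.items()}
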