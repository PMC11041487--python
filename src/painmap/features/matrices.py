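"""Texture-matrix construction: GLCM, GLRLM, GLSZM, GLDM, NGTDM.

All builders operate on a :class:`~painmap.features.discretize.DiscretizedROI`
restricted to its mask; voxels outside the mask never contribute.  The
conventions are:

* **GLCM** — 13 unique 3D offsets at Chebyshev distance 1; each matrix is
  made symmetric and normalized; both voxels of a pair must be in-mask.
* **GLRLM** — run lengths of equal gray level along the same 13
  directions; one matrix per direction.
* **GLSZM** — connected zones of equal gray level with 26-connectivity;
  a single matrix.
* **GLDM** — for each voxel, the dependence is one plus the number of
  26-neighbors (in-mask) whose gray level differs by at most ``alpha``
  (default 0); a single matrix indexed (gray level, dependence).
* **NGTDM** — per gray level, the count of voxels and the summed absolute
  difference between each voxel's level and the mean level of its
  in-mask 26-neighbors; voxels with no in-mask neighbor count toward
  ``n_i`` with a zero difference contribution.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "UNIQUE_OFFSETS",
    "ALL_OFFSETS",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
]

# 13 unique direction vectors (z, y, x): the half of the 26-neighborhood
# whose first nonzero component is positive.
UNIQUE_OFFSETS: list[tuple[int, int, int]] = [
    d
    for d in (
        (dz, dy, dx)
        for dz in (0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
    )
    if d != (0, 0, 0)
    and next(v for v in d if v != 0) > 0
]

ALL_OFFSETS: list[tuple[int, int, int]] = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _bbox_levels(d) -> np.ndarray:
    """Levels array cropped to the mask bounding box (0 outside mask)."""
    idx = np.where(d.mask)
    lo = [i.min() for i in idx]
    hi = [i.max() + 1 for i in idx]
    lev = np.where(d.mask, d.levels, 0)
    return lev[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.int64)


def _shifted_view(a: np.ndarray, d: tuple[int, int, int]) -> tuple[tuple, tuple]:
    """Slices (src, dst) so that ``a[dst]`` and ``a[src]`` pair voxel v with v+d."""
    src, dst = [], []
    for k, dk in enumerate(d):
        n = a.shape[k]
        if dk == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif dk > 0:
            src.append(slice(dk, n))
            dst.append(slice(0, n - dk))
        else:
            src.append(slice(0, n + dk))
            dst.append(slice(-dk, n))
    return tuple(src), tuple(dst)


def glcm_matrices(d) -> dict[tuple, np.ndarray]:
    """Normalized symmetric co-occurrence matrix per offset.

    Returns a dict keyed by the (z, y, x) offset; offsets along which
    the ROI yields no voxel pair are dropped (so a single-voxel mask
    yields an empty dict).
    """
    lev = _bbox_levels(d)
    ng = d.n_levels
    out = {}
    for off in UNIQUE_OFFSETS:
        src, dst = _shifted_view(lev, off)
        a = lev[dst]
        b = lev[src]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        ai = a[valid] - 1
        bi = b[valid] - 1
        counts = np.bincount(ai * ng + bi, minlength=ng * ng).reshape(ng, ng)
        p = (counts + counts.T).astype(float)
        out[off] = p / p.sum()
    return out


def glrlm_matrices(d) -> tuple[dict[tuple, np.ndarray], int]:
    """Run-length matrix (gray level x run length) per direction.

    Returns the 13 count matrices keyed by direction, and the number of
    masked voxels.
    """
    lev = _bbox_levels(d)
    ng = d.n_levels
    np_vox = int((lev > 0).sum())
    max_run = max(lev.shape)
    mats = {}
    for off in UNIQUE_OFFSETS:
        # run length ending at each voxel, by dynamic programming along
        # the first axis p with off[p] == +1 (guaranteed by construction)
        p_ax = next(k for k, v in enumerate(off) if v != 0)
        lev_t = np.moveaxis(lev, p_ax, 0)
        rest = tuple(off[k] for k in range(3) if k != p_ax)
        run = np.zeros_like(lev_t)
        run[0] = (lev_t[0] > 0).astype(np.int64)
        for t in range(1, lev_t.shape[0]):
            prev = np.zeros_like(lev_t[t])
            src, dst = _shifted_view(lev_t[t - 1], rest)
            # prev[dst] aligns voxel (t, j, i) with (t-1, j-dq, i-dr)
            prev_lev = np.zeros_like(lev_t[t])
            prev_lev[src] = lev_t[t - 1][dst]
            prev[src] = run[t - 1][dst]
            cont = (lev_t[t] > 0) & (lev_t[t] == prev_lev)
            run[t] = np.where(cont, prev + 1, (lev_t[t] > 0).astype(np.int64))
        # a run ends where the successor along +off differs / leaves the grid
        succ = np.zeros_like(lev_t)
        for t in range(lev_t.shape[0] - 1):
            src, dst = _shifted_view(lev_t[t + 1], rest)
            tmp = np.zeros_like(lev_t[t])
            tmp[dst] = lev_t[t + 1][src]
            succ[t] = tmp
        ends = (lev_t > 0) & (lev_t != succ)
        gl = lev_t[ends] - 1
        rl = run[ends] - 1
        counts = np.bincount(gl * max_run + rl, minlength=ng * max_run)
        mats[off] = counts.reshape(ng, max_run).astype(float)
    return mats, np_vox


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(d) -> tuple[np.ndarray, int]:
    """Size-zone matrix (gray level x zone size), 26-connected zones."""
    lev = _bbox_levels(d)
    ng = d.n_levels
    np_vox = int((lev > 0).sum())
    sizes_per_level: dict[int, np.ndarray] = {}
    max_size = 1
    for g in range(1, ng + 1):
        binary = lev == g
        if not binary.any():
            sizes_per_level[g] = np.array([], dtype=int)
            continue
        lab, n = ndimage.label(binary, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level[g] = sizes
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((ng, max_size), dtype=float)
    for g, sizes in sizes_per_level.items():
        for s in sizes:
            P[g - 1, s - 1] += 1
    return P, np_vox


def gldm_matrix(d, alpha: float = 0.0) -> tuple[np.ndarray, int]:
    """Dependence matrix (gray level x dependence), Chebyshev distance 1.

    Dependence of a voxel is one (itself) plus the number of in-mask
    neighbors whose gray level differs by at most ``alpha``.
    """
    lev = _bbox_levels(d)
    ng = d.n_levels
    inmask = lev > 0
    np_vox = int(inmask.sum())
    dep = np.zeros(lev.shape, dtype=np.int64)
    for off in ALL_OFFSETS:
        src, dst = _shifted_view(lev, off)
        nb = np.zeros_like(lev)
        nb[dst] = lev[src]
        dep[dst] += (inmask[dst] & (nb[dst] > 0)
                     & (np.abs(nb[dst] - lev[dst]) <= alpha)).astype(np.int64)
    dep = dep + 1
    nd = int(dep[inmask].max())
    counts = np.bincount((lev[inmask] - 1) * nd + (dep[inmask] - 1), minlength=ng * nd)
    return counts.reshape(ng, nd).astype(float), np_vox


def ngtdm_table(d) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level counts ``n_i`` and summed neighborhood differences ``s_i``."""
    lev = _bbox_levels(d)
    ng = d.n_levels
    inmask = lev > 0
    np_vox = int(inmask.sum())
    nb_sum = np.zeros(lev.shape, dtype=np.float64)
    nb_cnt = np.zeros(lev.shape, dtype=np.int64)
    for off in ALL_OFFSETS:
        src, dst = _shifted_view(lev, off)
        nb = np.zeros_like(lev)
        nb[dst] = lev[src]
        has = nb > 0
        nb_sum[dst] += np.where(has[dst], nb[dst], 0)
        nb_cnt[dst] += has[dst].astype(np.int64)
    diff = np.zeros(lev.shape, dtype=np.float64)
    ok = inmask & (nb_cnt > 0)
    diff[ok] = np.abs(lev[ok] - nb_sum[ok] / nb_cnt[ok])
    n = np.zeros(ng, dtype=float)
    s = np.zeros(ng, dtype=float)
    for g in range(1, ng + 1):
        sel = inmask & (lev == g)
        n[g - 1] = sel.sum()
        s[g - 1] = diff[sel].sum()
    return n, s, np_vox
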