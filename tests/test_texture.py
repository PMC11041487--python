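"""Texture families against independent brute-force oracles."""

import numpy as np
import pytest

from oracles import (
    naive_glcm,
    naive_glcm_features,
    naive_gldm,
    naive_glrlm,
    naive_glszm,
    naive_ngtdm,
)
from painmap.features import discretize
from painmap.features.matrices import (
    UNIQUE_OFFSETS,
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)
from painmap.features.texture import (
    GLCM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)


def _random_roi(rng, max_side=6):
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    vals = rng.normal(0, 120, shape)
    mask = rng.random(shape) > 0.25
    if mask.sum() < 2:
        mask[0, 0, 0] = mask[-1, -1, -1] = True
    return discretize(vals, mask, 40.0)


def _trim(P):
    """Drop trailing all-zero columns so shapes are comparable."""
    nz = np.where(P.any(axis=0))[0]
    return P[:, : nz.max() + 1] if len(nz) else P[:, :1]


def _constant_roi(shape=(3, 3, 3)):
    return discretize(np.full(shape, 10.0), np.ones(shape, bool), 25.0)


def _single_voxel_roi():
    mask = np.zeros((3, 3, 3), bool)
    mask[1, 1, 1] = True
    return discretize(np.full((3, 3, 3), 5.0), mask, 25.0)


class TestGLCM:
    def test_constant_roi(self):
        f = glcm_features(_constant_roi())
        assert f["JointEnergy"] == 1.0
        assert f["Contrast"] == 0.0
        assert f["MaximumProbability"] == 1.0
        assert f["Correlation"] == 1.0

    def test_checkerboard_features_match_hand_enumeration(self):
        vals = np.array([[[0.0, 30.0, 0.0], [30.0, 0.0, 30.0], [0.0, 30.0, 0.0]]])
        vals = np.moveaxis(vals, 0, 0)  # 1 x 3 x 3 slab of levels {1, 2}
        d = discretize(vals, np.ones_like(vals, bool), 25.0)
        mats = glcm_matrices(d)
        oracle = naive_glcm(d.levels, d.mask, d.n_levels)
        assert set(mats) == set(oracle)
        per_dir = [naive_glcm_features(oracle[k]) for k in mats]
        expect = {n: float(np.mean([f[n] for f in per_dir])) for n in GLCM_NAMES}
        got = glcm_features(d)
        for n in GLCM_NAMES:
            assert got[n] == pytest.approx(expect[n], rel=1e-9, abs=1e-12), n

    def test_label_permutation_leaves_contrast(self):
        vals = np.array([[[0.0, 30.0], [30.0, 0.0]]])
        d1 = discretize(vals, np.ones_like(vals, bool), 25.0)
        d2 = discretize(30.0 - vals, np.ones_like(vals, bool), 25.0)
        assert glcm_features(d1)["Contrast"] == pytest.approx(
            glcm_features(d2)["Contrast"], rel=1e-12)

    def test_single_voxel_defined(self):
        f = glcm_features(_single_voxel_roi())
        assert all(np.isfinite(v) for v in f.values())

    def test_matrices_match_oracle_random(self, rng):
        for _ in range(30):
            d = _random_roi(rng)
            mats = glcm_matrices(d)
            oracle = naive_glcm(d.levels, d.mask, d.n_levels)
            assert set(mats) == set(oracle)
            for k in mats:
                np.testing.assert_allclose(mats[k], oracle[k], rtol=1e-9, atol=1e-12)


class TestGLRLM:
    def test_constant_slab_runs(self):
        vals = np.full((1, 4, 4), 9.0)
        d = discretize(vals, np.ones_like(vals, bool), 25.0)
        mats, n_vox = glrlm_matrices(d)
        assert n_vox == 16
        along = mats[(0, 0, 1)]
        assert _trim(along).shape == (1, 4)
        assert along[0, 3] == 4.0  # four rows, each one run of length 4

    def test_single_voxel(self):
        mats, _ = glrlm_matrices(_single_voxel_roi())
        for P in mats.values():
            assert P.sum() == 1.0 and _trim(P).shape == (1, 1)

    def test_matches_oracle_random(self, rng):
        for _ in range(30):
            d = _random_roi(rng)
            mats, _ = glrlm_matrices(d)
            oracle = naive_glrlm(d.levels, d.mask, d.n_levels)
            assert set(mats) == set(oracle)
            for k in mats:
                np.testing.assert_allclose(_trim(mats[k]), _trim(oracle[k]),
                                           rtol=1e-9, atol=1e-12)

    def test_rotation_invariance_of_averaged_features(self, rng):
        vals = rng.normal(0, 100, (5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        d1 = discretize(vals, mask, 30.0)
        d2 = discretize(np.rot90(vals, k=1, axes=(1, 2)).copy(), mask, 30.0)
        f1, f2 = glrlm_features(d1), glrlm_features(d2)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), k


class TestGLSZM:
    def test_constant_slab_single_zone(self):
        vals = np.full((1, 4, 4), 3.0)
        d = discretize(vals, np.ones_like(vals, bool), 25.0)
        P, n_vox = glszm_matrix(d)
        assert P.sum() == 1.0 and P[0, 15] == 1.0 and n_vox == 16

    def test_matches_oracle_random(self, rng):
        for _ in range(30):
            d = _random_roi(rng)
            P, _ = glszm_matrix(d)
            np.testing.assert_allclose(
                _trim(P), _trim(naive_glszm(d.levels, d.mask, d.n_levels)),
                rtol=1e-9, atol=1e-12)


class TestGLDM:
    def test_single_voxel(self):
        P, n_vox = gldm_matrix(_single_voxel_roi())
        assert P.sum() == 1.0 and n_vox == 1 and P[0, 0] == 1.0

    def test_matches_oracle_random(self, rng):
        for _ in range(30):
            d = _random_roi(rng)
            P, _ = gldm_matrix(d)
            np.testing.assert_allclose(
                _trim(P), _trim(naive_gldm(d.levels, d.mask, d.n_levels)),
                rtol=1e-9, atol=1e-12)


class TestNGTDM:
    def test_single_voxel_coarseness_capped(self):
        f = ngtdm_features(_single_voxel_roi())
        assert f["Coarseness"] == 1e6
        assert f["Contrast"] == 0.0

    def test_matches_oracle_random(self, rng):
        for _ in range(30):
            d = _random_roi(rng)
            n, s, _ = ngtdm_table(d)
            n_o, s_o = naive_ngtdm(d.levels, d.mask, d.n_levels)
            np.testing.assert_allclose(n, n_o, rtol=1e-9)
            np.testing.assert_allclose(s, s_o, rtol=1e-9, atol=1e-12)


def test_offset_conventions_agree():
    from oracles import DIRECTIONS
    assert set(UNIQUE_OFFSETS) == set(DIRECTIONS)
    assert len(UNIQUE_OFFSETS) == 13


def test_glcm_rotation_invariance(rng):
    vals = rng.normal(0, 100, (5, 5, 5))
    mask = np.ones((5, 5, 5), bool)
    f1 = glcm_features(discretize(vals, mask, 30.0))
    f2 = glcm_features(discretize(np.rot90(vals, axes=(1, 2)).copy(), mask, 30.0))
    for k in f1:
        assert f1[k] == pytest.approx(f2[k], rel=1e-9), k


def test_degenerate_families_finite():
    for d in (_constant_roi(), _single_voxel_roi()):
        for fn in (glcm_features, glrlm_features, glszm_features,
                   gldm_features, ngtdm_features):
            assert all(np.isfinite(v) for v in fn(d).values())
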