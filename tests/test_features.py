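"""Discretization, first-order and shape features, and vector assembly."""

import numpy as np
import pytest

from oracles import naive_firstorder
from painmap.features import (
    N_FEATURES_PER_ROI,
    discretize,
    ensemble_features,
    extract_all,
)
from painmap.features.firstorder import FIRSTORDER_NAMES, firstorder_features
from painmap.features.shape import SHAPE_NAMES, shape_features
from painmap.roi import EN3, EN6, build_nested, make_sphere_mask
from painmap.volume import CTVolume, CenterPoint


class TestDiscretize:
    def test_constant_roi(self):
        vals = np.full((3, 3, 3), 42.0)
        d = discretize(vals, np.ones((3, 3, 3), bool), 25.0)
        assert d.n_levels == 1 and set(d.levels[d.mask]) == {1}

    def test_bin_edges(self):
        vals = np.array([[[0.0, 10.0, 24.9, 25.0, 49.0]]])
        d = discretize(vals, np.ones_like(vals, bool), 25.0)
        assert list(d.levels[0, 0]) == [1, 1, 1, 2, 2]

    def test_mapping_recovers_levels(self, rng):
        vals = rng.normal(0, 300, (6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.4
        d = discretize(vals, mask, 25.0)
        for v, lev in zip(vals[mask], d.levels[mask]):
            lo, hi = d.level_edges(int(lev))
            assert lo <= v < hi or (v == hi and lev == d.n_levels)

    def test_bad_width(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool), 0.0)

    def test_shift_invariance(self, rng):
        vals = rng.normal(0, 200, (5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        d1 = discretize(vals, mask, 25.0)
        d2 = discretize(vals + 137.0, mask, 25.0)
        np.testing.assert_array_equal(d1.levels, d2.levels)


class TestFirstOrder:
    def _feats(self, vals, mask, spacing=(1.0, 1.0, 1.0), bw=25.0):
        d = discretize(vals, mask, bw)
        return firstorder_features(vals, mask, spacing, d)

    def test_constant_roi(self):
        vals = np.full((4, 4, 4), 77.0)
        f = self._feats(vals, np.ones((4, 4, 4), bool))
        assert f["Mean"] == f["Median"] == f["Minimum"] == f["Maximum"] == 77.0
        assert f["Variance"] == f["Range"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == f["Kurtosis"] == 0.0

    def test_two_level_entropy_one_bit(self):
        vals = np.zeros((2, 2, 2))
        vals[:, :, 1] = 30.0  # two bins of width 25, equal counts
        f = self._feats(vals, np.ones((2, 2, 2), bool))
        assert f["Entropy"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_naive_oracle(self, rng):
        for _ in range(20):
            vals = rng.normal(50, 250, (5, 5, 5))
            mask = rng.random((5, 5, 5)) > 0.3
            if mask.sum() < 3:
                continue
            d = discretize(vals, mask, 25.0)
            f = firstorder_features(vals, mask, (2.0, 1.0, 1.5), d)
            g = naive_firstorder(vals, mask, (2.0, 1.0, 1.5), d.histogram())
            assert set(f) == set(g) == set(FIRSTORDER_NAMES)
            for k in f:
                assert f[k] == pytest.approx(g[k], rel=1e-9, abs=1e-12), k


class TestShape:
    def test_sphere_near_ideal(self):
        vol = CTVolume(np.zeros((56, 56, 56)), (1.0,) * 3)
        c = CenterPoint("P", "L", (27.5, 27.5, 27.5))
        m = make_sphere_mask(vol, c, 50.0)
        f = shape_features(m.mask, m.spacing_mm)
        assert 0.97 <= f["Sphericity"] <= 1.0
        assert 0.97 <= f["Elongation"] <= 1.0
        assert 0.97 <= f["Flatness"] <= 1.0
        diag = np.sqrt(3.0)
        assert abs(f["Maximum3DDiameter"] - 50.0) <= diag
        for k in ("Maximum2DDiameterSlice", "Maximum2DDiameterColumn",
                  "Maximum2DDiameterRow"):
            assert abs(f[k] - 50.0) <= diag
        analytic = 4 / 3 * np.pi * 25 ** 3
        assert abs(f["MeshVolume"] - analytic) / analytic < 0.05

    def test_voxel_volume_identity(self, rng):
        mask = rng.random((8, 8, 8)) > 0.5
        spacing = (2.0, 0.7, 1.1)
        f = shape_features(mask, spacing)
        assert f["VoxelVolume"] == pytest.approx(mask.sum() * np.prod(spacing))

    def test_single_voxel_defined(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        flags = []
        f = shape_features(mask, (1.0, 1.0, 1.0), flags)
        assert f["VoxelVolume"] == 1.0
        assert all(np.isfinite(v) for v in f.values())
        assert flags  # degeneracy is reported

    def test_anisotropic_ball_elongated(self):
        # a voxel ball stretched by spacing must report Elongation < 1
        vol = CTVolume(np.zeros((30, 30, 30)), (1.0,) * 3)
        c = CenterPoint("P", "L", (14.5, 14.5, 14.5))
        m = make_sphere_mask(vol, c, 20.0)
        f = shape_features(m.mask, (3.0, 1.0, 1.0))
        assert f["Elongation"] < 0.9 or f["Flatness"] < 0.9


@pytest.fixture(scope="module")
def lesion():
    rng = np.random.default_rng(3)
    vol = CTVolume(rng.normal(200, 100, (56, 56, 56)), (1.5,) * 3)
    c = CenterPoint("P9", "L1", (40.0, 40.0, 40.0))
    masks = build_nested(vol, c, EN6, sigma_mm=1.0)
    return vol, masks


class TestAssembly:
    def test_107_per_roi_no_duplicates(self, lesion):
        vol, masks = lesion
        fv = extract_all(vol, masks[0])
        assert len(fv) == N_FEATURES_PER_ROI == 107
        assert len(set(fv.names)) == 107

    def test_family_counts(self, lesion):
        vol, masks = lesion
        fv = extract_all(vol, masks[0])
        counts = {}
        for n in fv.names:
            fam = n.split("_")[0]
            counts[fam] = counts.get(fam, 0) + 1
        assert counts == {"firstorder": 18, "shape": 14, "glcm": 24,
                          "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}

    def test_ensemble_lengths(self, lesion):
        vol, masks = lesion
        vecs = [extract_all(vol, m) for m in masks]
        en6 = ensemble_features(vecs, EN6)
        en3 = ensemble_features(vecs[:3], EN3)
        assert len(en6) == 642 and len(en3) == 321
        assert en6.names[0].startswith("SP7_")

    def test_deterministic(self, lesion):
        vol, masks = lesion
        a = extract_all(vol, masks[2])
        b = extract_all(vol, masks[2])
        np.testing.assert_array_equal(a.values, b.values)

    def test_translation_invariance_of_texture(self):
        rng = np.random.default_rng(8)
        base = rng.normal(150, 120, (40, 40, 40))
        vol1 = CTVolume(base, (1.0,) * 3)
        vol2 = CTVolume(np.roll(base, 1, axis=2), (1.0,) * 3)
        c1 = CenterPoint("P", "L", (20.0, 20.0, 20.0))
        c2 = CenterPoint("P", "L", (20.0, 20.0, 21.0))
        f1 = extract_all(vol1, make_sphere_mask(vol1, c1, 14.0)).as_dict()
        f2 = extract_all(vol2, make_sphere_mask(vol2, c2, 14.0)).as_dict()
        for k in f1:
            if k.startswith("shape_"):
                continue
            assert f1[k] == pytest.approx(f2[k], rel=1e-9, abs=1e-12), k

    def test_length_mismatch_rejected(self, lesion):
        vol, masks = lesion
        vecs = [extract_all(vol, m) for m in masks[:2]]
        with pytest.raises(ValueError):
            ensemble_features(vecs, EN3)
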