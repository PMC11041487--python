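"""Split, scaling, SMOTE, LASSO, classifiers, CV and the metric panel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.linear_model import Lasso

from painmap import ml


def _dataset(rng, n_images=80, lesions_per=2, n_feat=10, pain_frac=0.8,
             informative=False, exact_fraction=False):
    n_pain = int(round(pain_frac * n_images))
    rows = []
    for i in range(n_images):
        if exact_fraction:
            label = int(i < n_pain)
        else:
            label = int(rng.random() < pain_frac)
        for j in range(lesions_per):
            rows.append((f"P{i:03d}", f"P{i:03d}", f"L{j}", label))
    ids = pd.DataFrame(rows, columns=["patient", "image", "lesion", "y"])
    X = rng.normal(0, 1, (len(ids), n_feat))
    if informative:
        X[:, 0] += 3.0 * ids["y"].to_numpy()
    return ml.LabeledDataset(
        X=X, y=ids["y"].to_numpy(), feature_names=[f"f{k}" for k in range(n_feat)],
        patient_ids=ids["patient"].to_numpy(), image_ids=ids["image"].to_numpy(),
        lesion_ids=ids["lesion"].to_numpy())


class TestSplit:
    def test_ratio_preserved_at_study_scale(self, rng):
        ds = _dataset(rng, n_images=176, lesions_per=3, pain_frac=0.84,
                      exact_fraction=True)
        cfg = ml.PipelineConfig(seed=0)
        out = ml.stratified_split(ds, cfg)
        te = out.test()
        assert 0.80 <= te.y.mean() <= 0.87
        assert abs(len(out.train().y) / len(out.y) - 0.7) < 0.08

    def test_full_train_fraction_rejected(self):
        with pytest.raises(ValueError):
            ml.PipelineConfig(train_fraction=1.0)

    def test_deterministic(self, rng):
        ds = _dataset(rng)
        cfg = ml.PipelineConfig(seed=5)
        a = ml.stratified_split(ds, cfg).split
        b = ml.stratified_split(ds, cfg).split
        np.testing.assert_array_equal(a, b)

    def test_patient_grouping_respected(self, rng):
        ds = _dataset(rng, n_images=40, lesions_per=3)
        out = ml.stratified_split(ds, ml.PipelineConfig(seed=1))
        sides = pd.DataFrame({"p": out.patient_ids, "s": out.split})
        assert (sides.groupby("p")["s"].nunique() == 1).all()

    def test_tiny_class_rejected(self, rng):
        ds = _dataset(rng, n_images=10, lesions_per=1, pain_frac=1.0)
        ds.y[0] = 0  # a single painless image: cannot stratify
        with pytest.raises(ValueError, match="fewer than 2"):
            ml.stratified_split(ds, ml.PipelineConfig())

    def test_conflicting_image_labels_rejected(self, rng):
        X = rng.normal(0, 1, (4, 3))
        with pytest.raises(ValueError, match="conflicting"):
            ml.LabeledDataset(X, [0, 1, 0, 1], ["a", "b", "c"],
                              ["P0", "P0", "P1", "P1"], ["I0", "I0", "I1", "I1"],
                              ["L0", "L1", "L0", "L1"])


class TestBalanceCheck:
    def test_identical_groups(self):
        cov = pd.DataFrame({"age": [50.0, 60, 70, 80], "sex": list("mmff"),
                            "cancer_type": list("llbb")})
        out = ml.balance_check(cov, cov.copy())
        chi = out[out["kind"] == "chi2"]
        assert (chi["statistic"] == 0).all() and (chi["p_value"] == 1).all()

    def test_equal_2x2_statistic_zero(self):
        tr = pd.DataFrame({"age": np.r_[np.zeros(10), np.ones(10)],
                           "sex": ["m"] * 10 + ["f"] * 10,
                           "cancer_type": ["l"] * 10 + ["b"] * 10})
        out = ml.balance_check(tr, tr.copy())
        assert out.loc[out["covariate"] == "sex", "statistic"].iloc[0] == 0.0

    def test_degenerate_category_flagged(self):
        tr = pd.DataFrame({"age": [1.0, 2.0], "sex": ["m", "m"],
                           "cancer_type": ["l", "l"]})
        out = ml.balance_check(tr, tr.copy())
        assert (out.loc[out["kind"] == "chi2", "flag"] == "degenerate table").all()

    def test_type_one_error_calibrated(self):
        # equal-mean ages: the Welch t test should reject ~5% of the time
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 400
        for _ in range(reps):
            tr = pd.DataFrame({"age": rng.normal(66, 14, 120)})
            te = pd.DataFrame({"age": rng.normal(66, 14, 55)})
            out = ml.balance_check(tr, te, numeric=["age"], categorical=[])
            rejections += out["p_value"].iloc[0] < 0.05
        assert rejections / reps <= 0.08


class TestScaler:
    def test_train_columns_standardized(self, rng):
        X = rng.normal(5, 3, (50, 4))
        Z = ml.ZScoreScaler().fit_transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-12)

    def test_constant_column_flagged_zero(self, rng):
        X = rng.normal(0, 1, (20, 3))
        X[:, 1] = 7.0
        sc = ml.ZScoreScaler().fit(X)
        assert list(sc.constant_features) == [1]
        assert np.all(sc.transform(X)[:, 1] == 0.0)

    def test_test_set_scaled_with_train_stats(self, rng):
        Xtr = rng.normal(0, 1, (30, 2))
        Xte = rng.normal(10, 5, (30, 2))
        sc = ml.ZScoreScaler().fit(Xtr)
        Zte = sc.transform(Xte)
        # if test had been scaled with its own stats its mean would be ~0
        assert np.abs(Zte.mean(axis=0)).min() > 1.0


class TestSmote:
    def test_balanced_unchanged(self, rng):
        X = rng.normal(0, 1, (20, 3))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        X2, y2 = ml.smote(X, y, seed=0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_study_class_sizes_balanced(self, rng):
        X = rng.normal(0, 1, (357 + 66, 5))
        y = np.r_[np.ones(357, int), np.zeros(66, int)]
        X2, y2 = ml.smote(X, y, k=5, seed=0)
        assert (y2 == 0).sum() == 357 and (y2 == 1).sum() == 357

    def test_synthetic_points_on_minority_segments(self, rng):
        X = rng.normal(0, 1, (40, 3))
        y = np.r_[np.ones(30, int), np.zeros(10, int)]
        X2, y2 = ml.smote(X, y, k=3, seed=1)
        minority = X[y == 0]
        synth = X2[len(X):]
        for s in synth:
            on_segment = False
            for a in range(len(minority)):
                for b in range(len(minority)):
                    if a == b:
                        continue
                    ab = minority[b] - minority[a]
                    asv = s - minority[a]
                    t = np.dot(asv, ab) / np.dot(ab, ab)
                    if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(asv - t * ab) < 1e-9:
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_majority_untouched_and_deterministic(self, rng):
        X = rng.normal(0, 1, (30, 2))
        y = np.r_[np.ones(24, int), np.zeros(6, int)]
        X2, y2 = ml.smote(X, y, seed=3)
        np.testing.assert_array_equal(X2[:30], X)
        X3, _ = ml.smote(X, y, seed=3)
        np.testing.assert_array_equal(X2, X3)

    def test_small_minority_reduces_k(self, rng):
        X = rng.normal(0, 1, (23, 2))
        y = np.r_[np.ones(20, int), np.zeros(3, int)]
        with pytest.warns(UserWarning, match="reducing k"):
            X2, y2 = ml.smote(X, y, k=5, seed=0)
        assert (y2 == 0).sum() == 20


class TestLasso:
    def test_orthonormal_design_soft_threshold(self, rng):
        # closed form: b_j = sign(b_ols) * max(|b_ols| - n*alpha, 0)
        n, p = 64, 8
        Q, _ = np.linalg.qr(rng.normal(0, 1, (n, p)))
        beta = np.array([3.0, -2.0, 1.5, 0.8, 0.3, 0.1, 0.0, 0.0])
        y = Q @ beta
        alpha = 0.01
        fit = Lasso(alpha=alpha, fit_intercept=False).fit(Q, y)
        b_ols = Q.T @ y
        expect = np.sign(b_ols) * np.maximum(np.abs(b_ols) - n * alpha, 0.0)
        np.testing.assert_allclose(fit.coef_, expect, atol=1e-6)

    def test_planted_feature_recovered(self, rng):
        n = 300
        X = rng.normal(0, 1, (n, 51))
        y = 10.0 * X[:, 0] + rng.normal(0, 1, n)
        sel = ml.lasso_select(X, y, ml.PipelineConfig(seed=0))
        assert 0 in sel

    def test_pure_noise_fallback_nonempty(self, rng):
        X = rng.normal(0, 1, (40, 5))
        y = rng.normal(0, 1, 40)
        sel = ml.lasso_select(X, y, ml.PipelineConfig(seed=0))
        assert len(sel) >= 1


class TestClassifiersAndMetrics:
    def test_separable_blobs_perfect_train_accuracy(self, rng):
        X = np.vstack([rng.normal(-4, 0.3, (30, 2)), rng.normal(4, 0.3, (30, 2))])
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        models = ml.train_classifiers(X, y, ml.PipelineConfig(seed=0))
        assert set(models) == set(ml.CLASSIFIER_NAMES)
        for name, m in models.items():
            assert (m.predict_labels(X) == y).mean() == 1.0, name

    def test_same_seed_identical_predictions(self, rng):
        X = rng.normal(0, 1, (60, 4))
        y = (X[:, 0] > 0).astype(int)
        cfg = ml.PipelineConfig(seed=7)
        s1 = ml.train_classifiers(X, y, cfg)["NNet"].scores(X)
        s2 = ml.train_classifiers(X, y, cfg)["NNet"].scores(X)
        np.testing.assert_array_equal(s1, s2)

    def test_paper_confusion_tallies(self):
        panel = ml.MetricPanel(tp=16, fn=11, tn=116, fp=20)
        assert round(panel.sensitivity, 2) == 0.59
        assert round(panel.specificity, 2) == 0.85
        assert panel.accuracy == pytest.approx(132 / 163)
        assert round(100 * panel.macro_precision, 1) == 67.9
        assert round(100 * panel.macro_f1, 1) == 69.5

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_panel_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        p = ml.MetricPanel(tp, fp, tn, fn)
        assert p.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
        if tp + fn:
            assert p.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert p.specificity == pytest.approx(tn / (tn + fp))
        if p.precision + p.sensitivity:
            assert p.f1 == pytest.approx(
                2 * p.precision * p.sensitivity / (p.precision + p.sensitivity))

    def test_auc_perfect_and_random(self, rng):
        y = np.r_[np.zeros(500, int), np.ones(500, int)]
        assert ml.trapezoid_auc(y, y.astype(float)) == 1.0
        assert abs(ml.trapezoid_auc(y, rng.random(1000)) - 0.5) < 0.05

    def test_auc_single_class_refused(self):
        with pytest.raises(ValueError):
            ml.trapezoid_auc(np.ones(5, int), np.random.rand(5))


class TestCrossValidationAndLeakage:
    def test_null_cv_auc_near_chance(self, rng):
        ds = _dataset(rng, n_images=60, lesions_per=2, pain_frac=0.5)
        cfg = ml.PipelineConfig(seed=0, cv_folds=5)
        cv = ml.cross_validate(ds, cfg)
        assert set(cv["classifier"]) == set(ml.CLASSIFIER_NAMES)
        assert cv["auc_mean"].between(0.35, 0.65).all()

    def test_informative_cv_beats_chance(self, rng):
        ds = _dataset(rng, n_images=60, lesions_per=2, pain_frac=0.5,
                      informative=True)
        cv = ml.cross_validate(ds, ml.PipelineConfig(seed=0))
        assert cv["auc_mean"].max() > 0.9

    def test_cv_deterministic(self, rng):
        ds = _dataset(rng, n_images=40, pain_frac=0.5, informative=True)
        cfg = ml.PipelineConfig(seed=2)
        a = ml.cross_validate(ds, cfg)
        b = ml.cross_validate(ds, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_no_leakage_from_test_rows(self, rng):
        # deleting the test split before fitting changes nothing fitted
        ds = _dataset(rng, n_images=80, lesions_per=2, pain_frac=0.7,
                      informative=True)
        cfg = ml.PipelineConfig(seed=3)
        ds = ml.stratified_split(ds, cfg)
        res_full = ml.run_experiment(ds, cfg)
        tr = ds.train()
        corrupted = ds.subset(np.ones(len(ds.y), bool))
        corrupted.X = ds.X.copy()
        corrupted.X[ds.split == "test"] += 1e3  # mangle test rows
        corrupted.split = ds.split
        res_mangled = ml.run_experiment(corrupted, cfg)
        assert res_full["selected_features"] == res_mangled["selected_features"]
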