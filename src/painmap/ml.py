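"""Imbalance-aware classification of painful vs painless lesions.

The modeling chain: stratified train/test split at the image level (with
patient-level grouping on by default), z-score scaling with train-only
statistics, SMOTE oversampling of the minority class (train only, never
the test set), LASSO feature selection with an internally cross-validated
penalty, four classifiers (random forest, Gaussian process, linear SVM,
neural network), 5-fold cross-validation with scaling/SMOTE/LASSO refit
inside each fold, and a metric panel (accuracy, precision, sensitivity,
specificity, F1, AUC) on the untouched test set.

Class convention: label 1 = pain, 0 = no pain.  Because the cohort is
heavily imbalanced toward painful lesions, the metric panel treats the
minority "no pain" class as the positive class (sensitivity = recall of
"no pain", specificity = recall of "pain") and additionally reports
macro-averaged precision and F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel
from sklearn.linear_model import LassoCV, lasso_path
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "LabeledDataset",
    "PipelineConfig",
    "MetricPanel",
    "ZScoreScaler",
    "stratified_split",
    "balance_check",
    "smote",
    "lasso_select",
    "train_classifiers",
    "cross_validate",
    "evaluate",
    "run_experiment",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("RF", "GPR", "L-SVM", "NNet")


@dataclass
class PipelineConfig:
    train_fraction: float = 0.7
    smote_k: int = 5
    cv_folds: int = 5
    lasso_cv_folds: int = 5
    seed: int = 0
    allow_patient_overlap: bool = False
    rf_n_estimators: int = 300
    mlp_hidden: tuple = (64,)
    mlp_max_iter: int = 2000
    svm_c: float = 1.0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class LabeledDataset:
    """Feature matrix with per-lesion labels, grouping ids and split."""

    X: np.ndarray                  # lesions x features
    y: np.ndarray                  # 1 = pain, 0 = no pain
    feature_names: list
    patient_ids: np.ndarray        # one per lesion
    image_ids: np.ndarray          # one per lesion (note-image pair id)
    lesion_ids: np.ndarray
    split: np.ndarray | None = None   # "train" / "test" per lesion

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        for arr_name in ("patient_ids", "image_ids", "lesion_ids"):
            setattr(self, arr_name, np.asarray(getattr(self, arr_name)))
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X and y disagree on the number of lesions")
        # one pain label per image: all lesions of an image share a label
        lab = pd.Series(self.y).groupby(pd.Series(self.image_ids)).nunique()
        if (lab > 1).any():
            bad = lab[lab > 1].index.tolist()
            raise ValueError(f"images with conflicting lesion labels: {bad}")

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            X=self.X[mask], y=self.y[mask], feature_names=self.feature_names,
            patient_ids=self.patient_ids[mask], image_ids=self.image_ids[mask],
            lesion_ids=self.lesion_ids[mask],
            split=None if self.split is None else self.split[mask],
        )

    def train(self) -> "LabeledDataset":
        if self.split is None:
            raise ValueError("split not assigned")
        return self.subset(self.split == "train")

    def test(self) -> "LabeledDataset":
        if self.split is None:
            raise ValueError("split not assigned")
        return self.subset(self.split == "test")


def stratified_split(ds: LabeledDataset, cfg: PipelineConfig) -> LabeledDataset:
    """Assign train/test at the image level, stratified by pain label.

    With ``allow_patient_overlap=False`` (default) all images of one
    patient fall on the same side of the split.  Raises if either class
    has fewer than 2 units or if the split would be empty.
    """
    rng = np.random.default_rng(cfg.seed)
    units = pd.DataFrame({
        "image": ds.image_ids,
        "patient": ds.patient_ids,
        "label": ds.y,
    })
    if cfg.allow_patient_overlap:
        units["unit"] = units["image"]
    else:
        units["unit"] = units["patient"]
    per_unit = units.groupby("unit").agg(
        label=("label", "first"), n=("label", "size"))
    for lab in (0, 1):
        if (per_unit["label"] == lab).sum() < 2:
            raise ValueError(f"class {lab} has fewer than 2 units; cannot stratify")
    test_units = set()
    for lab in (0, 1):
        u = per_unit.index[per_unit["label"] == lab].to_numpy()
        u = u[rng.permutation(len(u))]
        n_test = int(round((1 - cfg.train_fraction) * len(u)))
        n_test = min(max(n_test, 1), len(u) - 1)
        test_units.update(u[:n_test])
    split = np.where(np.isin(units["unit"], list(test_units)), "test", "train")
    out = ds.subset(np.ones(len(ds.y), bool))
    out.split = split
    for part in ("train", "test"):
        sel = split == part
        frac = ds.y[sel].mean()
        if abs(frac - ds.y.mean()) > 0.03:
            import warnings
            warnings.warn(
                f"{part} pain fraction {frac:.3f} deviates from global "
                f"{ds.y.mean():.3f} by more than 3 percentage points")
    return out


def balance_check(train_cov: pd.DataFrame, test_cov: pd.DataFrame,
                  numeric: list[str] = ("age",),
                  categorical: list[str] = ("sex", "cancer_type")) -> pd.DataFrame:
    """Covariate balance between splits: Welch t test / chi-square test.

    Returns a table ``covariate, kind, statistic, p_value, flag``; a
    degenerate contingency table (a covariate constant overall, or a
    level absent from one split) is flagged rather than failing.
    """
    rows = []
    for c in numeric:
        t, p = stats.ttest_ind(train_cov[c], test_cov[c], equal_var=False)
        rows.append({"covariate": c, "kind": "t", "statistic": float(t),
                     "p_value": float(p), "flag": ""})
    for c in categorical:
        group = np.r_[np.repeat("train", len(train_cov)),
                      np.repeat("test", len(test_cov))]
        vals = np.r_[train_cov[c].to_numpy(), test_cov[c].to_numpy()]
        tab = pd.crosstab(pd.Series(group, name="split"), pd.Series(vals, name=c))
        flag = ""
        if tab.shape[1] < 2 or (tab.sum(axis=0) == 0).any():
            rows.append({"covariate": c, "kind": "chi2", "statistic": float("nan"),
                         "p_value": float("nan"), "flag": "degenerate table"})
            continue
        chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        rows.append({"covariate": c, "kind": "chi2", "statistic": float(chi2),
                     "p_value": float(p), "flag": flag})
    return pd.DataFrame(rows)


class ZScoreScaler:
    """Per-feature (x - mean) / sd with train-only statistics.

    Zero-variance features are mapped to 0 and recorded in
    ``constant_features``.
    """

    def fit(self, X: np.ndarray) -> "ZScoreScaler":
        X = np.asarray(X, float)
        if X.shape[0] < 2:
            raise ValueError("need more than one row to fit a scaler")
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        self.constant_features = np.where(self.sd_ == 0)[0]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd_ == 0, 1.0, self.sd_)
        Z = (np.asarray(X, float) - self.mean_) / sd
        Z[:, self.constant_features] = 0.0
        return Z

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def smote(X: np.ndarray, y: np.ndarray, k: int = 5,
          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic Minority Oversampling: balance classes on the training set.

    Each synthetic sample is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0,1)``
    and ``x_nn`` one of the ``k`` nearest minority neighbors of ``x_i``.
    The majority class is untouched; a balanced input is returned
    unchanged.  If the minority class has fewer than ``k + 1`` samples,
    ``k`` is reduced with a warning.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    counts = np.bincount(y, minlength=2)
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = int(np.argmin(counts))
    n_needed = int(counts.max() - counts.min())
    Xm = X[y == minority]
    if len(Xm) < 2:
        raise ValueError("minority class needs at least 2 samples for SMOTE")
    if len(Xm) < k + 1:
        import warnings
        k_eff = len(Xm) - 1
        warnings.warn(f"minority class has {len(Xm)} samples; reducing k to {k_eff}")
    else:
        k_eff = k
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)          # first neighbor is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(len(Xm), size=n_needed)
    pick = rng.integers(1, k_eff + 1, size=n_needed)
    u = rng.random(n_needed)
    neigh = Xm[idx[base, pick]]
    synth = Xm[base] + u[:, None] * (neigh - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority)])
    return X_out, y_out


def lasso_select(X: np.ndarray, y: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Indices of features with nonzero LASSO coefficients.

    The L1 penalty is chosen by cross-validation on the given (training)
    data only.  If the chosen penalty zeroes every coefficient, the
    smallest penalty on the path with at least one nonzero coefficient
    is used instead.
    """
    cfg = cfg or PipelineConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    model = LassoCV(cv=cfg.lasso_cv_folds, random_state=cfg.seed, alphas=60,
                    max_iter=5000)
    with np.errstate(all="ignore"):
        model.fit(X, y)
    selected = np.where(model.coef_ != 0)[0]
    if len(selected) == 0:
        alphas, coefs, _ = lasso_path(X, y, alphas=np.geomspace(1e-4, 1.0, 60))
        nz = (coefs != 0).any(axis=0)
        if nz.any():
            selected = np.where(coefs[:, np.argmax(nz)] != 0)[0]
        if len(selected) == 0:
            selected = np.arange(X.shape[1])  # nothing informative at all
    return selected


class _Model:
    """Uniform adapter: fit / continuous score / hard label."""

    def __init__(self, name: str, est, kind: str):
        self.name = name
        self.est = est
        self.kind = kind                 # "proba" | "decision" | "regress"
        self.converged = True

    def fit(self, X, y):
        import warnings
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            self.est.fit(X, y)
            self.converged = not any("convergence" in str(x.message).lower() for x in w)
        return self

    def scores(self, X) -> np.ndarray:
        """Continuous score increasing with the probability of pain (=1)."""
        if self.kind == "proba":
            return self.est.predict_proba(X)[:, 1]
        if self.kind == "decision":
            return self.est.decision_function(X)
        return self.est.predict(X)       # GPR regression on {0,1} labels

    def predict_labels(self, X) -> np.ndarray:
        s = self.scores(X)
        thr = 0.0 if self.kind == "decision" else 0.5
        return (s > thr).astype(int)


def train_classifiers(X: np.ndarray, y: np.ndarray,
                      cfg: PipelineConfig | None = None) -> dict:
    """Fit the four classifier families on (scaled, selected) features."""
    cfg = cfg or PipelineConfig()
    models = {
        "RF": _Model("RF", RandomForestClassifier(
            n_estimators=cfg.rf_n_estimators, random_state=cfg.seed), "proba"),
        "GPR": _Model("GPR", GaussianProcessRegressor(
            kernel=RBF(length_scale=np.sqrt(X.shape[1])) + WhiteKernel(1e-1),
            random_state=cfg.seed, normalize_y=True), "regress"),
        "L-SVM": _Model("L-SVM", SVC(kernel="linear", C=cfg.svm_c,
                                     random_state=cfg.seed), "decision"),
        "NNet": _Model("NNet", MLPClassifier(
            hidden_layer_sizes=cfg.mlp_hidden, max_iter=cfg.mlp_max_iter,
            random_state=cfg.seed), "proba"),
    }
    for m in models.values():
        m.fit(X, y)
    return models


@dataclass(frozen=True)
class MetricPanel:
    """Confusion counts and the derived panel; positive class = "no pain"."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float = float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def f1(self) -> float:
        p, s = self.precision, self.sensitivity
        return 2 * p * s / (p + s) if (p + s) else 0.0

    @property
    def precision_negative(self) -> float:
        """Precision of the other ("pain") class."""
        d = self.tn + self.fn
        return self.tn / d if d else 0.0

    @property
    def macro_precision(self) -> float:
        return 0.5 * (self.precision + self.precision_negative)

    @property
    def macro_f1(self) -> float:
        p2, s2 = self.precision_negative, self.specificity
        f1_neg = 2 * p2 * s2 / (p2 + s2) if (p2 + s2) else 0.0
        return 0.5 * (self.f1 + f1_neg)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "f1": self.f1, "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1, "auc": self.auc,
        }


def trapezoid_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC by trapezoid over the empirical ROC (pain = positive for ranking)."""
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test set contains a single class")
    fpr, tpr, _ = roc_curve(y, scores)
    return float(np.trapezoid(tpr, fpr))


def evaluate(model: _Model, X_test: np.ndarray, y_test: np.ndarray) -> tuple[MetricPanel, np.ndarray]:
    """Metric panel + ROC points on a test set untouched by any fitting.

    Counts use the model's hard-label threshold with "no pain" (0) as
    the positive class; the AUC uses the continuous score.
    """
    y_test = np.asarray(y_test, int)
    pred = model.predict_labels(X_test)
    scores = model.scores(X_test)
    tp = int(((pred == 0) & (y_test == 0)).sum())
    fp = int(((pred == 0) & (y_test == 1)).sum())
    tn = int(((pred == 1) & (y_test == 1)).sum())
    fn = int(((pred == 1) & (y_test == 0)).sum())
    auc = trapezoid_auc(y_test, scores)
    fpr, tpr, _ = roc_curve(y_test, scores)
    return MetricPanel(tp, fp, tn, fn, auc=auc), np.column_stack([fpr, tpr])


def _fold_fit_eval(X_tr, y_tr, X_va, y_va, cfg: PipelineConfig) -> dict:
    scaler = ZScoreScaler().fit(X_tr)
    Z_tr = scaler.transform(X_tr)
    Z_va = scaler.transform(X_va)
    Xs, ys = smote(Z_tr, y_tr, k=cfg.smote_k, seed=cfg.seed)
    sel = lasso_select(Xs, ys, cfg)
    models = train_classifiers(Xs[:, sel], ys, cfg)
    out = {}
    for name, m in models.items():
        panel, _ = evaluate(m, Z_va[:, sel], y_va)
        out[name] = {"auc": panel.auc, "f1": panel.f1}
    return out


def cross_validate(ds_train: LabeledDataset, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Stratified k-fold CV with scaling/SMOTE/LASSO refit per fold.

    Returns mean and SD of AUC and F1 across folds for each classifier.
    Folds in which validation contains a single class are refused.
    """
    cfg = cfg or PipelineConfig()
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    per_fold = []
    for tr_idx, va_idx in skf.split(ds_train.X, ds_train.y):
        if len(np.unique(ds_train.y[va_idx])) < 2:
            raise ValueError("a CV fold contains a single class")
        per_fold.append(_fold_fit_eval(ds_train.X[tr_idx], ds_train.y[tr_idx],
                                       ds_train.X[va_idx], ds_train.y[va_idx], cfg))
    rows = []
    for name in CLASSIFIER_NAMES:
        aucs = [f[name]["auc"] for f in per_fold]
        f1s = [f[name]["f1"] for f in per_fold]
        rows.append({"classifier": name,
                     "auc_mean": float(np.mean(aucs)), "auc_sd": float(np.std(aucs)),
                     "f1_mean": float(np.mean(f1s)), "f1_sd": float(np.std(f1s))})
    return pd.DataFrame(rows)


def run_experiment(ds: LabeledDataset, cfg: PipelineConfig | None = None) -> dict:
    """Full chain on a split dataset; returns per-classifier test panels.

    The test split is only ever transformed with train statistics and
    scored; nothing is fitted on it.
    """
    cfg = cfg or PipelineConfig()
    if ds.split is None:
        ds = stratified_split(ds, cfg)
    tr, te = ds.train(), ds.test()
    scaler = ZScoreScaler().fit(tr.X)
    Z_tr, Z_te = scaler.transform(tr.X), scaler.transform(te.X)
    Xs, ys = smote(Z_tr, tr.y, k=cfg.smote_k, seed=cfg.seed)
    sel = lasso_select(Xs, ys, cfg)
    models = train_classifiers(Xs[:, sel], ys, cfg)
    results = {"selected_features": [ds.feature_names[i] for i in sel],
               "n_train": len(tr.y), "n_test": len(te.y), "models": {}}
    for name, m in models.items():
        panel, roc = evaluate(m, Z_te[:, sel], te.y)
        results["models"][name] = {"panel": panel, "roc": roc,
                                   "converged": m.converged}
    return results
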