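"""Imbalance-aware subtype classifiers over the four baseline features.

The core learner is a RUS-boosted decision-tree ensemble: adaptive boosting
in which each round first randomly under-samples the majority class to a
target ratio, fits a depth-limited tree on the re-balanced resample using
the current boosting weights, and then evaluates the weighted error on the
*full* training set to derive the learner's vote weight.  Four reference
classifiers (logistic regression, LDA, a k-NN random-subspace ensemble and
a small feed-forward network ensemble), fitted with minority-class
upweighting, are provided for model comparison via stratified 10-fold
cross-validated AUC-ROC and a Kruskal–Wallis test.

Holdout evaluation is always at the culture-well level (entire wells are
assigned to the test set) to prevent within-well leakage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FEATURE_NAMES",
    "RusBoostClassifier",
    "ClassifierReport",
    "CVResult",
    "split_holdout",
    "train_rusboost",
    "train_reference_models",
    "tune_hyperparameters",
    "crossval_auc",
    "compare_models",
    "roc_auc",
    "evaluate_holdout",
    "confidence_retention_curve",
    "pca_projection",
    "balanced_subsample",
]

FEATURE_NAMES = ["mfr_hz", "isicv", "sync_median", "sync_skewness"]

DEFAULT_SEARCH_SPACES = {
    "rusboost": {
        "max_depth": [1, 2, 3, 4, 5, 6, 7, 8],
        "n_rounds": [50, 100, 200, 300, 500],
        "learning_rate": [0.01, 0.03, 0.1, 0.3, 1.0],
    },
    "knn": {"n_neighbors": list(range(1, 26)), "max_features": [2, 3]},
    "fnn": {"hidden": [4, 8, 16, 32, 64], "n_members": [3, 5]},
    "log": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "lda": {"shrinkage": [None, "auto"]},
}


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return X, y


class RusBoostClassifier(BaseEstimator, ClassifierMixin):
    """Adaptive boosting of depth-limited trees with per-round random
    under-sampling of the majority class.

    Parameters
    ----------
    n_rounds : boosting rounds requested (rounds whose weighted error on
        the full training set is >= 0.5 are discarded and re-sampled, with
        bounded retries; boosting stops early if retries are exhausted).
    max_depth : depth limit of each tree.
    learning_rate : shrinkage applied to the log-odds learner weights.
    ratio : majority:minority size ratio of each resample (1.0 = balanced).
    random_state : seed for under-sampling and tree randomness.
    """

    def __init__(
        self,
        n_rounds: int = 200,
        max_depth: int = 3,
        learning_rate: float = 0.5,
        ratio: float = 1.0,
        random_state: int | None = None,
        max_retries: int = 10,
    ):
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.ratio = ratio
        self.random_state = random_state
        self.max_retries = max_retries

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("binary classification only")
        self.classes_ = classes
        minority = classes[np.argmin(counts)]
        majority = classes[1 - np.argmin(counts)]  # ties: argmax would collide
        min_idx = np.flatnonzero(y == minority)
        maj_idx = np.flatnonzero(y == majority)
        n_maj_sample = min(int(round(self.ratio * min_idx.size)), maj_idx.size)

        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        self.train_errors_: list[float] = []
        self.resample_class_counts_: list[tuple[int, int]] = []  # (minority, majority)
        eps_floor = 1e-10
        for _ in range(self.n_rounds):
            accepted = False
            for _retry in range(self.max_retries):
                take_maj = rng.choice(maj_idx, size=n_maj_sample, replace=False)
                res = np.concatenate([min_idx, take_maj])
                tree = DecisionTreeClassifier(
                    max_depth=self.max_depth,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
                tree.fit(X[res], y[res], sample_weight=w[res])
                pred = tree.predict(X)
                err = float(w[pred != y].sum())
                if err < 0.5:
                    accepted = True
                    break
            if not accepted:
                break
            err = max(err, eps_floor)
            alpha = self.learning_rate * math.log((1.0 - err) / err)
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            self.train_errors_.append(err)
            self.resample_class_counts_.append((min_idx.size, n_maj_sample))
            w = w * np.exp(alpha * (pred != y))
            w /= w.sum()
            if err <= eps_floor:  # perfect learner: nothing left to reweight
                break
        if not self.estimators_:
            raise RuntimeError("boosting failed: no learner achieved error < 0.5")
        self.alphas_ = np.asarray(self.alphas_)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        num = np.zeros(X.shape[0])
        for tree, alpha in zip(self.estimators_, self.alphas_):
            proba = tree.predict_proba(X)
            col = {c: i for i, c in enumerate(tree.classes_)}
            p1 = proba[:, col[self.classes_[1]]] if self.classes_[1] in col else 0.0
            num += alpha * p1
        p = num / self.alphas_.sum()
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    @property
    def feature_importances_(self) -> np.ndarray:
        """Mean impurity decrease aggregated over learners, weighted by the
        learner vote weights; normalized to sum to 1."""
        imp = np.zeros(self.estimators_[0].n_features_in_)
        for tree, alpha in zip(self.estimators_, self.alphas_):
            imp += alpha * tree.feature_importances_
        total = imp.sum()
        return imp / total if total > 0 else imp


@dataclass
class CVResult:
    """Per-fold AUC-ROC for each model, with fold assignments."""

    fold_auc: dict[str, np.ndarray]
    fold_assignments: np.ndarray
    k: int


@dataclass
class ClassifierReport:
    """Holdout evaluation artifacts of one classifier."""

    confusion: np.ndarray  # rows true [neg, pos], cols predicted [neg, pos]
    accuracy: float
    f1_negative: float
    f1_positive: float
    auc: float
    roc_points: np.ndarray  # (fpr, tpr) rows
    feature_importances: dict[str, float] | None
    confidence_curve: pd.DataFrame
    n_test: int

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "f1_negative": self.f1_negative,
            "f1_positive": self.f1_positive,
            "auc": self.auc,
            "roc_points": self.roc_points.tolist(),
            "feature_importances": self.feature_importances,
            "confidence_curve": self.confidence_curve.to_dict(orient="list"),
            "n_test": self.n_test,
        }


def split_holdout(
    features: pd.DataFrame, n_holdout_wells: int = 2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out whole wells: every unit of a held-out well goes to the test
    set, so no within-well information leaks into training."""
    wells = sorted(features["well_id"].unique())
    if len(wells) < n_holdout_wells + 1:
        raise ValueError(
            f"need at least {n_holdout_wells + 1} wells, got {len(wells)}"
        )
    rng = np.random.default_rng(seed)
    test_wells = set(rng.choice(wells, size=n_holdout_wells, replace=False))
    in_test = features["well_id"].isin(test_wells)
    return features[~in_test].reset_index(drop=True), features[in_test].reset_index(drop=True)


def train_rusboost(
    X, y, hyperparams: dict | None = None, seed: int = 0
) -> RusBoostClassifier:
    params = {"n_rounds": 200, "max_depth": 3, "learning_rate": 0.5, "ratio": 1.0}
    params.update(hyperparams or {})
    model = RusBoostClassifier(random_state=seed, **params)
    return model.fit(X, y)


class _MlpEnsemble(BaseEstimator, ClassifierMixin):
    """Small feed-forward network ensemble; class imbalance is handled by
    oversampling the minority class to parity in each member's training set."""

    def __init__(self, hidden: int = 16, n_members: int = 5, random_state: int = 0,
                 max_iter: int = 1200):
        self.hidden = hidden
        self.n_members = n_members
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        self.classes_ = classes
        minority = classes[np.argmin(counts)]
        min_idx = np.flatnonzero(y == minority)
        maj_idx = np.flatnonzero(y != minority)
        self.members_ = []
        for _ in range(self.n_members):
            extra = rng.choice(min_idx, size=maj_idx.size - min_idx.size, replace=True)
            res = np.concatenate([min_idx, maj_idx, extra])
            net = MLPClassifier(
                hidden_layer_sizes=(self.hidden,),
                max_iter=self.max_iter,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            with warnings.catch_warnings():
                # members that stop at the iteration cap still contribute
                # useful votes; the ensemble average absorbs the variance
                warnings.simplefilter("ignore", ConvergenceWarning)
                net.fit(X[res], y[res])
            self.members_.append(net)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        probs = np.zeros((X.shape[0], 2))
        for net in self.members_:
            p = net.predict_proba(X)
            cols = {c: i for i, c in enumerate(net.classes_)}
            probs[:, 0] += p[:, cols[self.classes_[0]]]
            probs[:, 1] += p[:, cols[self.classes_[1]]]
        return probs / self.n_members

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def make_model(family: str, hyperparams: dict | None = None, seed: int = 0):
    """Fresh unfitted classifier of a family; scaling is built into the
    scale-sensitive families."""
    hp = dict(hyperparams or {})
    if family == "rusboost":
        return RusBoostClassifier(random_state=seed, **hp)
    if family == "log":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(class_weight="balanced", max_iter=2000,
                                       C=hp.get("C", 1.0))),
        ])
    if family == "lda":
        # uniform priors upweight the minority class to parity
        solver = "lsqr" if hp.get("shrinkage") else "svd"
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LinearDiscriminantAnalysis(priors=[0.5, 0.5], solver=solver,
                                               shrinkage=hp.get("shrinkage"))),
        ])
    if family == "knn":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", BaggingClassifier(
                KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5)),
                n_estimators=10,
                max_features=hp.get("max_features", 2),
                bootstrap=False,
                random_state=seed,
            )),
        ])
    if family == "fnn":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", _MlpEnsemble(hidden=hp.get("hidden", 16),
                                 n_members=hp.get("n_members", 5),
                                 random_state=seed)),
        ])
    raise ValueError(f"unknown model family {family!r}")


def train_reference_models(
    X, y, seed: int = 0, hyperparams: dict[str, dict] | None = None
) -> dict:
    """Fit the four non-tree reference classifiers with minority upweighting."""
    X, y = _check_Xy(X, y)
    hp = hyperparams or {}
    models = {}
    for i, family in enumerate(("log", "lda", "knn", "fnn")):
        models[family] = make_model(family, hp.get(family), seed=seed + i).fit(X, y)
    return models


def tune_hyperparameters(
    family: str,
    X,
    y,
    budget: int = 30,
    seed: int = 0,
    candidates: list[dict] | None = None,
    inner_folds: int = 5,
) -> tuple[dict, dict]:
    """Budget-limited seeded random search over the family's documented
    space, maximizing inner stratified-CV AUC.

    Returns (best_hyperparameters, info); ``info["method"]`` is
    ``"random-search"`` (flagged: this is the sequential-model-free
    fallback), with the evaluated candidates and their scores.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    X, y = _check_Xy(X, y)
    rng = np.random.default_rng(seed)
    if candidates is None:
        space = DEFAULT_SEARCH_SPACES[family]
        keys = sorted(space)
        seen, candidates = set(), []
        for _ in range(budget * 4):
            cand = {k: space[k][rng.integers(0, len(space[k]))] for k in keys}
            sig = tuple(sorted(cand.items(), key=lambda kv: kv[0]))
            if sig not in seen:
                seen.add(sig)
                candidates.append(cand)
            if len(candidates) >= budget:
                break
    else:
        candidates = list(candidates)[: max(budget, len(candidates))]

    k = min(inner_folds, int(np.bincount(y).min()))
    if k < 2:
        raise ValueError("minority class too small for inner CV")
    results = []
    for i, cand in enumerate(candidates):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        aucs = []
        for tr, te in skf.split(X, y):
            model = make_model(family, cand, seed=seed + i)
            model.fit(X[tr], y[tr])
            scores = model.predict_proba(X[te])[:, 1]
            if len(np.unique(y[te])) < 2:
                continue
            aucs.append(roc_auc(scores, y[te])[1])
        results.append((float(np.mean(aucs)), cand))
    best_score, best = max(results, key=lambda r: r[0])
    info = {
        "method": "random-search",
        "n_evaluated": len(results),
        "best_inner_cv_auc": best_score,
        "trace": [{"params": c, "auc": s} for s, c in results],
    }
    return best, info


def crossval_auc(
    model_factories: dict, X, y, k: int = 10, seed: int = 0
) -> CVResult:
    """Stratified k-fold AUC-ROC per model.

    ``model_factories`` maps model name to a zero-argument callable
    returning a fresh unfitted classifier with fit/predict_proba.
    """
    X, y = _check_Xy(X, y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if int(np.bincount(y).min()) < k:
        raise ValueError("each class needs at least k members for stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    assignments = np.empty(len(y), dtype=int)
    for f, (_, te) in enumerate(folds):
        assignments[te] = f
    fold_auc = {}
    for name, factory in model_factories.items():
        aucs = []
        for tr, te in folds:
            model = factory() if callable(factory) else clone(factory)
            model.fit(X[tr], y[tr])
            scores = model.predict_proba(X[te])[:, 1]
            aucs.append(roc_auc(scores, y[te])[1])
        fold_auc[name] = np.asarray(aucs)
    return CVResult(fold_auc=fold_auc, fold_assignments=assignments, k=k)


def compare_models(cv: CVResult, alpha: float = 0.05) -> dict:
    """Kruskal–Wallis comparison of the models' per-fold AUC distributions.

    Decision is "no model outperforms" when p >= alpha.
    """
    groups = list(cv.fold_auc.values())
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 AUC values")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:  # scipy.kruskal rejects all-identical input
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*groups)
    return {
        "H": float(H),
        "p_value": float(p),
        "alpha": alpha,
        "decision": "no model outperforms" if p >= alpha else "models differ",
        "models": list(cv.fold_auc),
    }


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve over all score thresholds plus the AUC.

    The AUC equals the concordance probability that a random positive is
    scored above a random negative, with ties counted one-half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def confidence_retention_curve(
    scores, y_true, thresholds=None
) -> pd.DataFrame:
    """Accuracy vs fraction of units retained as the required prediction
    confidence ``max(score, 1−score)`` increases.

    Retention is monotonically non-increasing in the threshold; accuracy is
    NaN where nothing is retained.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true).astype(int)
    if thresholds is None:
        thresholds = np.linspace(0.5, 1.0, 26)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.min() < 0.5 or thresholds.max() > 1.0:
        raise ValueError("confidence thresholds must lie in [0.5, 1]")
    pred = (scores >= 0.5).astype(int)
    conf = np.maximum(scores, 1.0 - scores)
    rows = []
    for c in thresholds:
        keep = conf >= c
        n_keep = int(keep.sum())
        acc = float((pred[keep] == y_true[keep]).mean()) if n_keep else float("nan")
        rows.append({"confidence": float(c), "accuracy": acc,
                     "retention": n_keep / len(y_true)})
    return pd.DataFrame(rows)


def evaluate_holdout(
    model, X_test, y_test, feature_names: list[str] | None = None
) -> ClassifierReport:
    """Holdout metrics at the 0.5 score threshold plus ROC, importances and
    the confidence–retention trade-off."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test).astype(int)
    if X_test.shape[0] == 0:
        raise ValueError("empty test set")
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set must contain both classes")
    scores = model.predict_proba(X_test)[:, 1]
    pred = (scores >= 0.5).astype(int)
    conf = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_test, pred):
        conf[t, p] += 1
    accuracy = float((pred == y_test).mean())
    f1_neg = float(f1_score(y_test, pred, pos_label=0))
    f1_pos = float(f1_score(y_test, pred, pos_label=1))
    roc_points, auc = roc_auc(scores, y_test)
    importances = None
    if hasattr(model, "feature_importances_"):
        names = feature_names or FEATURE_NAMES
        importances = dict(zip(names, map(float, model.feature_importances_)))
    curve = confidence_retention_curve(scores, y_test)
    return ClassifierReport(
        confusion=conf,
        accuracy=accuracy,
        f1_negative=f1_neg,
        f1_positive=f1_pos,
        auc=auc,
        roc_points=roc_points,
        feature_importances=importances,
        confidence_curve=curve,
        n_test=len(y_test),
    )


def balanced_subsample(y, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subsample (all of the smaller class plus
    an equal-size random draw of the larger)."""
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n = counts.min()
    idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=n, replace=False))
    return np.sort(np.concatenate(idx))


def pca_projection(
    train_X, test_X, feature_names: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """First two principal components of the training features (standardized
    on the training set); the test set is projected with the training
    loadings.  A zero-variance feature is an error naming the feature."""
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if train_X.shape[0] < 3:
        raise ValueError("need at least 3 training rows")
    names = feature_names or FEATURE_NAMES
    variances = train_X.var(axis=0)
    for j, v in enumerate(variances):
        if v == 0:
            raise ValueError(f"zero-variance feature: {names[j]}")
    scaler = StandardScaler().fit(train_X)
    pca = PCA(n_components=2).fit(scaler.transform(train_X))
    return (
        pca.transform(scaler.transform(train_X)),
        pca.transform(scaler.transform(test_X)),
    )
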