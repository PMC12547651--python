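"""RUSBoost core, reference models, CV comparison and holdout evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nocilabel.classify import (
    FEATURE_NAMES,
    CVResult,
    RusBoostClassifier,
    balanced_subsample,
    compare_models,
    confidence_retention_curve,
    crossval_auc,
    evaluate_holdout,
    make_model,
    pca_projection,
    roc_auc,
    split_holdout,
    train_reference_models,
    train_rusboost,
    tune_hyperparameters,
)


def blobs(n_pos=50, n_neg=50, sep=6.0, seed=0, d=4):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, (n_neg, d)), rng.normal(sep, 1, (n_pos, d))]
    )
    y = np.r_[np.zeros(n_neg, int), np.ones(n_pos, int)]
    return X, y


def brute_force_auc(scores, labels):
    """Pairwise concordance with ties counted one-half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSplitHoldout:
    @staticmethod
    def table(n_wells=8, units=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for w in range(n_wells):
            for u in range(units):
                rows.append(
                    {"well_id": f"W{w}", "unit_id": f"u{u}",
                     **{f: rng.normal() for f in FEATURE_NAMES},
                     "label": bool(rng.random() < 0.4)}
                )
        return pd.DataFrame(rows)

    def test_two_of_eight_wells_held_out(self):
        train, test = split_holdout(self.table(), 2, seed=1)
        assert train["well_id"].nunique() == 6
        assert test["well_id"].nunique() == 2

    def test_no_well_appears_in_both(self):
        train, test = split_holdout(self.table(), 2, seed=3)
        assert not set(train["well_id"]) & set(test["well_id"])

    def test_seeded_split_is_reproducible(self):
        t1 = split_holdout(self.table(), 2, seed=7)[1]
        t2 = split_holdout(self.table(), 2, seed=7)[1]
        assert list(t1["well_id"]) == list(t2["well_id"])

    def test_too_few_wells_errors(self):
        with pytest.raises(ValueError, match="wells"):
            split_holdout(self.table(n_wells=2), 2, seed=0)


class TestRusBoost:
    def test_separable_training_accuracy(self):
        X, y = blobs()
        model = train_rusboost(X, y, {"n_rounds": 20, "max_depth": 2}, seed=0)
        assert (model.predict(X) == y).mean() == 1.0

    def test_accepted_learners_have_error_below_half(self):
        X, y = blobs(n_pos=30, n_neg=120, sep=1.5, seed=2)
        model = train_rusboost(X, y, {"n_rounds": 40, "max_depth": 2}, seed=1)
        assert all(e < 0.5 for e in model.train_errors_)

    def test_resamples_are_class_balanced(self):
        # 5% minority prevalence, 1:1 target ratio
        X, y = blobs(n_pos=10, n_neg=190, sep=2.0, seed=4)
        model = train_rusboost(X, y, {"n_rounds": 15, "max_depth": 2}, seed=2)
        for n_min, n_maj in model.resample_class_counts_:
            assert n_min == 10 and n_maj == 10

    def test_single_stump_matches_exhaustive_best_split(self):
        """One depth-1 round on a 6-point set: the chosen partition equals the
        best weighted-Gini split over all feature thresholds (both classes
        kept in full by the 1:1 undersample, weights uniform)."""
        X = np.array([[0.1], [0.9], [2.0], [3.1], [4.0], [4.9]])
        y = np.array([0, 0, 0, 1, 1, 1])

        def gini(w, lab):
            tot = w.sum()
            if tot == 0:
                return 0.0
            p = w[lab == 1].sum() / tot
            return 2 * p * (1 - p)

        best = None
        w = np.full(6, 1 / 6)
        for thr in (X[:-1, 0] + X[1:, 0]) / 2:
            left = X[:, 0] <= thr
            score = (
                w[left].sum() * gini(w[left], y[left])
                + w[~left].sum() * gini(w[~left], y[~left])
            )
            if best is None or score < best[0]:
                best = (score, thr)
        model = RusBoostClassifier(n_rounds=1, max_depth=1, random_state=0).fit(X, y)
        stump = model.estimators_[0]
        assert stump.tree_.threshold[0] == pytest.approx(best[1])

    def test_scores_bounded_and_single_class_rejected(self):
        X, y = blobs()
        model = train_rusboost(X, y, seed=0)
        p = model.predict_proba(X)[:, 1]
        assert np.all((p >= 0) & (p <= 1))
        with pytest.raises(ValueError, match="class"):
            train_rusboost(X, np.zeros_like(y), seed=0)

    def test_non_finite_features_rejected(self):
        X, y = blobs(n_pos=5, n_neg=5)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train_rusboost(X, y, seed=0)

    def test_feature_importances_normalized(self):
        X, y = blobs(sep=2.0, seed=3)
        model = train_rusboost(X, y, {"n_rounds": 30}, seed=0)
        assert model.feature_importances_.sum() == pytest.approx(1.0)


class TestReferenceModels:
    def test_all_models_score_in_unit_interval(self):
        X, y = blobs(n_pos=40, n_neg=80, sep=2.0)
        models = train_reference_models(X, y, seed=0)
        assert set(models) == {"log", "lda", "knn", "fnn"}
        for name, model in models.items():
            p = model.predict_proba(X)[:, 1]
            assert np.all((p >= 0) & (p <= 1)), name

    def test_separable_data_all_models_reach_auc_one(self):
        X, y = blobs(sep=8.0)
        models = train_reference_models(X, y, seed=0)
        models["rusboost"] = train_rusboost(X, y, {"n_rounds": 20}, seed=0)
        for name, model in models.items():
            _, auc = roc_auc(model.predict_proba(X)[:, 1], y)
            assert auc == 1.0, name

    def test_balanced_class_weight_ratio(self):
        # sklearn's "balanced" weighting is inverse-prevalence
        from sklearn.utils.class_weight import compute_class_weight

        y = np.r_[np.zeros(90, int), np.ones(10, int)]
        w = compute_class_weight("balanced", classes=np.array([0, 1]), y=y)
        assert w[1] / w[0] == pytest.approx(9.0)


class TestTuning:
    def test_budget_one_returns_single_point(self):
        X, y = blobs(n_pos=30, n_neg=30, sep=2.0)
        best, info = tune_hyperparameters("rusboost", X, y, budget=1, seed=0)
        assert info["n_evaluated"] == 1
        assert best == info["trace"][0]["params"]

    def test_dominant_candidate_wins(self):
        X, y = blobs(n_pos=40, n_neg=40, sep=2.0)
        candidates = [
            {"n_rounds": 1, "max_depth": 1, "learning_rate": 0.01},
            {"n_rounds": 60, "max_depth": 3, "learning_rate": 0.5},
        ]
        best, info = tune_hyperparameters(
            "rusboost", X, y, budget=2, seed=0, candidates=candidates
        )
        aucs = [t["auc"] for t in info["trace"]]
        assert best == candidates[int(np.argmax(aucs))]

    def test_seeded_search_is_deterministic(self):
        X, y = blobs(n_pos=30, n_neg=60, sep=2.0)
        b1, _ = tune_hyperparameters("knn", X, y, budget=5, seed=3)
        b2, _ = tune_hyperparameters("knn", X, y, budget=5, seed=3)
        assert b1 == b2

    def test_search_method_is_flagged(self):
        X, y = blobs(n_pos=20, n_neg=20, sep=3.0)
        _, info = tune_hyperparameters("rusboost", X, y, budget=1, seed=0)
        assert info["method"] == "random-search"


class ConstantModel:
    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.tile([0.5, 0.5], (len(X), 1))


class TestCrossval:
    def test_constant_scores_give_half_auc_every_fold(self):
        X, y = blobs(n_pos=40, n_neg=40)
        cv = crossval_auc({"const": ConstantModel}, X, y, k=10, seed=0)
        np.testing.assert_allclose(cv.fold_auc["const"], 0.5)

    def test_folds_partition_the_training_set(self):
        X, y = blobs(n_pos=40, n_neg=40)
        cv = crossval_auc({"const": ConstantModel}, X, y, k=10, seed=0)
        counts = np.bincount(cv.fold_assignments, minlength=10)
        assert counts.sum() == len(y)
        assert counts.min() >= 1

    def test_separable_data_all_folds_auc_one(self):
        X, y = blobs(sep=8.0)
        cv = crossval_auc(
            {"tree": lambda: RusBoostClassifier(n_rounds=10, random_state=0)},
            X, y, k=5, seed=0,
        )
        np.testing.assert_allclose(cv.fold_auc["tree"], 1.0)

    def test_class_smaller_than_k_errors(self):
        X, y = blobs(n_pos=5, n_neg=50)
        with pytest.raises(ValueError, match="stratification"):
            crossval_auc({"const": ConstantModel}, X, y, k=10, seed=0)


class TestCompareModels:
    @staticmethod
    def cv_from(groups):
        return CVResult(
            fold_auc={f"m{i}": np.asarray(g, float) for i, g in enumerate(groups)},
            fold_assignments=np.zeros(1, int),
            k=len(groups[0]),
        )

    def test_identical_groups_h_zero_p_one(self):
        cv = self.cv_from([[0.8, 0.9, 0.7]] * 5)
        res = compare_models(cv)
        assert res["H"] == 0.0 and res["p_value"] == 1.0
        assert res["decision"] == "no model outperforms"

    def test_h_matches_direct_rank_formula(self):
        groups = [[1.0, 2.0, 3.0], [10.0, 11.0, 12.0]]
        res = compare_models(self.cv_from(groups))
        # brute-force rank computation, no ties
        all_vals = np.concatenate(groups)
        ranks = stats.rankdata(all_vals)
        n = len(all_vals)
        h = 12 / (n * (n + 1)) * sum(
            len(g) * (ranks[i * 3:(i + 1) * 3].mean()) ** 2
            for i, g in enumerate(groups)
        ) - 3 * (n + 1)
        assert res["H"] == pytest.approx(h, rel=1e-12)

    def test_group_order_exchangeable(self):
        groups = [[0.7, 0.8, 0.85], [0.6, 0.9, 0.75], [0.95, 0.88, 0.71]]
        h1 = compare_models(self.cv_from(groups))["H"]
        h2 = compare_models(self.cv_from(groups[::-1]))["H"]
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_models(self.cv_from([[0.5], [0.6]]))


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_hand_counted_concordance(self):
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_all_ties_half(self):
        _, auc = roc_auc([0.3, 0.3, 0.3, 0.3], [0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_matches_brute_force_concordance(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 200))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                labels[0], labels[1] = 0, 1
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_roc_curve_monotone_from_origin_to_one(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        points, _ = roc_auc(scores, labels)
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestEvaluateHoldout:
    class FixedScores:
        def __init__(self, scores):
            self.scores = np.asarray(scores, float)

        def predict_proba(self, X):
            return np.column_stack([1 - self.scores, self.scores])

    def test_confusion_matrix_formulas(self):
        # TP=3 FN=1 FP=1 TN=5 -> accuracy 0.8, positive F1 0.75
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.2, 0.3, 0.4])
        rep = evaluate_holdout(self.FixedScores(scores), np.zeros((10, 4)), y)
        assert rep.confusion.tolist() == [[5, 1], [1, 3]]
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.f1_positive == pytest.approx(0.75)

    def test_all_majority_prediction_zero_minority_f1(self):
        y = np.array([0, 0, 0, 0, 1])
        rep = evaluate_holdout(self.FixedScores(np.full(5, 0.1)), np.zeros((5, 4)), y)
        assert rep.f1_positive == 0.0

    def test_importances_reported_for_tree(self):
        X, y = blobs(sep=3.0)
        model = train_rusboost(X, y, {"n_rounds": 20}, seed=0)
        rep = evaluate_holdout(model, X, y)
        assert rep.feature_importances is not None
        assert sum(rep.feature_importances.values()) == pytest.approx(1.0)


class TestConfidenceCurve:
    def test_half_threshold_retains_everything(self):
        curve = confidence_retention_curve([0.6, 0.2, 0.9], [1, 0, 1], [0.5])
        assert curve["retention"].iloc[0] == 1.0

    def test_filter_and_count_example(self):
        # confidences {0.6, 0.9, 0.95}, correctness {0, 1, 1}
        scores = np.array([0.4, 0.9, 0.95])
        y = np.array([1, 1, 1])  # first prediction (0) is wrong
        curve = confidence_retention_curve(scores, y, [0.8])
        assert curve["accuracy"].iloc[0] == pytest.approx(1.0)
        assert curve["retention"].iloc[0] == pytest.approx(2 / 3)

    def test_retention_monotone_non_increasing(self, rng):
        scores = rng.random(200)
        y = rng.integers(0, 2, 200)
        curve = confidence_retention_curve(scores, y)
        assert (np.diff(curve["retention"]) <= 1e-12).all()

    def test_thresholds_outside_half_one_rejected(self):
        with pytest.raises(ValueError):
            confidence_retention_curve([0.6], [1], [0.3])


class TestPca:
    def test_component_variances_non_increasing(self, rng):
        X = rng.normal(0, [3, 2, 1, 0.5], (100, 4))
        coords, _ = pca_projection(X, X)
        assert coords[:, 0].var() >= coords[:, 1].var()

    def test_training_mean_projects_to_origin(self, rng):
        X = rng.normal(2, 1, (50, 4))
        _, test = pca_projection(X, X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(test, 0.0, atol=1e-10)

    def test_recovers_planted_two_dim_subspace(self, rng):
        latent = rng.normal(0, [5, 2], (300, 2))
        basis, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        X = latent @ basis[:, :2].T  # 2-D data embedded in 4-D
        train, _ = pca_projection(X, X)
        # reconstructed coordinates must explain all variance
        total = (X - X.mean(0)).var(axis=0).sum() / X.std(0).mean() ** 2
        assert train.var(axis=0).sum() > 0
        # principal plane orthogonal complement carries ~no variance
        from sklearn.preprocessing import StandardScaler
        from sklearn.decomposition import PCA

        z = StandardScaler().fit_transform(X)
        full = PCA(n_components=4).fit(z)
        assert full.explained_variance_ratio_[2:].sum() < 1e-10

    def test_zero_variance_feature_named(self, rng):
        X = rng.normal(0, 1, (20, 4))
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="sync_median"):
            pca_projection(X, X)


class TestBalancedSubsample:
    def test_equal_class_counts(self, rng):
        y = rng.integers(0, 2, 100)
        idx = balanced_subsample(y, seed=0)
        counts = np.bincount(y[idx])
        assert counts[0] == counts[1]
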