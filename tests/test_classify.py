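"""Classifier engine: base learners, forward selection, balanced-subset
ensembles and the leave-one-out protocol."""

import numpy as np
import pandas as pd
import pytest

from qusrecur import classify, features


def tiny_table(x, y):
    df = pd.DataFrame(x, columns=list(features.FEATURE_NAMES),
                      index=[f"P{i:02d}" for i in range(len(x))])
    df["label"] = np.where(np.asarray(y) == 1, "recurrence", "no_recurrence")
    df["survival_months"] = 12.0
    df["event"] = np.asarray(y) == 1
    return df


class TestFLD:
    def test_recovers_discriminant_direction(self):
        # isotropic clouds at (0,0) and (2,0): the estimated discriminant
        # is parallel to (1,0) within 5 degrees once sampling noise is
        # small (the angle error scales as ~sqrt(8/n) radians)
        rng = np.random.default_rng(0)
        n = 2000
        x0 = rng.normal([0, 0], 1, (n, 2))
        x1 = rng.normal([2, 0], 1, (n, 2))
        m = classify.train_fld(np.vstack([x0, x1]),
                               np.array([0] * n + [1] * n))
        w = m.weights / np.linalg.norm(m.weights)
        assert np.degrees(np.arccos(abs(w[0]))) < 5.0

    def test_matches_sklearn_lda_direction(self):
        # independent closed-form oracle: sklearn LDA's coefficient vector
        # is proportional to S_w^-1 (mu1 - mu0) as well
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (60, 3))
        y = rng.integers(0, 2, 60)
        X[y == 1, 0] += 1.0
        w = classify.train_fld(X, y).weights
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y).coef_[0]
        cos = abs(w @ ref) / (np.linalg.norm(w) * np.linalg.norm(ref))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_duplicated_columns_engage_ridge(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (30, 1))
        X = np.hstack([x, x])          # singular within-class scatter
        y = (x[:, 0] > 0).astype(int)
        m = classify.train_fld(X, y)
        assert np.all(np.isfinite(m.weights))

    def test_label_swap_flips_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 3))
        y = np.array([0, 1] * 20)
        X[y == 1] += 1.0
        w1 = classify.train_fld(X, y).weights
        w2 = classify.train_fld(X, 1 - y).weights
        np.testing.assert_allclose(w1, -w2, atol=1e-9)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            classify.train_fld(np.zeros((5, 2)), np.ones(5))


class TestKNN:
    def test_exact_match_returns_its_label(self):
        X = np.array([[0.0, 0], [1, 1], [2, 2]])
        y = np.array([0, 1, 0])
        lab, _ = classify.knn_predict(X, y, X[1:2], k=1)
        assert lab[0] == 1

    def test_three_neighbors_majority(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0]])
        y = np.array([1, 1, 0, 0])
        lab, score = classify.knn_predict(X, y, np.array([[0.05]]), k=3)
        assert lab[0] == 1
        assert score[0] == pytest.approx(2 / 3)

    def test_distance_tie_breaks_to_lower_index(self):
        X = np.array([[1.0], [-1.0]])   # equidistant from 0
        y = np.array([0, 1])
        lab, _ = classify.knn_predict(X, y, np.array([[0.0]]), k=1)
        assert lab[0] == 0              # index 0 wins the tie

    def test_even_k_vote_tie_predicts_recurrence(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        lab, score = classify.knn_predict(X, y, np.array([[0.5]]), k=2)
        assert score[0] == pytest.approx(0.5)
        assert lab[0] == 1

    def test_k_exceeding_train_raises(self):
        with pytest.raises(ValueError):
            classify.knn_predict(np.zeros((3, 1)), np.zeros(3),
                                 np.zeros((1, 1)), k=4)

    def test_matches_sklearn_on_tie_free_data(self):
        from sklearn.neighbors import KNeighborsClassifier
        rng = np.random.default_rng(3)
        Xtr = rng.normal(0, 1, (30, 3))
        ytr = rng.integers(0, 2, 30)
        Xte = rng.normal(0, 1, (10, 3))
        for k in (1, 3, 5):
            mine, _ = classify.knn_predict(Xtr, ytr, Xte, k)
            ref = KNeighborsClassifier(n_neighbors=k).fit(Xtr, ytr)
            np.testing.assert_array_equal(mine, ref.predict(Xte))


class TestSVM:
    def test_grid_has_121_pairs(self):
        grid = classify.svm_param_grid(classify.ClassifierConfig(family="svm"))
        assert len(grid) == 121
        assert (2.0**0, 2.0**0) in grid and (2.0**10, 2.0**10) in grid

    def test_separable_data_trains_perfectly(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (20, 2))
        y = np.array([0, 1] * 10)
        X[y == 1] += 6.0
        c, g, clf = classify.grid_search_svm(
            X, y, classify.ClassifierConfig(family="svm"))
        assert (clf.predict(X) == y).all()

    def test_xor_needs_rbf(self):
        """The XOR pattern is not linearly separable; some RBF grid pair
        reaches inner-LOO accuracy > 0.9."""
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float) * 4
        labels = np.array([0, 0, 1, 1])
        X = np.vstack([c + rng.normal(0, 0.3, (6, 2)) for c in centers])
        y = np.repeat(labels, 6)
        best = max(
            classify.inner_loo_balanced_accuracy(X, y, "svm",
                                                 {"c": c, "gamma": g})
            for c, g in ((2.0**i, 2.0**j)
                         for i in range(0, 11, 2) for j in range(0, 11, 2)))
        assert best > 0.9

    def test_low_level_solver_matches_svc(self):
        """The fast inner-LOO path must agree with the public estimator."""
        from sklearn.svm import SVC
        rng = np.random.default_rng(6)
        for trial in range(20):
            X = rng.normal(0, 1, (14, 2))
            y = np.array([0, 1] * 7)
            X[y == 1] += 1.5
            c = float(2 ** rng.integers(0, 11))
            g = float(2 ** rng.integers(0, 11))
            mine = classify._loo_predictions(X, y, "svm",
                                             {"c": c, "gamma": g})
            ref = np.empty_like(mine)
            for i in range(len(y)):
                tr = np.arange(len(y)) != i
                ref[i] = int(SVC(C=c, gamma=g).fit(X[tr], y[tr])
                             .predict(X[i:i + 1])[0])
            np.testing.assert_array_equal(mine, ref)


class TestSFS:
    def test_perfect_feature_selected_first(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (20, 31))
        y = np.array([1] * 10 + [0] * 10)
        X[:, 6] += 8.0 * y             # SAS separates perfectly
        sel, path = classify.sequential_forward_select(
            X, y, classify.ClassifierConfig(family="knn"))
        assert sel[0] == 6
        assert path[0] == pytest.approx(1.0)
        assert len(sel) == 1           # no further improvement possible

    def test_noise_features_complete_without_error(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (16, 31))
        y = np.array([1] * 8 + [0] * 8)
        sel, path = classify.sequential_forward_select(
            X, y, classify.ClassifierConfig(family="fld"))
        assert 1 <= len(sel) <= 3

    def test_criterion_non_decreasing(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (18, 31))
        y = np.array([1] * 9 + [0] * 9)
        X[:, 4] += 1.0 * y
        X[:, 6] += 1.0 * y
        _, path = classify.sequential_forward_select(
            X, y, classify.ClassifierConfig(family="knn"))
        assert all(b >= a for a, b in zip(path, path[1:]))


class TestBalancedSubsets:
    def test_subset_sizes_balance_the_classes(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (50, 31))
        y = np.array([1] * 16 + [0] * 34)
        X[:, 4] += 3 * y
        models = classify.balanced_subset_ensemble(
            X, y, classify.ClassifierConfig(family="fld"), rng_seed=5)
        assert len(models) == 7
        for m in models:
            rows = m.subset_rows
            assert len(rows) == 32
            assert (y[rows] == 1).sum() == 16

    def test_subsets_draw_different_majorities(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (30, 31))
        y = np.array([1] * 8 + [0] * 22)
        models = classify.balanced_subset_ensemble(
            X, y, classify.ClassifierConfig(family="fld"), rng_seed=1)
        draws = {tuple(m.subset_rows) for m in models}
        assert len(draws) > 1

    def test_already_balanced_degenerates_gracefully(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (12, 31))
        y = np.array([1] * 6 + [0] * 6)
        X[:, 4] += 3 * y
        models = classify.balanced_subset_ensemble(
            X, y, classify.ClassifierConfig(family="knn"), rng_seed=2)
        for m in models:
            assert len(m.subset_rows) == 12

    def test_tiny_minority_raises(self):
        X = np.zeros((10, 31))
        y = np.array([1] + [0] * 9)
        with pytest.raises(ValueError, match="minority"):
            classify.balanced_subset_ensemble(
                X, y, classify.ClassifierConfig(family="fld"), rng_seed=0)


class TestLOO:
    def test_metric_arithmetic(self):
        sens, spec, acc = classify.metrics_from_confusion(13, 4, 24, 10)
        assert sens == pytest.approx(76.5, abs=0.05)
        assert spec == pytest.approx(70.6, abs=0.05)
        assert acc == pytest.approx(72.5, abs=0.05)

    def test_needs_ten_patients(self):
        rng = np.random.default_rng(13)
        t = tiny_table(rng.normal(0, 1, (8, 31)), [1] * 3 + [0] * 5)
        with pytest.raises(ValueError):
            classify.loo_evaluate(t, classify.ClassifierConfig(family="knn"))

    def test_each_patient_held_out_once(self, separated_table):
        folds, rep = classify.loo_evaluate(
            separated_table, classify.ClassifierConfig(family="knn", seed=0))
        assert len(folds) == len(separated_table)
        assert sorted(f.held_out for f in folds) \
            == sorted(map(str, separated_table.index))
        assert rep.n == len(separated_table)

    def test_majority_vote_cannot_tie(self, separated_table):
        folds, _ = classify.loo_evaluate(
            separated_table, classify.ClassifierConfig(family="knn", seed=0))
        for f in folds:
            assert len(f.votes) == 7
            assert f.ensemble_label == (sum(f.votes) >= 4)

    def test_report_recomputes_from_folds(self, separated_table):
        folds, rep = classify.loo_evaluate(
            separated_table, classify.ClassifierConfig(family="knn", seed=0))
        rep2 = classify.summarize_folds(folds, "knn")
        assert rep.as_dict() == rep2.as_dict()

    def test_even_subset_count_rejected(self):
        with pytest.raises(ValueError):
            classify.ClassifierConfig(family="knn", n_subsets=6)
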