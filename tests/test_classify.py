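"""LDA, balanced scoring, stratified CV, pair search, confusion algebra."""

import numpy as np
import pytest

from cuffsep import (
    ConfusionMatrix,
    FeatureTable,
    balanced_accuracy,
    confusion_difference,
    cross_validate,
    fit_lda,
    fold_difference,
    pair_search,
    predict_lda,
    stratified_folds,
)


def _table(values, labels, channel_ids=None):
    values = np.asarray(values, dtype=float)
    return FeatureTable(
        values=values,
        labels=np.asarray(labels, dtype=int),
        trial_ids=np.arange(len(values)),
        channel_ids=(
            np.arange(values.shape[1]) if channel_ids is None
            else np.asarray(channel_ids)
        ),
    )


def _gaussian_table(rng, means, n_per_class, sd=1.0):
    means = np.asarray(means, dtype=float)
    values, labels = [], []
    for cid, mu in enumerate(means):
        x = mu + sd * rng.standard_normal((n_per_class, len(mu)))
        values.append(np.abs(x))
        labels += [cid] * n_per_class
    return _table(np.concatenate(values), labels)


class TestFitPredictLda:
    def test_toy_class_means_and_decision(self):
        # classes: A {(0,0),(0,1)}, B {(2,0),(2,1)}; hand-computed means
        # (0, 0.5) and (2, 0.5); the midplane is x = 1
        table = _table([[0, 0], [0, 1], [2, 0], [2, 1]], [0, 0, 1, 1])
        model = fit_lda(table, shrinkage=0.05)
        np.testing.assert_allclose(model.class_means, [[0, 0.5], [2, 0.5]])
        assert predict_lda(model, [[0.9, 0.5]])[0] == 0
        assert predict_lda(model, [[1.1, 0.5]])[0] == 1

    def test_mirrored_classes_boundary_on_symmetry_axis(self):
        table = _table(
            [[1, 2.3], [1, 1.7], [3, 2.3], [3, 1.7]], [0, 0, 1, 1]
        )
        model = fit_lda(table, shrinkage=0.05)
        pred = predict_lda(model, table.values)
        np.testing.assert_array_equal(pred, table.labels)

    def test_full_shrinkage_reduces_to_nearest_mean(self):
        rng = np.random.default_rng(0)
        table = _gaussian_table(rng, [[0, 0, 5], [4, 1, 0], [1, 5, 2]], 20)
        model = fit_lda(table, shrinkage=1.0)
        # pooled_cov proportional to identity
        off_diag = model.pooled_cov - np.diag(np.diag(model.pooled_cov))
        assert np.allclose(off_diag, 0)
        assert np.allclose(
            np.diag(model.pooled_cov), model.pooled_cov[0, 0]
        )
        x = np.abs(rng.standard_normal((50, 3))) * 3
        d = ((x[:, None, :] - model.class_means[None]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(
            predict_lda(model, x), model.class_ids[np.argmin(d, axis=1)]
        )

    def test_exact_tie_resolves_to_lowest_class_id(self):
        # two classes with identical training data have identical means,
        # hence bitwise-equal discriminant scores everywhere
        table = _table([[0.0], [0.5], [0.0], [0.5]], [3, 3, 7, 7])
        model = fit_lda(table, shrinkage=0.05)
        pred = predict_lda(model, [[0.1], [1.7], [42.0]])
        np.testing.assert_array_equal(pred, [3, 3, 3])

    def test_sample_at_class_mean_classified_as_that_class(self):
        rng = np.random.default_rng(1)
        means = [[0, 0], [10, 0], [0, 10]]
        table = _gaussian_table(rng, means, 30, sd=0.5)
        model = fit_lda(table, shrinkage=0.05)
        pred = predict_lda(model, model.class_means)
        np.testing.assert_array_equal(pred, model.class_ids)

    def test_dimension_mismatch_rejected(self):
        table = _table([[0, 0], [0, 1], [2, 0], [2, 1]], [0, 0, 1, 1])
        model = fit_lda(table, shrinkage=0.05)
        with pytest.raises(ValueError, match="dimension"):
            predict_lda(model, [[1.0, 2.0, 3.0]])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_lda(_table([[0.0], [1.0]], [0, 0]))

    def test_invalid_shrinkage_rejected(self):
        table = _table([[0, 0], [0, 1], [2, 0], [2, 1]], [0, 0, 1, 1])
        with pytest.raises(ValueError, match="shrinkage"):
            fit_lda(table, shrinkage=1.5)

    def test_singular_covariance_guidance(self):
        # x-variance is exactly zero within classes -> singular at lam = 0
        table = _table([[0, 0], [0, 1], [2, 0], [2, 1]], [0, 0, 1, 1])
        with pytest.raises(ValueError, match="raise the shrinkage"):
            fit_lda(table, shrinkage=0.0)

    def test_prediction_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(2)
        table = _gaussian_table(rng, [[1, 2], [3, 1], [2, 4]], 25)
        scaled = _table(table.values * 37.5, table.labels)
        x = np.abs(rng.standard_normal((40, 2))) * 3
        p1 = predict_lda(fit_lda(table, 0.05), x)
        p2 = predict_lda(fit_lda(scaled, 0.05), 37.5 * x)
        np.testing.assert_array_equal(p1, p2)


class TestBalancedAccuracy:
    def test_diagonal_is_perfect(self):
        cm = ConfusionMatrix(np.diag([5, 9, 3]), np.arange(3))
        assert balanced_accuracy(cm) == 100.0

    def test_hand_example(self):
        cm = ConfusionMatrix(np.array([[8, 2], [5, 5]]), np.arange(2))
        assert balanced_accuracy(cm) == pytest.approx(65.0)

    def test_uniform_random_expectation_is_chance(self):
        rng = np.random.default_rng(0)
        k, n = 4, 500
        scores = []
        for _ in range(50):
            y = np.repeat(np.arange(k), n)
            pred = rng.integers(0, k, k * n)
            counts = np.zeros((k, k), dtype=int)
            for t, p in zip(y, pred):
                counts[t, p] += 1
            scores.append(balanced_accuracy(ConfusionMatrix(counts, np.arange(k))))
        assert abs(np.mean(scores) - 100.0 / k) < 1.0

    def test_empty_class_row_rejected(self):
        cm = ConfusionMatrix(np.array([[3, 0], [0, 0]]), np.arange(2))
        with pytest.raises(ValueError):
            balanced_accuracy(cm)

    def test_equals_plain_accuracy_when_balanced(self):
        rng = np.random.default_rng(5)
        k, n = 3, 40
        y = np.repeat(np.arange(k), n)
        pred = rng.integers(0, k, k * n)
        counts = np.zeros((k, k), dtype=int)
        for t, p in zip(y, pred):
            counts[t, p] += 1
        plain = 100.0 * np.mean(pred == y)
        assert balanced_accuracy(
            ConfusionMatrix(counts, np.arange(k))
        ) == pytest.approx(plain)


class TestStratifiedFolds:
    def test_balanced_six_by_fifty(self):
        labels = np.repeat(np.arange(6), 50)
        folds = stratified_folds(labels, k=5, seed=0)
        for f in range(5):
            held = labels[folds.fold_of_trial == f]
            assert len(held) == 60
            assert np.all(np.bincount(held, minlength=6) == 10)

    def test_seed_determinism(self):
        labels = np.repeat(np.arange(4), 13)
        f1 = stratified_folds(labels, k=5, seed=9)
        f2 = stratified_folds(labels, k=5, seed=9)
        np.testing.assert_array_equal(f1.fold_of_trial, f2.fold_of_trial)

    def test_per_class_counts_differ_by_at_most_one(self):
        labels = np.repeat(np.arange(3), 13)  # 13 not divisible by 5
        folds = stratified_folds(labels, k=5, seed=1)
        for cid in range(3):
            per_fold = np.bincount(
                folds.fold_of_trial[labels == cid], minlength=5
            )
            assert per_fold.max() - per_fold.min() <= 1

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            stratified_folds([0, 0, 0, 1, 1, 1, 1, 1], k=5, seed=0)


class TestCrossValidate:
    def test_perfect_separation_scores_100(self):
        rng = np.random.default_rng(0)
        table = _gaussian_table(rng, [[0, 0], [50, 50]], 25, sd=0.5)
        folds = stratified_folds(table.labels, k=5, seed=0)
        res = cross_validate(table, folds)
        np.testing.assert_allclose(res.fold_scores, 100.0)
        assert res.median_score == 100.0
        assert np.trace(res.confusion.counts) == 50

    def test_confusion_row_sums_match_trial_counts(self):
        rng = np.random.default_rng(1)
        table = _gaussian_table(rng, [[0, 1], [1, 0], [1, 1]], 20)
        folds = stratified_folds(table.labels, k=5, seed=0)
        res = cross_validate(table, folds)
        np.testing.assert_array_equal(res.confusion.counts.sum(axis=1), 20)

    def test_median_is_median_of_fold_scores(self):
        rng = np.random.default_rng(2)
        table = _gaussian_table(rng, [[0, 2], [2, 0]], 25, sd=2.0)
        folds = stratified_folds(table.labels, k=5, seed=3)
        res = cross_validate(table, folds)
        assert res.median_score == pytest.approx(np.median(res.fold_scores))

    def test_trial_duplication_leaves_fold_scores_unchanged(self):
        # duplicating every trial (duplicates assigned to the same fold)
        # rescales the pooled covariance by a constant, which the decision
        # rule is invariant to
        rng = np.random.default_rng(3)
        table = _gaussian_table(rng, [[0, 1], [2, 0]], 15, sd=1.0)
        folds = stratified_folds(table.labels, k=5, seed=4)
        res = cross_validate(table, folds, shrinkage=0.05)

        dup = _table(
            np.repeat(table.values, 2, axis=0), np.repeat(table.labels, 2)
        )
        from cuffsep import FoldAssignment

        dup_folds = FoldAssignment(
            fold_of_trial=np.repeat(folds.fold_of_trial, 2),
            n_folds=5,
            seed=folds.seed,
        )
        dup_res = cross_validate(dup, dup_folds, shrinkage=0.05)
        np.testing.assert_allclose(dup_res.fold_scores, res.fold_scores)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        table = _gaussian_table(rng, [[0, 3], [3, 0]], 20, sd=1.5)
        folds = stratified_folds(table.labels, k=5, seed=5)
        res = cross_validate(table, folds)

        perm = rng.permutation(table.n_trials)
        from cuffsep import FoldAssignment

        p_table = _table(table.values[perm], table.labels[perm])
        p_folds = FoldAssignment(
            fold_of_trial=folds.fold_of_trial[perm], n_folds=5, seed=0
        )
        p_res = cross_validate(p_table, p_folds)
        np.testing.assert_allclose(
            sorted(p_res.fold_scores), sorted(res.fold_scores)
        )
        np.testing.assert_allclose(p_res.fold_scores, res.fold_scores)

    def test_mismatched_folds_rejected(self):
        rng = np.random.default_rng(6)
        table = _gaussian_table(rng, [[0], [5]], 10)
        folds = stratified_folds(np.repeat([0, 1], 5), k=5, seed=0)
        with pytest.raises(ValueError, match="match"):
            cross_validate(table, folds)


class TestFoldDifference:
    def _result(self, seed, offset=0.0):
        rng = np.random.default_rng(seed)
        table = _gaussian_table(rng, [[0, 2], [2, 0]], 25, sd=1.8)
        folds = stratified_folds(table.labels, k=5, seed=0)
        res = cross_validate(table, folds)
        if offset:
            res.fold_scores = res.fold_scores + offset
        return res

    def test_self_difference_is_zero(self):
        res = self._result(0)
        diff, med = fold_difference(res, res)
        np.testing.assert_array_equal(diff, np.zeros(5))
        assert med == 0.0

    def test_constant_offset(self):
        a = self._result(1, offset=5.0)
        b = self._result(1)
        diff, med = fold_difference(a, b)
        np.testing.assert_allclose(diff, 5.0)
        assert med == pytest.approx(5.0)

    def test_mismatched_fold_assignments_rejected(self):
        rng = np.random.default_rng(2)
        table = _gaussian_table(rng, [[0, 2], [2, 0]], 25)
        res_a = cross_validate(table, stratified_folds(table.labels, 5, seed=1))
        res_b = cross_validate(table, stratified_folds(table.labels, 5, seed=2))
        with pytest.raises(ValueError, match="share"):
            fold_difference(res_a, res_b)


class TestPairSearch:
    def test_three_channels_three_pairs(self):
        rng = np.random.default_rng(0)
        table = _gaussian_table(rng, [[0, 0, 0], [3, 1, 2]], 15)
        folds = stratified_folds(table.labels, k=5, seed=0)
        ranking = pair_search(table, folds)
        assert len(ranking) == 3
        assert {p for p, _ in ranking} == {(0, 1), (0, 2), (1, 2)}

    def test_sixteen_channels_120_pairs(self):
        rng = np.random.default_rng(1)
        values = np.abs(rng.standard_normal((30, 16)))
        table = _table(values, np.repeat([0, 1], 15))
        folds = stratified_folds(table.labels, k=5, seed=0)
        ranking = pair_search(table, folds)
        # brute-force enumeration oracle
        from itertools import combinations

        assert len(ranking) == len(list(combinations(range(16), 2))) == 120

    def test_informative_pair_ranked_first(self):
        rng = np.random.default_rng(2)
        n_per = 12
        labels = np.repeat(np.arange(4), n_per)
        values = np.abs(rng.standard_normal((len(labels), 6))) * 0.1 + 1.0
        # classes on a circle: only channels (1, 4) jointly separate them
        angles = labels * (2 * np.pi / 4)
        values[:, 1] = 2.0 + np.cos(angles) + 0.05 * rng.standard_normal(len(labels))
        values[:, 4] = 2.0 + np.sin(angles) + 0.05 * rng.standard_normal(len(labels))
        table = _table(values, labels)
        folds = stratified_folds(labels, k=5, seed=0)
        ranking = pair_search(table, folds)
        assert ranking[0][0] == (1, 4)

    def test_ranking_scores_sorted_descending(self):
        rng = np.random.default_rng(3)
        table = _gaussian_table(rng, [[0, 0, 0, 5], [5, 0, 0, 0]], 10)
        folds = stratified_folds(table.labels, k=5, seed=0)
        scores = [s for _, s in pair_search(table, folds)]
        assert scores == sorted(scores, reverse=True)

    def test_single_channel_rejected(self):
        rng = np.random.default_rng(4)
        table = _table(np.abs(rng.standard_normal((10, 1))), np.repeat([0, 1], 5))
        folds = stratified_folds(table.labels, k=5, seed=0)
        with pytest.raises(ValueError, match="2 channels"):
            pair_search(table, folds)


class TestConfusionDifference:
    def test_identical_matrices_zero(self):
        cm = ConfusionMatrix(np.array([[10, 0], [0, 10]]), np.arange(2))
        np.testing.assert_array_equal(
            confusion_difference(cm, cm), np.zeros((2, 2))
        )

    def test_hand_example_row_normalised(self):
        a = ConfusionMatrix(np.array([[10, 0], [0, 10]]), np.arange(2))
        b = ConfusionMatrix(np.array([[5, 5], [5, 5]]), np.arange(2))
        np.testing.assert_allclose(
            confusion_difference(a, b),
            [[0.5, -0.5], [-0.5, 0.5]],
        )

    def test_row_normalised_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        a = ConfusionMatrix(rng.integers(1, 20, (4, 4)), np.arange(4))
        b = ConfusionMatrix(rng.integers(1, 20, (4, 4)), np.arange(4))
        diff = confusion_difference(a, b)
        np.testing.assert_allclose(diff.sum(axis=1), 0.0, atol=1e-12)

    def test_count_mode(self):
        a = ConfusionMatrix(np.array([[3, 1], [0, 4]]), np.arange(2))
        b = ConfusionMatrix(np.array([[1, 3], [2, 2]]), np.arange(2))
        np.testing.assert_array_equal(
            confusion_difference(a, b, row_normalise=False),
            [[2, -2], [-2, 2]],
        )

    def test_mismatched_shapes_rejected(self):
        a = ConfusionMatrix(np.eye(2, dtype=int), np.arange(2))
        b = ConfusionMatrix(np.eye(3, dtype=int), np.arange(3))
        with pytest.raises(ValueError):
            confusion_difference(a, b)


class TestSklearnOracle:
    def test_agreement_on_random_instance(self):
        # reference implementation cross-check (lam = 0, uniform priors)
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(10)
        k, p, n = 4, 5, 30
        means = rng.uniform(0, 4, (k, p))
        table = _gaussian_table(rng, means, n)
        model = fit_lda(table, shrinkage=0.0)
        ref = LinearDiscriminantAnalysis(priors=np.full(k, 1 / k))
        ref.fit(table.values, table.labels)
        x = np.abs(rng.standard_normal((200, p))) * 2
        agree = np.mean(predict_lda(model, x) == ref.predict(x))
        assert agree >= 0.99
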