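"""Clustering costs, ABC-trained class centers, nearest-center classification."""

import numpy as np
import pytest

from abcfs import (
    AbcConfig,
    LabeledMatrix,
    SynthSpec,
    class_mean,
    classify_nearest_food,
    generate,
    kmeans_objective,
    train_class_centers,
    within_class_cost,
)
from abcfs.clustering import ClassCenterModel

FAST = AbcConfig(max_cycles=100, seed=0)


def geometric_median(X, iters=2000, tol=1e-12):
    """Weiszfeld iteration: independent oracle for the mean-distance optimum."""
    X = np.asarray(X, dtype=float)
    y = X.mean(axis=0)
    for _ in range(iters):
        d = np.linalg.norm(X - y, axis=1)
        if np.any(d < 1e-14):
            return X[d.argmin()]
        w = 1.0 / d
        y_new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


class TestWithinClassCost:
    def test_zero_at_coincident_samples(self):
        s = np.tile([1.0, 2.0], (5, 1))
        assert within_class_cost([1.0, 2.0], s) == 0.0

    def test_single_sample_distance(self):
        assert within_class_cost([0.0, 0.0], [[0.0, 2.0]]) == 2.0

    def test_two_sample_average(self):
        assert within_class_cost([1.0], [[0.0], [4.0]]) == 2.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            within_class_cost([0.0, 0.0], [[1.0, 2.0, 3.0]])

    def test_duplicating_samples_leaves_cost_unchanged(self):
        rng = np.random.default_rng(0)
        s = rng.random((7, 3))
        c = rng.random(3)
        assert within_class_cost(c, s) == pytest.approx(
            within_class_cost(c, np.vstack([s, s])), abs=1e-12
        )


class TestKmeansObjective:
    def test_zero_when_samples_at_centers(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0]])
        w = np.eye(2)
        assert kmeans_objective(w, x, x) == 0.0

    def test_squared_norm_single_pair(self):
        assert kmeans_objective([[1.0]], [[3.0, 0.0]], [[0.0, 0.0]]) == 9.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        x = rng.random((10, 2))
        z = rng.random((3, 2))
        w = np.zeros((10, 3))
        w[np.arange(10), rng.integers(0, 3, 10)] = 1.0
        expected = sum(
            w[i, j] * np.sum((x[i] - z[j]) ** 2)
            for i in range(10)
            for j in range(3)
        )
        assert kmeans_objective(w, x, z) == pytest.approx(expected, abs=1e-9)

    def test_rejects_invalid_assignment_rows(self):
        with pytest.raises(ValueError):
            kmeans_objective([[0.5, 0.0]], [[0.0, 0.0]], [[0.0, 0.0], [1.0, 1.0]])


class TestClassMean:
    def test_midpoint(self):
        assert np.array_equal(class_mean([[0.0, 0.0], [2.0, 2.0]]), [1.0, 1.0])

    def test_single_row_identity(self):
        assert np.array_equal(class_mean([[3.0, -1.0]]), [3.0, -1.0])

    def test_agrees_with_manual_summation(self):
        rng = np.random.default_rng(2)
        s = rng.random((13, 4))
        manual = np.array([sum(s[i, j] for i in range(13)) / 13 for j in range(4)])
        assert np.allclose(class_mean(s), manual, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_mean(np.empty((0, 2)))


def _two_blob_data(seed=0, sigma=0.1, gap=3.0, n=25):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sigma, size=(n, 2))
    b = rng.normal(gap, sigma, size=(n, 2))
    return LabeledMatrix(
        features=np.vstack([a, b]),
        labels=np.array(["a"] * n + ["b"] * n, dtype=object),
    )


class TestTrainClassCenters:
    def test_degenerate_box_collapses_to_the_point(self):
        c = np.array([2.0, -1.0, 0.5])
        data = LabeledMatrix(
            features=np.vstack([np.tile(c, (6, 1)), np.zeros((6, 3))]),
            labels=np.array(["x"] * 6 + ["y"] * 6, dtype=object),
        )
        model = train_class_centers(data, [0, 1, 2], FAST)
        assert np.allclose(model.centers_by_class["x"], c, atol=1e-6)

    def test_best_center_near_class_mean_on_tight_blobs(self):
        data = _two_blob_data()
        model = train_class_centers(data, [0, 1], FAST)
        for label in ("a", "b"):
            samples = data.features[data.class_indices(label)]
            best = model.best_center_by_class[label]
            assert np.linalg.norm(best - class_mean(samples)) < 0.2

    def test_center_dimension_matches_subset(self):
        data, _, _ = generate(SynthSpec(n_per_class=(15, 15), seed=1))
        model = train_class_centers(data, [4, 1, 7], FAST)
        for centers in model.centers_by_class.values():
            assert centers.shape == (FAST.n_foods, 3)

    def test_abc_best_not_worse_than_geometric_median_oracle(self):
        rng = np.random.default_rng(5)
        for d in (1, 2, 3):
            samples = rng.normal(size=(30, d))
            data = LabeledMatrix(
                features=np.vstack([samples, samples + 10.0]),
                labels=np.array(["a"] * 30 + ["b"] * 30, dtype=object),
            )
            model = train_class_centers(data, list(range(d)), AbcConfig(seed=d))
            best = model.best_center_by_class["a"]
            gm_cost = within_class_cost(geometric_median(samples), samples)
            assert within_class_cost(best, samples) <= gm_cost + 1e-2

    def test_duplicated_training_rows_leave_trained_cost_unchanged(self):
        # the 1/n normalization makes the cost scale-free in sample count,
        # so training on each row twice reaches the same cost level (exact
        # bit-equality is broken only by float summation order)
        data = _two_blob_data(seed=3)
        doubled = LabeledMatrix(
            features=np.vstack([data.features, data.features]),
            labels=np.concatenate([data.labels, data.labels]),
            class_set=data.class_set,
        )
        m1 = train_class_centers(data, [0, 1], AbcConfig(seed=3))
        m2 = train_class_centers(doubled, [0, 1], AbcConfig(seed=3))
        for label in data.class_set:
            rows = data.features[data.class_indices(label)]
            c1 = within_class_cost(m1.best_center_by_class[label], rows)
            c2 = within_class_cost(m2.best_center_by_class[label], rows)
            assert c1 == pytest.approx(c2, abs=1e-6)

    def test_empty_class_raises_with_class_name(self):
        data = _two_blob_data()
        data.class_set.append("ghost")
        with pytest.raises(ValueError, match="ghost"):
            train_class_centers(data, [0, 1], FAST)


class TestClassifyNearestFood:
    def _model(self):
        return ClassCenterModel(
            centers_by_class={
                "a": np.array([[0.0, 0.0], [0.2, 0.0]]),
                "b": np.array([[2.0, 0.0]]),
            },
            feature_indices=[0, 1],
            class_set=["a", "b"],
        )

    def test_exact_center_match(self):
        assert classify_nearest_food(self._model(), [0.0, 0.0]) == "a"

    def test_tie_breaks_to_earlier_class(self):
        # the query sits exactly 1.0 from the nearest center of each class
        model = ClassCenterModel(
            centers_by_class={"a": np.array([[0.0, 0.0]]), "b": np.array([[2.0, 0.0]])},
            feature_indices=[0, 1],
            class_set=["a", "b"],
        )
        assert classify_nearest_food(model, [1.0, 0.0]) == "a"

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            classify_nearest_food(self._model(), [0.0, 0.0, 0.0])

    def test_invariant_under_center_permutation_within_class(self):
        rng = np.random.default_rng(8)
        model = ClassCenterModel(
            centers_by_class={
                "a": rng.random((10, 3)),
                "b": rng.random((10, 3)) + 1.0,
            },
            feature_indices=[0, 1, 2],
            class_set=["a", "b"],
        )
        X = rng.random((50, 3)) * 2.0
        before = classify_nearest_food(model, X)
        model.centers_by_class["a"] = model.centers_by_class["a"][::-1]
        model.centers_by_class["b"] = rng.permutation(model.centers_by_class["b"])
        assert np.array_equal(before, classify_nearest_food(model, X))

    def test_high_holdout_accuracy_on_separable_fixture(self, separable_data):
        train = separable_data.take(np.r_[0:30, 40:70])
        test = separable_data.take(np.r_[30:40, 70:80])
        model = train_class_centers(train, [0, 1], FAST)
        pred = classify_nearest_food(model, test.features)
        assert (pred == test.labels).mean() > 0.95
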