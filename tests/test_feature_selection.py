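"""Stratified splitting, subset scoring, and the greedy forward search."""

import math

import numpy as np
import pytest

from abcfs import (
    AbcConfig,
    LabeledMatrix,
    SynthSpec,
    abcfs_select,
    derive_seed,
    generate,
    score_subset,
    stratified_split,
)
from abcfs.feature_selection import (
    ALL_FEATURES_USED,
    SCORE_DECLINED,
)
from conftest import shuffled_labels

FAST = AbcConfig(max_cycles=100, seed=0)


def _imbalanced_data(n_a=60, n_b=40, seed=0):
    rng = np.random.default_rng(seed)
    return LabeledMatrix(
        features=rng.random((n_a + n_b, 3)),
        labels=np.array(["a"] * n_a + ["b"] * n_b, dtype=object),
    )


class TestStratifiedSplit:
    def test_per_class_floor_arithmetic(self):
        data = _imbalanced_data()
        train, test = stratified_split(data, 0.75, np.random.default_rng(0))
        assert train.class_counts() == {"a": 45, "b": 30}
        assert test.class_counts() == {"a": 15, "b": 10}

    def test_partitions_the_input(self):
        data = _imbalanced_data()
        train, test = stratified_split(data, 0.75, np.random.default_rng(1))
        combined = np.vstack([train.features, test.features])
        assert combined.shape == data.features.shape
        key = lambda X: sorted(map(tuple, X))
        assert key(combined) == key(data.features)

    def test_empty_side_guard(self):
        # floor(0.2 * 3) = 0 training samples for a 3-sample class
        data = _imbalanced_data(n_a=3, n_b=3)
        with pytest.raises(ValueError):
            stratified_split(data, 0.2, np.random.default_rng(0))

    def test_tiny_class_named_in_error(self):
        data = LabeledMatrix(
            features=np.zeros((4, 1)),
            labels=np.array(["a", "a", "a", "rare"], dtype=object),
        )
        with pytest.raises(ValueError, match="rare"):
            stratified_split(data, 0.75, np.random.default_rng(0))

    def test_deterministic_under_seed(self):
        data = _imbalanced_data()
        t1, _ = stratified_split(data, 0.75, np.random.default_rng(42))
        t2, _ = stratified_split(data, 0.75, np.random.default_rng(42))
        assert np.array_equal(t1.features, t2.features)


class TestScoreSubset:
    def test_perfectly_separated_fixture_scores_one(self, separable_data):
        mean, std = score_subset(separable_data, [0, 1], runs=5, abc_config=FAST)
        assert mean == 1.0

    def test_single_run_has_zero_std(self, separable_data):
        _, std = score_subset(separable_data, [0], runs=1, abc_config=FAST)
        assert std == 0.0

    def test_label_shuffled_fixture_scores_near_chance(self):
        data, _, _ = generate(
            SynthSpec(n_per_class=(50, 50), n_informative=2, n_noise=2, seed=5)
        )
        null = shuffled_labels(data, seed=6)
        mean, _ = score_subset(null, [0, 1], runs=20, abc_config=FAST)
        assert 0.3 < mean < 0.7

    def test_deterministic_under_config_seed(self, separable_data):
        a = score_subset(separable_data, [0], runs=3, abc_config=AbcConfig(seed=11))
        b = score_subset(separable_data, [0], runs=3, abc_config=AbcConfig(seed=11))
        assert a == b

    def test_empty_subset_rejected(self, separable_data):
        with pytest.raises(ValueError):
            score_subset(separable_data, [], runs=1, abc_config=FAST)


def table_scorer(seed, n_features):
    """Deterministic random score table over subsets (order-independent)."""

    def score(subset):
        key = [seed] + sorted(int(j) for j in subset)
        val = np.random.default_rng(
            np.random.SeedSequence(key)
        ).random()
        return float(val), 0.0

    return score


def greedy_oracle(n_features, score, max_features=None):
    """Brute-force greedy enumeration with the same tie/stop rules."""
    if max_features is None:
        max_features = n_features
    selected, last = [], -math.inf
    while len(selected) < max_features:
        remaining = [c for c in range(n_features) if c not in selected]
        if not remaining:
            break
        scored = [(score(selected + [c])[0], -c) for c in remaining]
        best_v, neg_c = max(scored)
        if selected and best_v < last:
            break
        selected.append(-neg_c)
        last = best_v
    return selected


class TestAbcfsSelect:
    @pytest.mark.parametrize("table_seed", range(20))
    def test_matches_brute_force_greedy_on_random_tables(self, table_seed):
        score = table_scorer(table_seed, 5)
        data = LabeledMatrix(
            features=np.zeros((4, 5)),
            labels=np.array(["a", "a", "b", "b"], dtype=object),
        )
        result = abcfs_select(data, runs=1, abc_config=FAST, scorer=score)
        assert result.selected_features == greedy_oracle(5, score)

    def test_counting_scorer_reduces_to_plain_sfs(self):
        informative = {1, 3, 4}
        score = lambda sub: (len(set(sub) & informative) / 3, 0.0)
        data = LabeledMatrix(
            features=np.zeros((4, 6)),
            labels=np.array(["a", "a", "b", "b"], dtype=object),
        )
        result = abcfs_select(data, runs=1, abc_config=FAST, scorer=score)
        # informative features first (lowest index on ties), then plateau
        assert result.selected_features[:3] == [1, 3, 4]
        assert result.selected_features == greedy_oracle(6, score)

    def test_single_feature_dataset_uses_it(self, separable_data):
        data = separable_data.restrict([0])
        result = abcfs_select(data, runs=2, abc_config=FAST)
        assert result.selected_features == [0]
        assert result.stop_reason == ALL_FEATURES_USED

    def test_accepted_scores_nondecreasing_and_unique_features(self):
        score = table_scorer(99, 6)
        data = LabeledMatrix(
            features=np.zeros((4, 6)),
            labels=np.array(["a", "a", "b", "b"], dtype=object),
        )
        result = abcfs_select(data, runs=1, abc_config=FAST, scorer=score)
        means = [s.mean_score for s in result.trace.steps]
        assert all(b >= a for a, b in zip(means, means[1:]))
        assert len(set(result.selected_features)) == len(result.selected_features)

    def test_declining_feature_excluded_from_selection(self):
        # scripted scores: rise, then strictly decline at the third step
        table = {(0,): 0.6, (1,): 0.5, (0, 1): 0.8, (0, 1, 2): 0.7}

        def score(sub):
            key = tuple(sorted(sub))
            return table.get(key, 0.1), 0.0

        data = LabeledMatrix(
            features=np.zeros((4, 3)),
            labels=np.array(["a", "a", "b", "b"], dtype=object),
        )
        result = abcfs_select(data, runs=1, abc_config=FAST, scorer=score)
        assert result.selected_features == [0, 1]
        assert result.stop_reason == SCORE_DECLINED
        assert result.trace.rejected_step is not None
        assert result.trace.rejected_step.chosen_feature == 2

    def test_max_features_bound(self):
        score = table_scorer(7, 6)
        data = LabeledMatrix(
            features=np.zeros((4, 6)),
            labels=np.array(["a", "a", "b", "b"], dtype=object),
        )
        result = abcfs_select(
            data, max_features=2, runs=1, abc_config=FAST, scorer=score
        )
        if result.stop_reason != SCORE_DECLINED:
            assert len(result.selected_features) <= 2

    def test_selection_deterministic_under_seed(self, separable_data):
        cfg = AbcConfig(max_cycles=60, seed=21)
        r1 = abcfs_select(separable_data, runs=3, abc_config=cfg)
        r2 = abcfs_select(separable_data, runs=3, abc_config=cfg)
        assert r1.to_dict() == r2.to_dict()


class TestDeriveSeed:
    def test_stable_and_bounded(self):
        assert derive_seed(1, 2, 3) == derive_seed(1, 2, 3)
        assert 0 <= derive_seed(123456789, 42) < 2**31

    def test_distinct_keys_give_distinct_seeds(self):
        seeds = {derive_seed(0, s, c) for s in range(10) for c in range(10)}
        assert len(seeds) == 100
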