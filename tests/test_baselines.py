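"""Importance baselines: hand-computed Gini, PI nulls, exact Shapley axioms."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from tpscore import (
    OutcomeVector,
    TrainConfig,
    gini_feature_importance,
    permutation_importance,
    shapley_values,
    train_model,
    union_top_k,
)
from tpscore.baselines import shapley_temporal, shapley_values_retrain


class TestGiniImportance:
    def test_single_stump_hand_value(self):
        """Perfect 2/2 split on feature 1: that feature gets importance 1.

        By hand: root Gini 0.5 with weight 1, pure children, so the node
        importance is 0.5 and after normalization the split feature carries
        everything.
        """
        X = np.array([[5.0, 0.0], [3.0, 0.0], [4.0, 1.0], [6.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        imp = gini_feature_importance(stump)
        np.testing.assert_allclose(imp, [0.0, 1.0], atol=1e-9)

    def test_unused_feature_scores_zero(self, rng):
        X = rng.random((100, 5))
        y = (X[:, 2] > 0.5).astype(int)
        tree = DecisionTreeClassifier(max_depth=2, random_state=0).fit(X, y)
        imp = gini_feature_importance(tree)
        used = set(tree.tree_.feature[tree.tree_.feature >= 0])
        for j in range(5):
            if j not in used:
                assert imp[j] == 0.0

    def test_two_identical_trees_equal_one(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        t1 = DecisionTreeClassifier(random_state=0).fit(X, y)

        class Pair:
            estimators_ = [t1, t1]

        np.testing.assert_allclose(
            gini_feature_importance(Pair()), gini_feature_importance(t1), atol=1e-12
        )

    def test_nonnegative_and_sums_to_one(self, rng):
        X = rng.random((200, 6))
        y = (X[:, 0] + X[:, 3] > 1).astype(int)
        forest = RandomForestClassifier(n_estimators=15, random_state=1).fit(X, y)
        imp = gini_feature_importance(forest)
        assert np.all(imp >= 0)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_sklearn_attribute(self, rng):
        """Independent cross-check against scikit-learn's own computation."""
        X = rng.random((300, 5))
        y = (X[:, 1] > X[:, 4]).astype(int)
        forest = RandomForestClassifier(n_estimators=10, random_state=2).fit(X, y)
        np.testing.assert_allclose(
            gini_feature_importance(forest), forest.feature_importances_, atol=1e-9
        )

    def test_rejects_temporal_backbone(self, small_cohort):
        X, Y, _ = small_cohort
        model = train_model(X, Y, TrainConfig(kind="gru", hidden=8, max_epochs=5, patience=2))
        with pytest.raises(TypeError, match="recurrent"):
            gini_feature_importance(model)

    def test_rejects_unfitted(self):
        with pytest.raises(Exception):
            gini_feature_importance(DecisionTreeClassifier())


class IgnoreFeatureModel:
    """Predicts from feature 0 only; feature 1 is provably ignored."""

    def predict_proba(self, X):
        return np.clip(X[:, 0], 0.0, 1.0)


class TestPermutationImportance:
    def test_ignored_feature_is_exactly_zero(self, rng):
        X = rng.random((80, 2))
        y = (X[:, 0] > 0.5).astype(int)
        imp = permutation_importance(IgnoreFeatureModel(), X, y, n_repeats=5, seed=0)
        assert imp[1] == 0.0

    def test_sole_informative_feature_drop_near_half(self, rng):
        """Permuting the only informative feature of a perfect model sends
        AUROC to ~0.5, so the importance concentrates near 0.5."""
        n = 2000
        X = rng.random((n, 2))
        y = (X[:, 0] > 0.5).astype(int)
        imp = permutation_importance(IgnoreFeatureModel(), X, y, n_repeats=50, seed=1)
        se = 1.0 / np.sqrt(n)  # crude scale of a permuted-AUROC deviation
        assert abs(imp[0] - 0.5) < 3 * se

    def test_seeded_determinism(self, rng):
        X = rng.random((50, 3))
        y = (X[:, 0] > 0.5).astype(int)
        a = permutation_importance(IgnoreFeatureModel(), X, y, n_repeats=1, seed=9)
        b = permutation_importance(IgnoreFeatureModel(), X, y, n_repeats=1, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_null_feature_converges_to_zero(self, rng):
        X = rng.random((500, 2))
        y = rng.integers(0, 2, 500)
        est = LogisticRegression().fit(X, y)
        imp = permutation_importance(est, X, y, n_repeats=50, seed=2)
        assert abs(imp[1]) < 0.05

    def test_single_class_labels_error(self, rng):
        X = rng.random((10, 2))
        with pytest.raises(ValueError, match="single-class"):
            permutation_importance(IgnoreFeatureModel(), X, np.ones(10), seed=0)


class TestShapley:
    def test_single_feature_equals_f_minus_baseline(self, rng):
        X = rng.random((6, 1))
        predict = lambda m: 0.3 + 0.5 * m[:, 0]
        phi = shapley_values(predict, X)
        np.testing.assert_allclose(phi[:, 0], predict(X) - 0.3, atol=1e-12)

    def test_additive_model_decomposes_exactly(self, rng):
        X = rng.random((5, 2))
        g1 = lambda v: v**2
        g2 = lambda v: np.sin(v)
        predict = lambda m: g1(m[:, 0]) + g2(m[:, 1])
        phi = shapley_values(predict, X)
        np.testing.assert_allclose(phi[:, 0], g1(X[:, 0]) - g1(0.0), atol=1e-9)
        np.testing.assert_allclose(phi[:, 1], g2(X[:, 1]) - np.sin(0.0), atol=1e-9)

    def test_efficiency_per_case(self, rng):
        X = rng.integers(0, 2, size=(8, 4)).astype(float)
        predict = lambda m: 1.0 / (1.0 + np.exp(-(m @ np.array([1.0, -2.0, 0.5, 3.0]))))
        phi = shapley_values(predict, X)
        base = predict(np.zeros((1, 4)))[0]
        np.testing.assert_allclose(phi.sum(axis=1), predict(X) - base, atol=1e-9)

    def test_dummy_feature_zero(self, rng):
        X = rng.random((5, 3))
        predict = lambda m: m[:, 0] * m[:, 1]
        phi = shapley_values(predict, X)
        np.testing.assert_allclose(phi[:, 2], 0.0, atol=1e-12)

    def test_symmetric_players_equal(self):
        X = np.ones((3, 2))
        predict = lambda m: m[:, 0] + m[:, 1]
        phi = shapley_values(predict, X)
        np.testing.assert_allclose(phi[:, 0], phi[:, 1], atol=1e-12)

    def test_too_many_features_without_budget(self, rng):
        with pytest.raises(ValueError, match="budget|n_permutations"):
            shapley_values(lambda m: m.sum(axis=1), rng.random((2, 13)))

    def test_sampling_mode_approximates_exact(self, rng):
        X = rng.integers(0, 2, size=(10, 5)).astype(float)
        predict = lambda m: m @ np.array([0.5, -0.3, 0.2, 0.0, 0.1])
        exact = shapley_values(predict, X)
        approx = shapley_values(predict, X, n_permutations=200, seed=0)
        np.testing.assert_allclose(approx, exact, atol=0.05)

    def test_retrain_oracle_agrees_on_separable_toy(self):
        """Masking-based and retrain-per-coalition values agree on a toy
        problem where feature 0 separates the classes and feature 1 is
        pure noise."""
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]] * 5)
        y = X[:, 0].astype(int)
        phi_retrain = shapley_values_retrain(
            lambda: DecisionTreeClassifier(random_state=0), X, y
        )
        est = DecisionTreeClassifier(random_state=0).fit(X, y)
        phi_mask = shapley_values(lambda m: est.predict_proba(m)[:, 1], X)
        # noise feature: both modes assign ~0; signal feature dominates in both
        assert np.abs(phi_retrain[:, 1]).max() < 0.3
        assert np.abs(phi_mask[:, 1]).max() < 0.3
        assert np.abs(phi_retrain[:, 0]).mean() > np.abs(phi_retrain[:, 1]).mean()
        assert np.abs(phi_mask[:, 0]).mean() > np.abs(phi_mask[:, 1]).mean()

    def test_temporal_flattening_aggregates_per_feature(self, small_cohort):
        X, Y, _ = small_cohort
        from tpscore.backbone import FixtureModel

        model = FixtureModel(lambda arr: arr[:, :, 0].mean(axis=1), list(X.feature_ids))
        sub = __import__("tpscore").backbone.subset_cases(X, np.arange(5))
        # restrict to 2 features x 10 days = 20 players -> sampling mode
        small = __import__("tpscore").EventTensor(
            sub.data[:, :, :2], list(sub.case_ids), list(sub.day_labels),
            sub.feature_ids[:2], sub.feature_category[:2],
        )
        model2 = FixtureModel(lambda arr: arr[:, :, 0].mean(axis=1), list(small.feature_ids))
        agg = shapley_temporal(model2, small, n_permutations=30, seed=0)
        assert agg.shape == (2,)
        assert agg[0] > agg[1]  # the read feature dominates the ignored one


class TestUnionTopK:
    def make_cols(self, scores: dict):
        features = sorted({f for s in scores.values() for f in s})
        return {
            lab: pd.Series([s.get(f, 0.0) for f in features], index=features)
            for lab, s in scores.items()
        }

    def test_identical_columns_union_is_k(self):
        col = {"m1": {"a": 3.0, "b": 2.0, "c": 1.0}, "m2": {"a": 3.0, "b": 2.0, "c": 1.0}}
        union, ranks = union_top_k(self.make_cols(col), k=2)
        assert union == ["a", "b"]
        assert ranks.loc["a", "m1"] == 1 and ranks.loc["b", "m2"] == 2

    def test_disjoint_topk_union_is_mk(self):
        col = {
            "m1": {"a": 9.0, "b": 8.0, "c": 0.1, "d": 0.2},
            "m2": {"a": 0.1, "b": 0.2, "c": 9.0, "d": 8.0},
        }
        union, _ = union_top_k(self.make_cols(col), k=2)
        assert sorted(union) == ["a", "b", "c", "d"]

    def test_absolute_value_ranking_and_hand_union(self):
        col = {
            "m1": {"a": -5.0, "b": 1.0, "c": 0.5},  # |.| puts a first
            "m2": {"a": 0.0, "b": -2.0, "c": 1.0},
        }
        union, ranks = union_top_k(self.make_cols(col), k=1)
        assert union == ["a", "b"]
        assert ranks.loc["a", "m1"] == 1
        assert ranks.loc["a", "m2"] == 3

    def test_mismatched_universes_error(self):
        cols = {
            "m1": pd.Series([1.0], index=["a"]),
            "m2": pd.Series([1.0], index=["b"]),
        }
        with pytest.raises(ValueError, match="universe"):
            union_top_k(cols, k=1)
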