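"""Feature-selection consensus, AUC, and permutation machinery."""

import numpy as np
import pandas as pd
import pytest

from mddpanel.ml import (
    auc_mann_whitney,
    consensus_panel,
    fit_logistic_roc,
    lasso_stability_selection,
    permutation_test_auc,
    rf_importance,
    svm_rfe_loocv,
)


def brute_force_auc(scores, labels) -> float:
    """Oracle: count concordant and tied case/control pairs directly."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = ties = 0
    for c in cases:
        for h in controls:
            wins += c > h
            ties += c == h
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def _features(rng, n_per_class=15, p=8):
    cols = [f"g{i}" for i in range(p)]
    X = pd.DataFrame(rng.normal(size=(2 * n_per_class, p)), columns=cols)
    y = np.array([1] * n_per_class + [0] * n_per_class)
    return X, y


class TestAuc:
    def test_separated_and_tied_examples(self):
        assert auc_mann_whitney([2, 3, 0, 1], [1, 1, 0, 0]) == 1.0
        assert auc_mann_whitney([5, 5, 5, 5], [1, 1, 0, 0]) == 0.5
        assert auc_mann_whitney([1, 3, 2, 4], [1, 1, 0, 0]) == 0.25

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 50))
            labels = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_label_swap_reflects_auc(self, rng):
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        scores = rng.normal(size=20)
        a = auc_mann_whitney(scores, labels)
        assert auc_mann_whitney(scores, 1 - labels) == pytest.approx(1 - a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_mann_whitney([1, 2], [1, 1])


class TestStabilitySelection:
    def test_b_one_gives_binary_probabilities(self, rng):
        X, y = _features(rng)
        res = lasso_stability_selection(X, y, B=1, seed=0)
        assert set(res.selection_probability.unique()) <= {0.0, 1.0}

    def test_constant_feature_never_selected(self, rng):
        X, y = _features(rng)
        X["g0"] = 1.0
        X.loc[y == 1, "g1"] += 3.0
        res = lasso_stability_selection(X, y, B=30, seed=1)
        assert res.selection_probability["g0"] == 0.0

    def test_separating_feature_dominates(self, rng):
        X, y = _features(rng)
        X.loc[y == 1, "g0"] = rng.uniform(1, 2, 15)
        X.loc[y == 0, "g0"] = rng.uniform(-2, -1, 15)
        res = lasso_stability_selection(X, y, B=100, seed=2)
        assert res.selection_probability["g0"] >= 0.95
        assert "g0" in res.stable_set

    def test_threshold_is_strict(self, rng):
        X, y = _features(rng, p=3)
        X.loc[y == 1, "g0"] += 3.0
        res = lasso_stability_selection(X, y, B=5, threshold=1.0, seed=3)
        assert res.stable_set == []  # probability 1.0 is not > 1.0

    def test_invalid_b_rejected(self, rng):
        X, y = _features(rng)
        with pytest.raises(ValueError, match="B"):
            lasso_stability_selection(X, y, B=0)


class TestSvmRfe:
    def test_separating_feature_wins_with_perfect_accuracy(self, rng):
        X, y = _features(rng, n_per_class=10, p=2)
        X.loc[y == 1, "g0"] = rng.uniform(1, 2, 10)
        X.loc[y == 0, "g0"] = rng.uniform(-2, -1, 10)
        res = svm_rfe_loocv(X, y)
        assert res.optimal_set == ["g0"]
        assert res.accuracy_curve[res.optimal_size] == 1.0

    def test_identical_copies_tie_to_smallest(self, rng):
        base = rng.normal(size=20)
        base[:10] += 2.0
        X = pd.DataFrame({"a": base, "b": base, "c": base})
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        res = svm_rfe_loocv(X, y)
        assert len(set(res.accuracy_curve.values())) == 1  # flat curve
        assert res.optimal_size == 1

    def test_null_features_near_chance(self, rng):
        X, y = _features(rng, n_per_class=15, p=4)
        res = svm_rfe_loocv(X, y)
        assert 0.3 <= max(res.accuracy_curve.values()) <= 0.8

    def test_elimination_order_is_permutation(self, rng):
        X, y = _features(rng, p=6)
        res = svm_rfe_loocv(X, y)
        assert sorted(res.elimination_order) == sorted(X.columns)

    def test_single_feature_rejected(self, rng):
        X, y = _features(rng, p=1)
        with pytest.raises(ValueError, match="2 features"):
            svm_rfe_loocv(X, y)


class TestRandomForest:
    def test_constant_feature_has_zero_importance(self, rng):
        X, y = _features(rng, p=4)
        X["g0"] = 7.0
        X.loc[y == 1, "g1"] += 2.0
        res = rf_importance(X, y, ntree=200, seed=0)
        assert res.mean_decrease_gini["g0"] == 0.0
        assert "g0" not in res.selected_set

    def test_separating_feature_ranks_first(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X, y = _features(r)
            X.loc[y == 1, "g3"] = r.uniform(1, 2, 15)
            X.loc[y == 0, "g3"] = r.uniform(-2, -1, 15)
            res = rf_importance(X, y, ntree=500, seed=seed)
            hits += res.rank["g3"] == 1
        assert hits >= 9

    def test_seeded_determinism(self, rng):
        X, y = _features(rng)
        a = rf_importance(X, y, ntree=100, seed=5)
        b = rf_importance(X, y, ntree=100, seed=5)
        pd.testing.assert_series_equal(a.mean_decrease_gini, b.mean_decrease_gini)

    def test_top_k_rule(self, rng):
        X, y = _features(rng)
        res = rf_importance(X, y, ntree=100, seed=1, rule="top_k", top_k=3)
        assert len(res.selected_set) == 3


class TestConsensusAndModel:
    def test_intersection_examples(self):
        assert consensus_panel({"a", "b", "c"}, {"a", "b"}, {"b"}) == ["b"]
        assert consensus_panel({"a", "b"}, {"a", "b"}, {"a", "b"}) == ["a", "b"]
        with pytest.warns(UserWarning, match="empty"):
            assert consensus_panel({"a"}, {"b"}, {"c"}) == []

    def test_universe_order_preserved(self):
        panel = consensus_panel({"z", "m"}, {"m", "z"}, {"z", "m"}, universe=["z", "m"])
        assert panel == ["z", "m"]

    def test_perfect_separation_gives_auc_one(self, rng):
        X = pd.DataFrame({"f": np.r_[rng.uniform(1, 2, 10), rng.uniform(-2, -1, 10)]})
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        _, auc, roc = fit_logistic_roc(X, y)
        assert auc == 1.0
        assert roc["tpr"].iloc[-1] == 1.0 and roc["fpr"].iloc[-1] == 1.0

    def test_single_feature_model_matches_feature_auc(self, rng):
        X, y = _features(rng, p=2)
        Xf = X[["g0"]]
        _, auc_model, _ = fit_logistic_roc(Xf, y)
        auc_feat = auc_mann_whitney(Xf["g0"], y)
        assert auc_model == pytest.approx(max(auc_feat, 1 - auc_feat), abs=1e-9)

    def test_null_model_auc_moderately_optimistic(self):
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X, y = _features(r, p=3)
            _, auc, _ = fit_logistic_roc(X, y)
            aucs.append(auc)
        assert 0.4 <= np.mean(aucs) <= 0.75


class TestPermutation:
    def test_minimum_p_is_one_over_b_plus_one(self, rng):
        X = pd.DataFrame({"f": np.r_[rng.uniform(5, 6, 8), rng.uniform(-6, -5, 8)]})
        y = np.r_[np.ones(8, int), np.zeros(8, int)]
        auc, p = permutation_test_auc(X, y, B=199, seed=0)
        assert auc == 1.0
        assert p >= 1 / 200
        assert p == pytest.approx(1 / 200, abs=0.02)  # near the floor

    def test_floor_formula_at_b_one(self, rng):
        X, y = _features(rng, p=2)
        _, p = permutation_test_auc(X, y, B=1, seed=0)
        assert p in (0.5, 1.0)

    def test_null_auc_half_not_significant(self):
        ps = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X, y = _features(r, n_per_class=15, p=2)
            _, p = permutation_test_auc(X, y, B=100, seed=seed)
            ps.append(p)
        assert np.median(ps) >= 0.3


class TestAucProperties:
    """Algebraic identities of the Mann-Whitney AUC on arbitrary scores."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    scores_labels = st.lists(
        st.tuples(st.integers(-50, 50), st.booleans()), min_size=4, max_size=40
    ).filter(lambda xs: 0 < sum(lab for _, lab in xs) < len(xs))

    @settings(max_examples=60, derandomize=True)
    @given(scores_labels)
    def test_label_swap_and_score_negation(self, xs):
        scores = np.array([s for s, _ in xs], dtype=float)
        labels = np.array([int(lab) for _, lab in xs])
        a = auc_mann_whitney(scores, labels)
        assert 0.0 <= a <= 1.0
        assert auc_mann_whitney(scores, 1 - labels) == pytest.approx(1 - a, abs=1e-12)
        assert auc_mann_whitney(-scores, labels) == pytest.approx(1 - a, abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(scores_labels, st.integers(1, 5))
    def test_monotone_transform_invariance(self, xs, k):
        scores = np.array([s for s, _ in xs], dtype=float)
        labels = np.array([int(lab) for _, lab in xs])
        a = auc_mann_whitney(scores, labels)
        assert auc_mann_whitney(k * scores + 3, labels) == pytest.approx(a, abs=1e-12)
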