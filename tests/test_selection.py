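"""Random-forest SNP ranking: tuning, Gini, SHAP, Boruta, elbow, set algebra."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestRegressor

from aiopheno.selection import (
    RFConfig, SNPSets, RandomForestSNPSelector, tune_and_fit_rf,
    gini_importance, shap_importance, boruta_select, elbow_threshold,
    select_by_elbow, combine_sets,
)


@pytest.fixture(scope="module")
def dosages():
    rng = np.random.default_rng(42)
    return rng.integers(0, 3, (400, 30)).astype(float)


class TestForestFit:
    def test_planted_step_function_gives_high_oob(self, dosages):
        y = (dosages[:, 4] >= 1).astype(float) * 10.0
        forest, info = tune_and_fit_rf(
            dosages, y, RFConfig(n_estimators=200, max_features=1.0, seed=0))
        assert info["oob_r2"] >= 0.9

    def test_pure_noise_gives_near_zero_oob(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, (500, 30)).astype(float)
        y = rng.normal(size=500)
        _, info = tune_and_fit_rf(X, y, RFConfig(n_estimators=200, seed=0))
        assert abs(info["oob_r2"]) < 0.1

    def test_same_seed_reproduces_scores(self, dosages):
        y = dosages[:, 2] + np.random.default_rng(0).normal(0, 0.5, 400)
        f1, _ = tune_and_fit_rf(dosages, y, RFConfig(n_estimators=50, seed=9))
        f2, _ = tune_and_fit_rf(dosages, y, RFConfig(n_estimators=50, seed=9))
        np.testing.assert_array_equal(gini_importance(f1), gini_importance(f2))

    def test_constant_phenotype_rejected(self, dosages):
        with pytest.raises(ValueError, match="constant"):
            tune_and_fit_rf(dosages, np.ones(400))

    def test_zero_budget_rejected(self, dosages):
        with pytest.raises(ValueError, match="budget"):
            tune_and_fit_rf(dosages, dosages[:, 0], RFConfig(budget=0, tune=True))

    def test_bayesian_tuning_returns_best_params(self, dosages):
        y = dosages[:, 0] * 2 + np.random.default_rng(3).normal(0, 0.5, 400)
        forest, info = tune_and_fit_rf(
            dosages, y, RFConfig(tune=True, budget=6, n_initial=4, seed=0))
        assert set(info["best_params"]) == {"n_estimators", "max_depth",
                                            "min_samples_split",
                                            "min_impurity_decrease", "max_features"}
        assert len(info["trace"]) == 6
        assert info["oob_r2"] == max(info["trace"])


class TestGini:
    def test_causal_snp_ranks_first(self, dosages):
        rng = np.random.default_rng(5)
        y = 5 * dosages[:, 7] + rng.normal(0, 1, 400)
        forest, _ = tune_and_fit_rf(dosages, y, RFConfig(n_estimators=150, seed=0))
        assert np.argmax(gini_importance(forest)) == 7

    def test_constant_snp_has_zero_importance(self, dosages):
        X = dosages.copy()
        X[:, 3] = 1.0
        y = X[:, 0] + np.random.default_rng(0).normal(0, 0.3, 400)
        forest, _ = tune_and_fit_rf(X, y, RFConfig(n_estimators=100, seed=0))
        assert gini_importance(forest)[3] == 0.0

    def test_scores_sum_to_one(self, dosages):
        y = dosages[:, 1] + np.random.default_rng(2).normal(0, 0.5, 400)
        forest, _ = tune_and_fit_rf(dosages, y, RFConfig(n_estimators=80, seed=0))
        assert gini_importance(forest).sum() == pytest.approx(1.0, abs=1e-9)


class TestShap:
    def test_depth_one_tree_matches_two_player_game(self):
        """For a depth-1 tree the Shapley value of the split feature is the
        full deviation from the baseline and every other feature gets 0."""
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, (200, 4)).astype(float)
        y = (X[:, 1] >= 1).astype(float)
        rf = RandomForestRegressor(n_estimators=1, max_depth=1, bootstrap=False,
                                   max_features=None, random_state=0).fit(X, y)
        tree = rf.estimators_[0].tree_
        assert tree.feature[0] == 1
        from aiopheno._treeshap import forest_shap_values
        phi, expected = forest_shap_values(rf, X[:20])
        pred = rf.predict(X[:20])
        np.testing.assert_allclose(phi[:, 1], pred - expected, atol=1e-12)
        np.testing.assert_array_equal(phi[:, [0, 2, 3]], 0.0)

    def test_constant_snp_zero_mean_abs_shap(self, dosages):
        X = dosages.copy()
        X[:, 5] = 2.0
        y = X[:, 0] + np.random.default_rng(1).normal(0, 0.3, 400)
        forest, _ = tune_and_fit_rf(X, y, RFConfig(n_estimators=60, seed=0))
        assert shap_importance(forest, X[:100])[5] == 0.0

    def test_local_accuracy_through_public_api(self, dosages):
        from aiopheno._treeshap import forest_shap_values
        y = dosages[:, 0] - dosages[:, 9] + np.random.default_rng(4).normal(0, 0.5, 400)
        forest, _ = tune_and_fit_rf(dosages, y, RFConfig(n_estimators=40, seed=0))
        phi, ev = forest_shap_values(forest, dosages[:50])
        np.testing.assert_allclose(phi.sum(1) + ev, forest.predict(dosages[:50]), atol=1e-6)


class TestBoruta:
    def test_strong_snp_confirmed(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, (300, 20)).astype(float)
        y = 8 * X[:, 6] + rng.normal(0, 1, 300)
        decisions, _ = boruta_select(X, y, max_iter=12, seed=0)
        assert decisions[6] == "confirmed"

    def test_pure_noise_mostly_rejected(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, (500, 50)).astype(float)
        y = rng.normal(size=500)
        decisions, _ = boruta_select(X, y, max_iter=15, seed=0)
        assert (decisions == "rejected").mean() >= 0.9

    def test_input_not_modified(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, (100, 10)).astype(float)
        X0 = X.copy()
        boruta_select(X, X[:, 0] + rng.normal(0, 1, 100), max_iter=10, seed=0)
        np.testing.assert_array_equal(X, X0)

    def test_min_iterations_enforced(self):
        with pytest.raises(ValueError, match="max_iter"):
            boruta_select(np.zeros((10, 2)), np.arange(10.0), max_iter=5)


class TestElbow:
    def test_sharp_drop_example(self):
        scores = np.array([10, 9, 1, 0.9, 0.8])
        cut = elbow_threshold(scores)
        assert cut == 2                       # the third value
        selected, _ = select_by_elbow(scores)
        assert selected == {0, 1, 2}          # ≥-rule keeps the cutoff value

    def test_linear_decay_ties_break_earliest(self):
        assert elbow_threshold(np.array([5.0, 4.0, 3.0, 2.0, 1.0])) == 1

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            elbow_threshold(np.array([2.0, 1.0]))

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            elbow_threshold(np.array([1.0, 5.0, 2.0]))

    def test_adding_clear_top_score_never_drops_selected(self, rng):
        """Stability: adding another clearly-important score (a duplicate of
        the current top, well above the elbow) keeps every previously
        selected score selected. Note the rule is deliberately *not* stable
        to adding an extreme outlier far above the range — that creates a
        new dominant drop at the top and legitimately shrinks the selection.
        """
        for _ in range(50):
            scores = np.sort(rng.gamma(2.0, 1.0, 12))[::-1]
            scores[:3] += 10          # create a clear elbow after 3 scores
            before, _ = select_by_elbow(scores)
            grown = np.sort(np.concatenate([[scores[0]], scores]))[::-1]
            after, _ = select_by_elbow(grown)
            vals_before = set(np.round(scores[sorted(before)], 12))
            vals_after = set(np.round(grown[sorted(after)], 12))
            assert vals_before <= vals_after


class TestSetAlgebra:
    def test_worked_example(self):
        sets = combine_sets({1, 2, 3}, {2, 3, 4}, {3, 4, 5})
        assert sets.cross_set == {3}
        assert sets.union_set == {2, 3, 4}

    def test_identical_selections_collapse(self):
        sets = combine_sets({1, 5}, {1, 5}, {1, 5})
        assert sets.cross_set == sets.union_set == {1, 5}

    def test_cross_is_subset_of_union(self, rng):
        for _ in range(50):
            a, b, c = (set(rng.choice(20, rng.integers(0, 10), replace=False).tolist())
                       for _ in range(3))
            sets = combine_sets(a, b, c)
            assert sets.cross_set <= sets.union_set

    def test_invariant_enforced_by_type(self):
        with pytest.raises(ValueError):
            SNPSets(cross_set={1, 2}, union_set={1})


class TestPermutationBehaviour:
    def test_scores_follow_column_permutation(self):
        """Permuting SNP columns permutes Gini and SHAP scores (up to the
        forest's internal tie-breaking on exactly equal split gains)."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 8))
        y = 2 * X[:, 2] + X[:, 5] + rng.normal(0, 0.3, 200)
        perm = rng.permutation(8)
        kw = dict(n_estimators=20, max_features=1.0, bootstrap=False, random_state=0)
        f1 = RandomForestRegressor(**kw).fit(X, y)
        f2 = RandomForestRegressor(**kw).fit(X[:, perm], y)
        np.testing.assert_allclose(gini_importance(f1)[perm], gini_importance(f2), atol=0.02)
        np.testing.assert_allclose(shap_importance(f1, X)[perm],
                                   shap_importance(f2, X[:, perm]), atol=0.02)


class TestSelectorEstimator:
    def test_fits_and_reports(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, (250, 40)).astype(float)
        y = 6 * X[:, 10] - 6 * X[:, 30] + rng.normal(0, 2, 250)
        sel = RandomForestSNPSelector(config=RFConfig(n_estimators=120, seed=0),
                                      boruta_max_iter=12, shap_sample=120).fit(X, y)
        assert sel.cross_set_ <= sel.union_set_
        assert {10, 30} <= sel.union_set_
        frame = sel.report_frame()
        assert len(frame) == 40
        assert set(frame.columns) >= {"gini", "shap", "boruta_decision"}
        np.testing.assert_array_equal(sel.get_support("cross"),
                                      np.sort(np.array(sorted(sel.cross_set_))))

    def test_sklearn_param_interface(self):
        sel = RandomForestSNPSelector(boruta_max_iter=11)
        assert sel.get_params()["boruta_max_iter"] == 11
        sel.set_params(boruta_alpha=0.01)
        assert sel.boruta_alpha == 0.01
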