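"""Metrics, hyperparameter grids, grid-search CV, stacking, ablation."""

import numpy as np
import pytest
from sklearn.metrics import recall_score

from otva.modeling import (
    ConfusionMatrix,
    accuracy,
    enumerate_grid,
    fit_predict,
    grid_search_cv,
    grid_size,
    macro_average_sensitivity,
    redundancy_ablation,
    stack_experiment_c,
)
from otva.scenarios import FeatureTable


def separable_table(n=60, seed=0, n_features=3, ids_prefix="p"):
    """Linearly separable fixture: feature 0 encodes the class exactly."""
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2).astype(int)
    X = rng.normal(0, 0.05, size=(n, n_features))
    X[:, 0] += y * 2.0
    ids = tuple(f"{ids_prefix}{i}" for i in range(n))
    return FeatureTable(ids, tuple(f"f{i}" for i in range(n_features)), X, y)


class TestMetrics:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix(tp=10, fn=0, tn=5, fp=0)
        assert macro_average_sensitivity(cm) == 1.0
        assert accuracy(cm) == 1.0

    def test_degenerate_all_positive_classifier(self):
        cm = ConfusionMatrix(tp=16, fn=0, tn=0, fp=7)
        assert macro_average_sensitivity(cm) == 0.5
        assert accuracy(cm) == pytest.approx(16 / 23)

    def test_direct_arithmetic(self):
        cm = ConfusionMatrix(tp=8, fn=2, tn=3, fp=1)
        assert macro_average_sensitivity(cm) == pytest.approx(0.775)

    def test_always_wrong_classifier(self):
        assert accuracy(ConfusionMatrix(tp=0, fn=10, tn=0, fp=5)) == 0.0

    def test_absent_class_raises(self):
        with pytest.raises(ValueError, match="class absent"):
            macro_average_sensitivity(ConfusionMatrix(tp=0, fn=0, tn=5, fp=2))

    def test_matches_sklearn_macro_recall_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            tp, fn, tn, fp = rng.integers(0, 30, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            cm = ConfusionMatrix(tp=int(tp), fn=int(fn), tn=int(tn), fp=int(fp))
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            expected = recall_score(y_true, y_pred, average="macro")
            assert macro_average_sensitivity(cm) == pytest.approx(expected, abs=1e-12)


class TestGrids:
    # hand counts: SVM 3 nu x 2 gamma x (2 plain kernels + 5 degrees x 3
    # coef0 for poly) = 102; MLP 2*3*3*4 = 72; forests 5*10*10 = 500
    @pytest.mark.parametrize(
        "family,expected",
        [("svm", 102), ("mlp", 72), ("random_forest", 500), ("extra_trees", 500)],
    )
    def test_full_grid_sizes_match_hand_counts(self, family, expected):
        assert sum(1 for _ in enumerate_grid(family, "full")) == expected
        assert grid_size(family, "full") == expected

    def test_xgboost_grid_size_arithmetic(self):
        assert grid_size("xgboost", "full") == 10 * 11 * 6 * 41 * 41 * 5

    def test_svm_nu_candidates(self):
        nus = {p["nu"] for p in enumerate_grid("svm", "full")}
        assert nus == {0.4, 0.5, 0.6}

    def test_degree_only_for_poly_kernel(self):
        for p in enumerate_grid("svm", "full"):
            assert ("degree" in p) == (p["kernel"] == "poly")

    def test_fast_preset_is_small(self):
        for family in ("svm", "mlp", "random_forest", "extra_trees", "xgboost"):
            assert grid_size(family, "fast") <= 8

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            list(enumerate_grid("deep_net"))


class TestGridSearchCV:
    def test_single_combination_is_returned(self):
        table = separable_table()
        grid = [{"max_depth": 3, "subsample": 1.0}]
        res = grid_search_cv(table, "xgboost", grid=grid, seed=0)
        assert res.best_params == grid[0]
        assert res.n_evaluated == 1

    def test_separable_fixture_reaches_perfect_cv_ma(self):
        table = separable_table(n=80)
        res = grid_search_cv(table, "random_forest", preset="fast", seed=0)
        assert res.best_cv_ma == 1.0

    def test_class_rarer_than_folds_rejected(self):
        table = separable_table(n=60)
        y = np.zeros(60, dtype=int)
        y[:3] = 1
        bad = FeatureTable(table.patient_ids, table.feature_names, table.X, y)
        with pytest.raises(ValueError, match="fold"):
            grid_search_cv(bad, "xgboost", preset="fast", seed=0)

    def test_deterministic_under_seed(self):
        table = separable_table(n=50, seed=3)
        r1 = grid_search_cv(table, "xgboost", preset="fast", seed=5)
        r2 = grid_search_cv(table, "xgboost", preset="fast", seed=5)
        assert r1.best_params == r2.best_params
        assert r1.fold_ma == r2.fold_ma


class TestFitPredict:
    @pytest.mark.parametrize("family,params", [
        ("random_forest", {"n_estimators": 50}),
        ("extra_trees", {"n_estimators": 50}),
        ("xgboost", {"max_depth": 3}),
    ])
    def test_tree_families_memorize_separable_fixture(self, family, params):
        table = separable_table()
        preds, probs, _ = fit_predict(table, table, family, params, seed=0)
        assert np.array_equal(preds, table.y)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_constant_features_give_prevalence_probability(self):
        rng = np.random.default_rng(0)
        y = (rng.random(200) < 0.7).astype(int)
        X = np.ones((200, 3))
        table = FeatureTable(
            tuple(f"p{i}" for i in range(200)), ("a", "b", "c"), X, y
        )
        _, probs, _ = fit_predict(table, table, "random_forest",
                                  {"n_estimators": 100}, seed=0)
        assert np.allclose(probs, y.mean(), atol=0.05)

    def test_same_seed_identical_predictions(self):
        table = separable_table(n=70, seed=2)
        p1, _, _ = fit_predict(table, table, "extra_trees", {"n_estimators": 30}, seed=9)
        p2, _, _ = fit_predict(table, table, "extra_trees", {"n_estimators": 30}, seed=9)
        np.testing.assert_array_equal(p1, p2)

    def test_mismatched_columns_rejected(self):
        train = separable_table()
        test = FeatureTable(train.patient_ids, ("x", "y", "z"), train.X, train.y)
        with pytest.raises(ValueError, match="different feature columns"):
            fit_predict(train, test, "xgboost", {}, seed=0)


class TestStacking:
    def _fitted_a(self):
        table = separable_table(n=40, n_features=5)
        _, _, model = fit_predict(table, table, "xgboost", {"max_depth": 2}, seed=0)
        return model, table

    def test_binary_mode_appends_binary_column(self):
        model, a_table = self._fitted_a()
        b_table = separable_table(n=40, seed=1)
        stacked = stack_experiment_c(model, a_table, b_table, "binary")
        assert stacked.feature_names[-1] == "a_prediction"
        assert set(np.unique(stacked.X[:, -1])) <= {0.0, 1.0}

    def test_probability_mode_appends_unit_interval_column(self):
        model, a_table = self._fitted_a()
        b_table = separable_table(n=40, seed=1)
        stacked = stack_experiment_c(model, a_table, b_table, "probability")
        col = stacked.X[:, -1]
        assert stacked.feature_names[-1] == "a_prob_rvot"
        assert np.all((col >= 0) & (col <= 1))

    def test_extra_decile_columns_counted(self):
        model, a_table = self._fitted_a()
        b_table = separable_table(n=40, seed=1)
        extras = a_table  # 5 columns
        stacked = stack_experiment_c(model, a_table, b_table, "probability", extras)
        assert len(stacked.feature_names) == len(b_table.feature_names) + 6

    def test_patient_mismatch_rejected(self):
        model, a_table = self._fitted_a()
        b_table = separable_table(n=40, seed=1, ids_prefix="q")
        with pytest.raises(ValueError, match="patient sets"):
            stack_experiment_c(model, a_table, b_table, "binary")


class TestRedundancyAblation:
    def _b4_like(self, n, seed, informative_vptc):
        rng = np.random.default_rng(seed)
        y = (np.arange(n) % 2).astype(int)
        base = rng.normal(size=(n, 4))
        vptc = np.zeros((n, 6))
        if informative_vptc:
            vptc[np.arange(n), np.where(y == 1, 4, 1)] = 1.0  # class in transition
        else:
            vptc[np.arange(n), rng.integers(0, 6, n)] = 1.0
        names = ("norm_age", "sex", "hta", "v3_amp") + tuple(f"ptc_v{i}" for i in range(1, 7))
        return FeatureTable(tuple(f"p{i}" for i in range(n)), names,
                            np.hstack([base, vptc]), y)

    def test_informative_features_lift_performance(self):
        train = self._b4_like(120, 0, True)
        test = self._b4_like(60, 1, True)
        a_pred_train, a_pred_test = train.y.copy(), test.y.copy()  # perfect A model
        df = redundancy_ablation(train, test, a_pred_train, a_pred_test,
                                 family="xgboost", seed=0)
        assert len(df) == 4
        assert set(df.configuration) == {"neither", "vptc_only", "a_prediction_only", "both"}
        d = df.set_index("configuration").delta_macro_sensitivity
        assert d["vptc_only"] > 0 and d["a_prediction_only"] > 0

    def test_uninformative_features_leave_metrics_flat(self):
        deltas = []
        for seed in range(4):
            train = self._b4_like(120, seed, False)
            test = self._b4_like(60, 100 + seed, False)
            rng = np.random.default_rng(seed)
            df = redundancy_ablation(
                train, test, rng.integers(0, 2, 120), rng.integers(0, 2, 60),
                family="xgboost", seed=seed,
            )
            deltas.append(df.delta_macro_sensitivity.abs().max())
        assert np.mean(deltas) < 0.15  # pure noise: no systematic lift
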