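"""GBT fitting, evaluation metrics, TreeSHAP attribution and thresholds."""

import json

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from ecocoupling import drivers as drv

from oracles import bf_shapley

SMALL_GRID = {"max_depth": [3], "learning_rate": [0.1],
              "n_estimators": [100], "reg_lambda": [1.0]}


def make_units(n=200, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "x1": rng.uniform(-2, 2, n),
        "x2": rng.uniform(-2, 2, n),
        "x3": rng.uniform(-2, 2, n),
    })
    df["y"] = np.sin(df["x1"]) + noise * rng.standard_normal(n)
    return df


class TestAssembleDesign:
    def test_split_sizes_and_determinism(self):
        units = make_units(100)
        dm = drv.assemble_design(units, ["x1", "x2"], "y", seed=5)
        assert (len(dm.train_idx), len(dm.test_idx)) == (70, 30)
        dm2 = drv.assemble_design(units, ["x1", "x2"], "y", seed=5)
        np.testing.assert_array_equal(dm.train_idx, dm2.train_idx)

    def test_incomplete_units_dropped_and_counted(self):
        units = make_units(100)
        units.loc[[3, 7, 11], "x2"] = np.nan
        dm = drv.assemble_design(units, ["x1", "x2"], "y")
        assert dm.n_dropped == 3
        assert len(dm.X) == 97

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            drv.assemble_design(make_units(25), ["x1"], "y")


class TestEvalMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        assert drv.eval_metrics(y, y) == (1.0, 0.0, 0.0)

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([0.0, 1.0, 2.0])
        r2, *_ = drv.eval_metrics(y, np.full(3, 1.0))
        assert r2 == pytest.approx(0.0)

    def test_hand_worked_example(self):
        y = np.array([0.0, 1.0, 2.0])
        yhat = np.array([0.0, 1.0, 4.0])
        r2, rmse, mae = drv.eval_metrics(y, yhat)
        assert r2 == pytest.approx(-1.0)
        assert rmse == pytest.approx(np.sqrt(4 / 3))
        assert mae == pytest.approx(2 / 3)

    def test_matches_direct_formulas_on_random_vectors(self):
        rng = np.random.default_rng(0)
        y, yhat = rng.normal(size=100), rng.normal(size=100)
        r2, rmse, mae = drv.eval_metrics(y, yhat)
        assert r2 == pytest.approx(
            1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2),
            abs=1e-12)
        assert rmse == pytest.approx(np.sqrt(np.mean((y - yhat) ** 2)),
                                     abs=1e-12)
        assert mae == pytest.approx(np.mean(np.abs(y - yhat)), abs=1e-12)
        assert mae <= rmse

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            drv.eval_metrics(np.ones(5), np.arange(5.0))


class TestFitGbt:
    def test_noiseless_monotone_function_is_learned(self):
        dm = drv.assemble_design(make_units(400), ["x1", "x2", "x3"], "y",
                                 seed=0)
        _, report = drv.fit_gbt(dm, param_grid=SMALL_GRID, seed=0)
        assert report.r2_test > 0.95

    def test_pure_noise_has_low_test_r2(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            units = make_units(150, seed=seed)
            units["y"] = rng.standard_normal(len(units))
            dm = drv.assemble_design(units, ["x1", "x2", "x3"], "y", seed=seed)
            _, report = drv.fit_gbt(dm, param_grid=SMALL_GRID, seed=seed)
            hits += report.r2_test < 0.2
        assert hits >= 18

    def test_grid_search_returns_grid_member(self):
        grid = {"max_depth": [2, 3], "n_estimators": [50],
                "learning_rate": [0.1], "reg_lambda": [1.0]}
        dm = drv.assemble_design(make_units(120), ["x1", "x2"], "y", seed=1)
        _, report = drv.fit_gbt(dm, param_grid=grid, seed=1)
        assert report.best_params["max_depth"] in (2, 3)

    def test_degenerate_target_rejected(self):
        units = make_units(60)
        units["y"] = 1.0
        dm = drv.assemble_design(units, ["x1"], "y")
        with pytest.raises(ValueError):
            drv.fit_gbt(dm, param_grid=SMALL_GRID)


class TestShapAttribution:
    def _fit(self, n=150, features=("x1", "x2", "x3"), seed=0):
        dm = drv.assemble_design(make_units(n, seed=seed), list(features),
                                 "y", seed=seed)
        model, _ = drv.fit_gbt(dm, param_grid=SMALL_GRID, seed=seed)
        return model, dm

    def test_local_accuracy(self):
        model, dm = self._fit()
        res = drv.shap_attribution(model, dm.X)
        total = res.base_value + res.phi.sum(axis=1).to_numpy()
        np.testing.assert_allclose(total, res.predictions, atol=1e-4)

    def test_single_feature_model_owns_all_importance(self):
        model, dm = self._fit(features=("x1",))
        res = drv.shap_attribution(model, dm.X)
        assert res.importance_share()["x1"] == pytest.approx(100.0)

    def test_importance_shares_sum_to_100(self):
        model, dm = self._fit()
        assert res_sum(drv.shap_attribution(model, dm.X)) == pytest.approx(100.0)

    def test_symmetric_features_share_importance(self):
        rng = np.random.default_rng(3)
        n = 600
        units = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        units["y"] = units["a"] + units["b"]
        dm = drv.assemble_design(units, ["a", "b"], "y", seed=3)
        model, _ = drv.fit_gbt(dm, param_grid=SMALL_GRID, seed=3)
        share = drv.shap_attribution(model, dm.X).importance_share()
        assert abs(share["a"] - share["b"]) < 10.0

    def test_tiny_tree_matches_exhaustive_shapley_enumeration(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, size=(80, 2))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        model = xgb.XGBRegressor(n_estimators=3, max_depth=2, learning_rate=0.5,
                                 base_score=0.5, n_jobs=1, random_state=0)
        model.fit(X, y)
        Xdf = pd.DataFrame(X, columns=["f0", "f1"])
        res = drv.shap_attribution(model, Xdf)
        cfg = json.loads(model.get_booster().save_config())
        base = float(cfg["learner"]["learner_model_param"]["base_score"])
        for row in [0, 7, 33]:
            phi = bf_shapley(model, X[row], n_features=2, base_score=base)
            np.testing.assert_allclose(res.phi.iloc[row].to_numpy(), phi,
                                       atol=1e-5)

    def test_feature_count_mismatch_rejected(self):
        model, dm = self._fit()
        with pytest.raises(ValueError):
            drv.shap_attribution(model, dm.X[["x1", "x2"]])


def res_sum(res: drv.ShapResult) -> float:
    return float(res.importance_share().sum())


class TestDependenceThreshold:
    def _shap_for(self, f, n=800, seed=0, noise=0.05):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, n)
        other = rng.uniform(0, 10, n)
        units = pd.DataFrame({"x": x, "z": other})
        units["y"] = f(x) + noise * rng.standard_normal(n)
        dm = drv.assemble_design(units, ["x", "z"], "y", seed=seed)
        model, _ = drv.fit_gbt(dm, param_grid=SMALL_GRID, seed=seed)
        return drv.shap_attribution(model, dm.X)

    def test_kinked_response_crossing_near_breakpoint(self):
        res = self._shap_for(lambda x: np.where(x < 6, -0.2 * (x - 6),
                                                -1.0 * (x - 6)))
        th = drv.dependence_threshold(res, "x", seed=0)
        assert th.has_threshold
        assert th.direction == "+->-"
        assert th.breakpoint == pytest.approx(6.0, abs=1.0)

    def test_monotone_positive_effect_has_no_threshold(self):
        res = self._shap_for(lambda x: 0.5 * x + 2.0)
        th = drv.dependence_threshold(res, "x", seed=0)
        # a strictly increasing effect crosses zero once, upward
        assert th.direction in (None, "-->+")

    def test_strictly_positive_phi_yields_no_threshold(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 10, 300))
        res = drv.ShapResult(
            base_value=0.0,
            phi=pd.DataFrame({"x": np.full(300, 0.3)}),
            predictions=np.full(300, 0.3),
            feature_values=pd.DataFrame({"x": x}))
        th = drv.dependence_threshold(res, "x", n_boot=10, seed=0)
        assert not th.has_threshold

    def test_bootstrap_interval_deterministic_under_seed(self):
        res = self._shap_for(lambda x: np.where(x < 5, 0.5, -0.5))
        a = drv.dependence_threshold(res, "x", seed=11)
        b = drv.dependence_threshold(res, "x", seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.breakpoint <= a.ci_high

    def test_too_few_distinct_values_rejected(self):
        res = drv.ShapResult(
            base_value=0.0, phi=pd.DataFrame({"x": np.ones(40)}),
            predictions=np.ones(40),
            feature_values=pd.DataFrame({"x": np.arange(40) % 10}))
        with pytest.raises(ValueError):
            drv.dependence_threshold(res, "x")
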