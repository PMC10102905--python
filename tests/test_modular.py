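import numpy as np
import pandas as pd
import pytest

from tcimpact.modular import (
    BayesianModularRegression,
    PredictiveModelSpec,
    crossvalidate_model_menu,
    default_knots,
    fit_modular,
    fit_plugin,
    load_modular_fit,
    predict_new,
    rcs_basis,
    save_modular_fit,
)


def _rcs_reference(x, knots):
    """Independent textbook evaluation of the restricted cubic spline terms."""
    knots = np.sort(np.asarray(knots, dtype=float))
    k = len(knots)
    out = [np.asarray(x, dtype=float)]
    d = lambda v, t: np.where(v > t, (v - t) ** 3, 0.0)
    for j in range(k - 2):
        term = (
            d(x, knots[j])
            - d(x, knots[k - 2]) * (knots[k - 1] - knots[j]) / (knots[k - 1] - knots[k - 2])
            + d(x, knots[k - 1]) * (knots[k - 2] - knots[j]) / (knots[k - 1] - knots[k - 2])
        )
        out.append(term / (knots[k - 1] - knots[0]) ** 2)
    return np.column_stack(out)


class TestSplineBasis:
    def test_matches_reference_formula_at_and_between_knots(self):
        knots = np.array([18.0, 24.0, 33.0, 47.0])
        x = np.concatenate([knots, [15.0, 20.5, 29.9, 40.0, 55.0]])
        np.testing.assert_allclose(rcs_basis(x, knots), _rcs_reference(x, knots), rtol=1e-12)

    def test_linear_below_first_knot(self):
        knots = [10.0, 20.0, 30.0, 40.0]
        x = np.linspace(0, 9, 25)
        B = rcs_basis(x, knots)
        np.testing.assert_allclose(B[:, 0], x)
        np.testing.assert_allclose(B[:, 1:], 0.0)

    def test_linear_beyond_last_knot(self):
        knots = [10.0, 20.0, 30.0, 40.0]
        x = np.linspace(45, 60, 30)
        B = rcs_basis(x, knots)
        # natural spline: every column is affine in x beyond the boundary
        for j in range(B.shape[1]):
            slope = np.diff(B[:, j]) / np.diff(x)
            np.testing.assert_allclose(slope, slope[0], rtol=1e-8)

    def test_too_few_knots_or_constant_x_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis([1.0, 2.0], [5.0, 5.0])
        with pytest.raises(ValueError):
            default_knots(np.full(10, 3.0))


def _toy_X(n, seed=0, columns=("max_windspeed", "year", "z")):
    rng = np.random.default_rng(seed)
    data = {
        "max_windspeed": rng.uniform(18, 50, n),
        "year": rng.integers(1999, 2016, n).astype(float),
        "z": rng.standard_normal(n),
    }
    return pd.DataFrame({c: data[c] for c in columns})


class TestModularFit:
    def test_noiseless_linear_recovery(self):
        X = _toy_X(40, seed=1, columns=("max_windspeed", "z"))
        y = 3.0 + 0.8 * X["max_windspeed"].to_numpy() - 2.0 * X["z"].to_numpy()
        draws = np.tile(y, (300, 1))
        spec = PredictiveModelSpec(spline_features=())
        fit = fit_modular(draws, X, spec, seed=0)
        # coefficients on the standardized design: slope * sd(x)
        target = {
            "max_windspeed": 0.8 * X["max_windspeed"].std(ddof=0),
            "z": -2.0 * X["z"].std(ddof=0),
        }
        summ = fit.coefficient_summary().set_index("term")
        for term, value in target.items():
            assert summ.loc[term, "mean"] == pytest.approx(value, abs=0.01)
        # residual scale is near zero (bounded away only by prior shrinkage),
        # so coefficient draws concentrate tightly
        assert fit.coef_draws_.std(axis=0).max() < 0.15

    def test_intercept_only_centers_on_draw_means(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(10.0, 2.0, size=(400, 25))
        X = pd.DataFrame(index=range(25))
        fit = BayesianModularRegression(features=(), method="modular", random_state=0).fit(
            X, draws
        )
        assert fit.coef_draws_.shape == (400, 1)
        assert fit.coef_draws_.mean() == pytest.approx(draws.mean(), abs=0.2)

    def test_exposure_order_invariance(self):
        X = _toy_X(30, seed=4, columns=("max_windspeed", "z"))
        rng = np.random.default_rng(5)
        draws = rng.normal(size=(100, 30))
        spec = PredictiveModelSpec(spline_features=())
        a = fit_modular(draws, X, spec, seed=9)
        perm = np.random.default_rng(0).permutation(30)
        b = fit_modular(draws[:, perm], X.iloc[perm].reset_index(drop=True), spec, seed=9)
        np.testing.assert_allclose(a.coef_draws_, b.coef_draws_, rtol=1e-8)

    def test_one_beta_draw_per_causal_draw(self):
        X = _toy_X(20, seed=6)
        draws = np.random.default_rng(1).normal(size=(123, 20))
        fit = fit_modular(draws, X, seed=0)
        assert fit.posterior_.M == 123

    def test_misalignment_and_rank_deficiency_rejected(self):
        X = _toy_X(20, seed=7, columns=("max_windspeed", "z"))
        with pytest.raises(ValueError):
            fit_modular(np.zeros((10, 19)), X, PredictiveModelSpec(spline_features=()))
        X2 = X.copy()
        X2["dup"] = X2["max_windspeed"]
        with pytest.raises(ValueError):
            fit_modular(np.zeros((10, 20)), X2, PredictiveModelSpec(spline_features=()))


class TestPluginComparison:
    def test_degenerate_first_stage_coincides(self):
        """Zero first-stage variance: modular and plug-in posteriors agree in
        distribution."""
        X = _toy_X(35, seed=8, columns=("max_windspeed", "z"))
        rng = np.random.default_rng(9)
        y = 1.0 + 0.5 * X["max_windspeed"].to_numpy() + rng.normal(0, 3.0, 35)
        draws = np.tile(y, (500, 1))
        spec = PredictiveModelSpec(spline_features=())
        mod = fit_modular(draws, X, spec, seed=1)
        plug = fit_plugin(y, X, spec, draws=500, seed=2)
        np.testing.assert_allclose(
            mod.coef_draws_.mean(axis=0), plug.coef_draws_.mean(axis=0), atol=0.25
        )
        np.testing.assert_allclose(
            mod.coef_draws_.std(axis=0), plug.coef_draws_.std(axis=0), rtol=0.25
        )

    def test_first_stage_noise_widens_modular_intervals(self):
        X = _toy_X(40, seed=10, columns=("max_windspeed", "z"))
        rng = np.random.default_rng(11)
        y = 2.0 + 1.0 * X["max_windspeed"].to_numpy()
        draws = y[None, :] + rng.normal(0, 25.0, size=(500, 40))
        spec = PredictiveModelSpec(spline_features=())
        mod = fit_modular(draws, X, spec, seed=1)
        plug = fit_plugin(draws.mean(axis=0), X, spec, draws=500, seed=2)
        w = lambda f: np.diff(np.quantile(f.coef_draws_[:, 1], [0.025, 0.975]))[0]
        assert w(mod) > w(plug)

    def test_identical_seeds_identical_draws(self):
        X = _toy_X(30, seed=12)
        y = np.random.default_rng(13).normal(size=30)
        a = fit_plugin(y, X, draws=50, seed=5)
        b = fit_plugin(y, X, draws=50, seed=5)
        np.testing.assert_array_equal(a.coef_draws_, b.coef_draws_)


class TestPrediction:
    def test_interpolates_noiseless_training_point(self):
        X = _toy_X(40, seed=14, columns=("max_windspeed", "z"))
        y = -1.0 + 0.6 * X["max_windspeed"].to_numpy() + 1.5 * X["z"].to_numpy()
        fit = fit_modular(np.tile(y, (400, 1)), X, PredictiveModelSpec(spline_features=()), seed=0)
        preds = predict_new(fit, X.iloc[[3]])
        assert preds[0].mean == pytest.approx(y[3], abs=0.1)
        assert preds[0].draws.shape == (400,)

    def test_batch_equals_concatenated_singles_in_mean(self):
        X = _toy_X(30, seed=15, columns=("max_windspeed", "z"))
        y = 0.3 * X["max_windspeed"].to_numpy()
        fit = fit_modular(np.tile(y, (200, 1)), X, PredictiveModelSpec(spline_features=()), seed=0)
        batch = fit.predict(X.iloc[:5])
        lin_only = np.array([fit.predict(X.iloc[[j]])[0] for j in range(5)])
        np.testing.assert_allclose(batch, lin_only, atol=0.2)

    def test_out_of_schema_features_rejected(self):
        X = _toy_X(30, seed=16, columns=("max_windspeed", "z"))
        fit = fit_modular(np.zeros((10, 30)), X, PredictiveModelSpec(spline_features=()), seed=0)
        with pytest.raises(ValueError):
            fit.predict(pd.DataFrame({"max_windspeed": [20.0]}))

    def test_roundtrip_serialization(self, tmp_path):
        X = _toy_X(30, seed=17)
        y = np.random.default_rng(18).normal(size=(50, 30))
        fit = fit_modular(y, X, seed=0)
        save_modular_fit(fit, tmp_path)
        back = load_modular_fit(tmp_path)
        np.testing.assert_allclose(back.coef_draws_, fit.coef_draws_)
        np.testing.assert_allclose(
            back.predict(X.iloc[:3]), fit.predict(X.iloc[:3]), atol=1e-8
        )


class TestCrossValidation:
    def test_true_model_wins_majority_of_seeds(self):
        wins = 0
        spec_true = PredictiveModelSpec(
            features=("max_windspeed", "z"), spline_features=(), name="true"
        )
        spec_null = PredictiveModelSpec(features=(), spline_features=(), name="intercept")
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = _toy_X(80, seed=seed, columns=("max_windspeed", "z"))
            y = 0.8 * X["max_windspeed"].to_numpy() - 3.0 * X["z"].to_numpy() + rng.normal(0, 2, 80)
            table = crossvalidate_model_menu([spec_null, spec_true], y, X, folds=5, seed=seed)
            wins += table.iloc[0]["name"] == "true"
        assert wins >= 16

    def test_duplicate_candidates_tie_exactly(self):
        X = _toy_X(30, seed=19, columns=("max_windspeed", "z"))
        y = np.random.default_rng(20).normal(size=30)
        spec = PredictiveModelSpec(spline_features=(), name="m")
        table = crossvalidate_model_menu([spec, spec], y, X, folds=3, seed=1)
        assert table["mean_mse"].iloc[0] == table["mean_mse"].iloc[1]

    def test_leave_one_out_matches_hand_computation(self):
        """Intercept-only LOO on n=3: the held-out prediction is the shrunken
        training mean sum(y_train) / (2 + 1/tau^2)."""
        y = np.array([1.0, 2.0, 6.0])
        X = pd.DataFrame(index=range(3))
        spec = PredictiveModelSpec(features=(), spline_features=(), coef_prior_scale=10.0)
        table = crossvalidate_model_menu([spec, spec], y, X, folds=3, seed=0)
        shrink = 2.0 + 1.0 / 100.0
        errs = [(y[i] - (y.sum() - y[i]) / shrink) ** 2 for i in range(3)]
        assert table["mean_mse"].iloc[0] == pytest.approx(np.mean(errs), rel=1e-9)
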