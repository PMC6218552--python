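"""Sparse selection and weighted least squares: exact small-sample behaviour."""

import numpy as np
import pandas as pd
import pytest

from semlseffect import (default_config, fit_weighted_ols, load_model_card,
                         predict_with_interval, save_model_card,
                         select_features, standardized_effects)
from semlseffect.regression import OutcomeModel, _weighted_lasso_path


def _signal_data(rng, n=200, p=6, informative=2, sigma=0.5, weights=False):
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:informative] = 3.0
    y = 1.0 + X @ beta + sigma * rng.standard_normal(n)
    w = rng.uniform(0.5, 2.0, n) if weights else None
    names = [f"x{j}" for j in range(p)]
    return pd.DataFrame(X, columns=names), y, w, names


class TestFitWeightedOls:
    def test_hand_solved_normal_equations(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        model = fit_weighted_ols(X, [0.0, 1.0, 4.0])
        assert model.coefficient("x") == pytest.approx(2.0)
        assert model.intercept == pytest.approx(-1 / 3)

    def test_duplicated_rows_with_half_weight_match_original(self, rng):
        X, y, _, _ = _signal_data(rng, n=40)
        base = fit_weighted_ols(X, y)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.concatenate([y, y])
        w2 = np.full(80, 0.5)
        doubled = fit_weighted_ols(X2, y2, w2)
        assert np.allclose(doubled.coefficients, base.coefficients)
        assert doubled.intercept == pytest.approx(base.intercept)

    def test_covariance_symmetric_psd(self, rng):
        X, y, w, _ = _signal_data(rng, weights=True)
        model = fit_weighted_ols(X, y, w)
        assert np.allclose(model.covariance, model.covariance.T)
        assert np.linalg.eigvalsh(model.covariance).min() >= -1e-12

    def test_rank_deficient_design_names_columns(self, rng):
        X, y, _, _ = _signal_data(rng, n=30, p=3)
        X["x_dup"] = X["x0"]
        with pytest.raises(np.linalg.LinAlgError, match="x_dup|x0"):
            fit_weighted_ols(X, y)

    def test_underdetermined_rejected(self, rng):
        X, y, _, _ = _signal_data(rng, n=5, p=6)
        with pytest.raises(ValueError, match="more rows"):
            fit_weighted_ols(X, y)

    def test_robust_covariance_close_to_classical_when_homoscedastic(self, rng):
        X, y, _, _ = _signal_data(rng, n=2000, sigma=1.0)
        classical = fit_weighted_ols(X, y)
        robust = fit_weighted_ols(X, y, robust=True)
        assert np.allclose(robust.coefficients, classical.coefficients)
        ratio = np.diag(robust.covariance) / np.diag(classical.covariance)
        assert np.all((ratio > 0.8) & (ratio < 1.25))


class TestSelectFeatures:
    def test_tiny_penalty_keeps_all_informative_design(self, rng):
        X, y, _, names = _signal_data(rng, n=300, sigma=0.1)
        res = select_features(X, y, penalty_grid=np.array([1e-10]), seed=0)
        assert res.selected_features == names

    def test_huge_penalty_empties_selection(self, rng):
        X, y, _, _ = _signal_data(rng)
        res = select_features(X, y, penalty_grid=np.array([1e6]), seed=0)
        assert res.selected_features == []

    def test_one_se_rule_drops_noise_keeps_signal(self, rng):
        X, y, _, _ = _signal_data(rng, n=500, informative=2, sigma=0.5)
        res = select_features(X, y, seed=0)
        assert set(res.selected_features) >= {"x0", "x1"}
        assert len(res.selected_features) <= 4
        assert res.chosen_penalty in res.penalties

    def test_selected_set_shrinks_along_path(self, rng):
        X, y, _, _ = _signal_data(rng, n=300)
        Xm = X.to_numpy()
        Xs = (Xm - Xm.mean(0)) / Xm.std(0)
        alphas = np.geomspace(3.0, 1e-3, 40)
        coefs, _ = _weighted_lasso_path(Xs, y, np.ones(len(y)), alphas)
        sizes = (coefs != 0).sum(axis=0)  # alphas descending -> sizes grow
        assert np.all(np.diff(sizes) >= 0)

    def test_constant_feature_excluded_with_warning(self, rng):
        X, y, _, _ = _signal_data(rng)
        X["flat"] = 1.0
        with pytest.warns(RuntimeWarning, match="flat"):
            res = select_features(X, y, seed=0)
        assert "flat" not in res.selected_features
        assert res.dropped_constant == ["flat"]

    def test_fewer_rows_than_folds_rejected(self, rng):
        X, y, _, _ = _signal_data(rng, n=8)
        with pytest.raises(ValueError, match="n_folds"):
            select_features(X[:8], y[:8], n_folds=10)


class TestStandardizedEffects:
    def test_effect_is_coefficient_times_training_sd(self):
        model = OutcomeModel(
            arm="surgery", features=["gdi"], coefficients=np.array([0.27]),
            intercept=48.03, covariance=np.diag([0.0, 0.032**2]),
            residual_variance=0.0, feature_means=np.array([70.0]),
            feature_sds=np.array([9.5556]), n_obs=100)
        (eff,) = standardized_effects(model)
        assert eff.effect == pytest.approx(2.58, abs=0.01)
        assert eff.effect_sd == pytest.approx(9.5556 * 0.032)

    def test_zero_coefficient_zero_effect(self):
        model = OutcomeModel(
            arm="control", features=["x"], coefficients=np.array([0.0]),
            intercept=0.0, covariance=np.zeros((2, 2)), residual_variance=1.0,
            feature_means=np.array([5.0]), feature_sds=np.array([123.0]),
            n_obs=10)
        assert standardized_effects(model)[0].effect == 0.0

    def test_balanced_binary_feature_halves_coefficient(self, rng):
        x = np.tile([0.0, 1.0], 50)
        y = 2.0 + 4.0 * x
        model = fit_weighted_ols(pd.DataFrame({"flag": x}),
                                 y + 0.01 * rng.standard_normal(100))
        (eff,) = standardized_effects(model)
        assert eff.effect == pytest.approx(0.5 * model.coefficient("flag"),
                                           rel=1e-6)


class TestPredictWithInterval:
    def _zero_feature_control_model(self):
        cfg = default_config()
        feats = list(cfg.outcome_coefficients_control)
        k = len(feats)
        return OutcomeModel(
            arm="control", features=feats,
            coefficients=np.array([cfg.outcome_coefficients_control[f]
                                   for f in feats]),
            intercept=cfg.outcome_intercept_control,
            covariance=np.zeros((k + 1, k + 1)), residual_variance=0.0,
            feature_means=np.zeros(k), feature_sds=np.ones(k), n_obs=100)

    def test_all_zero_features_give_intercept(self):
        model = self._zero_feature_control_model()
        x = {f: 0.0 for f in model.features}
        point, lower, upper = predict_with_interval(model, x)
        assert point == pytest.approx(19.99)
        assert (lower, upper) == (point, point)  # degenerate: no uncertainty

    def test_hand_computed_half_width(self):
        model = OutcomeModel(
            arm="surgery", features=["x"], coefficients=np.array([2.0]),
            intercept=1.0, covariance=np.array([[0.0, 0.0], [0.0, 0.09]]),
            residual_variance=4.0, feature_means=np.array([0.0]),
            feature_sds=np.array([1.0]), n_obs=50)
        point, lower, upper = predict_with_interval(model, {"x": 3.0}, level=0.95)
        assert point == pytest.approx(7.0)
        half = 1.959963985 * np.sqrt(9 * 0.09 + 4.0)
        assert upper - point == pytest.approx(half, rel=1e-6)
        assert point - lower == pytest.approx(half, rel=1e-6)

    def test_missing_feature_named(self):
        model = self._zero_feature_control_model()
        with pytest.raises(KeyError, match="gdi"):
            predict_with_interval(model, {"smc_score": 0.0})

    def test_model_card_roundtrip(self, tmp_path, rng):
        X, y, w, _ = _signal_data(rng, weights=True)
        model = fit_weighted_ols(X, y, w, arm="surgery")
        path = tmp_path / "card.yaml"
        save_model_card(model, path)
        back = load_model_card(path)
        x = {f: 1.0 for f in model.features}
        assert predict_with_interval(back, x) == pytest.approx(
            predict_with_interval(model, x))
        assert back.arm == "surgery"
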