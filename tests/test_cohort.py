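"""Synthetic cohort generator: configuration, counts, confounding, truth."""

import io

import numpy as np
import pandas as pd
import pytest

from semlseffect import (default_config, fit_weighted_ols, generate_cohort, r2,
                         true_effect, write_cohort)
from semlseffect.cohort import CONTINUOUS_FEATURES, GeneratorConfig


class TestDefaultConfig:
    def test_outcome_coefficients_are_the_published_models(self):
        cfg = default_config()
        assert cfg.outcome_coefficients_surgery["gdi"] == 0.27
        assert cfg.outcome_coefficients_surgery["speed_nd"] == 11.50
        assert cfg.outcome_coefficients_surgery["dx_quadriplegia"] == -2.01
        assert cfg.outcome_intercept_surgery == 48.03
        assert cfg.outcome_coefficients_control["gdi"] == 0.57
        assert cfg.outcome_coefficients_control["step_length_nd"] == 5.67
        assert cfg.outcome_intercept_control == 19.99

    def test_feature_sds_implied_by_standardized_effects(self):
        cfg = default_config()
        # both arms constrain the first-visit GDI spread: 2.58/0.27 ~ 5.40/0.57
        assert 5.40 / 0.57 <= cfg.feature_sds["gdi"] <= 2.58 / 0.27
        assert cfg.feature_sds["step_length_nd"] == pytest.approx(0.90 / 5.67)
        assert cfg.feature_sds["strength_score"] == pytest.approx(1.12 / 5.51)

    def test_quadriplegia_prevalence_solves_bernoulli_sd(self):
        cfg = default_config()
        p = cfg.quadriplegia_prob
        assert np.sqrt(p * (1 - p)) == pytest.approx(0.84 / 2.01, abs=1e-12)
        assert p < 0.5  # lower root
        assert p == pytest.approx(0.2255, abs=5e-4)

    def test_cohort_fractions(self):
        cfg = default_config()
        assert cfg.surgery_fraction == pytest.approx(1424 / 2333)
        assert cfg.followup_missing_prob_control == pytest.approx(1 - 582 / 909)
        assert cfg.followup_missing_prob_surgery == pytest.approx(1 - 1133 / 1424)

    def test_propensity_loads_negatively_on_gdi(self):
        cfg = default_config()
        assert cfg.propensity_coefficients["gdi"] < 0

    @pytest.mark.parametrize("override, message", [
        ({"n_limbs": 0}, "n_limbs"),
        ({"quadriplegia_prob": 1.5}, "quadriplegia_prob"),
        ({"noise_sd_surgery": -1.0}, "positive"),
        ({"surgery_fraction": 1.0}, "surgery_fraction"),
    ])
    def test_invalid_config_rejected(self, override, message):
        cfg = default_config()
        for key, value in override.items():
            setattr(cfg, key, value)
        with pytest.raises(ValueError, match=message):
            cfg.validate()

    def test_invalid_correlation_matrix_rejected(self):
        cfg = default_config()
        bad = cfg.feature_correlations.copy()
        bad[0, 1] = 0.9  # asymmetric
        cfg.feature_correlations = bad
        with pytest.raises(ValueError, match="symmetric"):
            cfg.validate()

    def test_nuisance_features_must_be_null(self):
        cfg = default_config()
        cfg.outcome_coefficients_surgery["nuisance_01"] = 1.0
        with pytest.raises(ValueError, match="nuisance"):
            cfg.validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = default_config()
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        back = GeneratorConfig.from_yaml(path)
        assert back.outcome_coefficients_surgery == cfg.outcome_coefficients_surgery
        assert np.allclose(back.feature_correlations, cfg.feature_correlations)


class TestGenerateCohort:
    def test_default_cohort_reproduces_arm_counts_exactly(self, default_cohort):
        counts = default_cohort["arm"].value_counts()
        assert counts["surgery"] == 1424
        assert counts["control"] == 909

    def test_default_cohort_reproduces_followup_counts_exactly(self, default_cohort):
        kept = default_cohort.groupby("arm")["followup_available"].sum()
        assert kept["surgery"] == 1133
        assert kept["control"] == 582

    def test_followup_gdi_present_iff_available(self, default_cohort):
        available = default_cohort["followup_available"]
        assert default_cohort.loc[available, "gdi_followup"].notna().all()
        assert default_cohort.loc[~available, "gdi_followup"].isna().all()

    def test_followup_echoes_assigned_arm_counterfactual(self, default_cohort):
        sub = default_cohort[default_cohort["followup_available"]]
        expected = np.where(sub["arm"] == "surgery",
                            sub["true_gdi_surgery"], sub["true_gdi_control"])
        assert np.allclose(sub["gdi_followup"], expected)

    def test_same_seed_is_byte_identical(self):
        cfg = default_config(n_limbs=500)
        a, b = generate_cohort(cfg, seed=3), generate_cohort(cfg, seed=3)
        assert a.equals(b)
        buf_a, buf_b = io.StringIO(), io.StringIO()
        write_cohort(a, buf_a)
        write_cohort(b, buf_b)
        assert buf_a.getvalue() == buf_b.getvalue()

    def test_confounding_direction(self, large_cohort):
        by_arm = large_cohort.groupby("arm")["gdi"].mean()
        assert by_arm["surgery"] < by_arm["control"]
        # calibrated to roughly the observed 4.4-point severity gap
        assert 2.0 < by_arm["control"] - by_arm["surgery"] < 7.0

    def test_unconfounded_assignment_balances_arms(self):
        cfg = default_config(n_limbs=20_000)
        cfg.propensity_coefficients = {}
        cfg.propensity_intercept = 0.0
        cfg.surgery_fraction = 0.5
        cohort = generate_cohort(cfg, seed=5)
        assert (cohort["arm"] == "surgery").mean() == pytest.approx(0.5, abs=1e-3)
        for feat in ("gdi", "speed_nd", "dx_quadriplegia"):
            by_arm = cohort.groupby("arm")[feat].mean()
            pooled_sd = cohort[feat].std()
            smd = (by_arm["surgery"] - by_arm["control"]) / pooled_sd
            assert abs(smd) < 0.05

    def test_mean_true_effect_matches_analytic_value(self):
        cfg = default_config(n_limbs=50_000)
        cohort = generate_cohort(cfg, seed=9)
        feats = set(cfg.outcome_coefficients_surgery) | set(
            cfg.outcome_coefficients_control)
        analytic = cfg.outcome_intercept_surgery - cfg.outcome_intercept_control
        for f in feats:
            mean = (cfg.quadriplegia_prob if f == "dx_quadriplegia"
                    else cfg.feature_means[f])
            analytic += (cfg.outcome_coefficients_surgery.get(f, 0.0)
                         - cfg.outcome_coefficients_control.get(f, 0.0)) * mean
        assert true_effect(cohort).mean() == pytest.approx(analytic, abs=0.2)

    def test_invalid_inputs_rejected(self):
        cfg = default_config()
        cfg.n_limbs = -5
        with pytest.raises(ValueError):
            generate_cohort(cfg, seed=0)


class TestTrueEffect:
    def test_true_effect_is_counterfactual_difference(self, default_cohort):
        row = default_cohort.iloc[0]
        assert true_effect(row) == pytest.approx(
            row["true_gdi_surgery"] - row["true_gdi_control"])

    def test_identical_arm_models_and_shared_noise_give_zero(self):
        record = pd.Series({"true_gdi_surgery": 77.7, "true_gdi_control": 77.7})
        assert true_effect(record) == 0.0

    def test_non_synthetic_record_rejected(self):
        with pytest.raises(ValueError, match="counterfactual"):
            true_effect(pd.Series({"gdi": 70.0, "true_gdi_surgery": 80.0}))
        with pytest.raises(ValueError, match="counterfactual"):
            true_effect(pd.Series({"true_gdi_surgery": 80.0,
                                   "true_gdi_control": np.nan}))


class TestGeneratorCalibration:
    """Regressing true outcomes on true features recovers the configuration."""

    def test_true_models_recovered_within_monte_carlo_error(self):
        cfg = default_config(n_limbs=50_000)
        cohort = generate_cohort(cfg, seed=21)
        for arm, coeffs, intercept, target_r2 in (
            ("surgery", cfg.outcome_coefficients_surgery,
             cfg.outcome_intercept_surgery, 0.41),
            ("control", cfg.outcome_coefficients_control,
             cfg.outcome_intercept_control, 0.40),
        ):
            sub = cohort[cohort["arm"] == arm]
            y = sub[f"true_gdi_{arm}"].to_numpy()
            model = fit_weighted_ols(sub[list(coeffs)], y, arm=arm)
            for j, (feat, truth) in enumerate(coeffs.items()):
                se = np.sqrt(model.covariance[j + 1, j + 1])
                assert abs(model.coefficient(feat) - truth) < 3 * se, feat
            int_se = np.sqrt(model.covariance[0, 0])
            assert abs(model.intercept - intercept) < 3 * int_se
            fitted_r2 = r2(y, model.linear_predictor(sub))
            assert fitted_r2 == pytest.approx(target_r2, abs=0.03)
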