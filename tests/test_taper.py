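"""Kozak taper equations: closed forms, fitting, DRH convenience wrapper."""

import math

import numpy as np
import pytest

from larchbiomass import (SimulationConfig, TaperParameterSet,
                          diameter_at_relative_height, fit_taper,
                          predict_diameter, simulate_stand)
from larchbiomass.reference import TAPER_PARAMS
from larchbiomass.taper import MODEL_N_PARAMS, join_sections, reference_params

KOZAK2 = reference_params("kozakII2004")


def _scalar_kozak2(b, dbh, height, t):
    """Independent scalar evaluation of the variable-exponent form."""
    b1, b2, b3, b4, b5, b6, b7, b8, b9 = b
    x = (1 - t ** (1 / 3)) / (1 - (1.3 / height) ** (1 / 3))
    e = (b4 * t**4 + b5 * math.exp(-dbh / height) + b6 * x**0.1
         + b7 / dbh + b8 * height ** (1 - t ** (1 / 3)) + b9 * x)
    return b1 * dbh**b2 * height**b3 * x**e


class TestClosedForms:
    def test_breast_height_anchor(self):
        """At h = 1.3 the base ratio is 1, so d = b1 DBH^b2 H^b3 exactly."""
        d = predict_diameter(KOZAK2, 17.4, 13.6, 1.3 / 13.6)
        b1, b2, b3 = KOZAK2.b[:3]
        assert d == pytest.approx(b1 * 17.4**b2 * 13.6**b3, rel=1e-14)
        assert d == pytest.approx(17.475716924637855, rel=1e-12)

    def test_midstem_value_frozen_against_scalar_oracle(self):
        d = predict_diameter(KOZAK2, 17.4, 13.6, 0.5)
        assert d == pytest.approx(_scalar_kozak2(KOZAK2.b, 17.4, 13.6, 0.5), rel=1e-14)
        assert d == pytest.approx(12.070170208228356, rel=1e-12)

    @pytest.mark.parametrize("model_id", sorted(MODEL_N_PARAMS))
    def test_tip_diameter_is_zero(self, model_id):
        params = reference_params(model_id)
        assert predict_diameter(params, 17.4, 13.6, 1.0) == 0.0

    @pytest.mark.parametrize("model_id", sorted(MODEL_N_PARAMS))
    def test_vectorized_matches_scalar_loop(self, model_id):
        params = reference_params(model_id)
        rng = np.random.default_rng(0)
        dbh = rng.uniform(6, 26, 10)
        height = rng.uniform(5, 20, 10)
        t = rng.uniform(0.0, 0.95, 10)
        vec = predict_diameter(params, dbh, height, t)
        scal = [predict_diameter(params, d, h, ti) for d, h, ti in zip(dbh, height, t)]
        np.testing.assert_allclose(vec, scal, rtol=1e-14)

    def test_taper_decreases_along_upper_stem(self):
        d = predict_diameter(KOZAK2, 17.4, 13.6, np.array([0.2, 0.5, 0.8]))
        assert d[0] > d[1] > d[2] > 0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            predict_diameter(KOZAK2, 17.4, 1.2, 0.5)  # below breast height
        with pytest.raises(ValueError):
            predict_diameter(KOZAK2, 17.4, 13.6, 1.5)
        with pytest.raises(ValueError):
            predict_diameter(KOZAK2, -3.0, 13.6, 0.5)


class TestParameterSet:
    def test_length_validation(self):
        with pytest.raises(ValueError, match="parameters"):
            TaperParameterSet("kozakII2004", (1.0, 2.0))
        with pytest.raises(ValueError, match="unknown taper model"):
            TaperParameterSet("kozak1999", (1.0,) * 9)
        with pytest.raises(ValueError, match="positive"):
            TaperParameterSet("kozakI2004", (-1.0, 1, 0, 0, 0, 0))


class TestDRH:
    def test_wrapper_matches_predict(self):
        a = diameter_at_relative_height(KOZAK2, 17.4, 13.6, 0.2)
        b = predict_diameter(KOZAK2, 17.4, 13.6, 0.2)
        assert a == b

    def test_monotone_between_02_and_08(self):
        assert diameter_at_relative_height(KOZAK2, 17.4, 13.6, 0.2) > \
            diameter_at_relative_height(KOZAK2, 17.4, 13.6, 0.8)

    @pytest.mark.parametrize("i", [0.0, 1.0, -0.1, 1.1])
    def test_endpoint_relative_heights_rejected(self, i):
        with pytest.raises(ValueError):
            diameter_at_relative_height(KOZAK2, 17.4, 13.6, i)


class TestFitting:
    @pytest.mark.parametrize("model_id", sorted(MODEL_N_PARAMS))
    def test_noiseless_recovery_from_perturbed_start(self, model_id):
        """With zero residual noise the generating vector is the global
        optimum; the fit must land on it from a displaced start."""
        true_b = np.asarray(TAPER_PARAMS[model_id], dtype=float)
        config = SimulationConfig(n_trees=40, seed=21, taper_model=model_id,
                                  taper_params=tuple(true_b), taper_noise_sd=0.0)
        trees, taper, _ = simulate_stand(config)
        start = TaperParameterSet(model_id, tuple(true_b * 0.9))
        fit = fit_taper(model_id, join_sections(trees, taper), start=start)
        np.testing.assert_allclose(fit.params.b, true_b, rtol=1e-6)
        assert fit.converged

    def test_duplicated_observations_leave_estimates_unchanged(self, small_stand):
        _, trees, taper, _ = small_stand
        data = join_sections(trees, taper)
        fit1 = fit_taper("kozakII2004", data)
        import pandas as pd
        fit2 = fit_taper("kozakII2004", pd.concat([data, data], ignore_index=True))
        np.testing.assert_allclose(fit2.params.b, fit1.params.b, rtol=1e-6)

    def test_refit_from_optimum_returns_optimum(self, small_stand):
        _, trees, taper, _ = small_stand
        data = join_sections(trees, taper)
        fit1 = fit_taper("kozakII2004", data)
        fit2 = fit_taper("kozakII2004", data, start=fit1.params)
        np.testing.assert_allclose(fit2.params.b, fit1.params.b, rtol=1e-5)
        assert fit2.sse <= fit1.sse * (1 + 1e-12)

    def test_covariance_and_se_shape(self, small_stand):
        _, trees, taper, _ = small_stand
        fit = fit_taper("kozakII2004", join_sections(trees, taper))
        assert fit.se.shape == (9,)
        assert np.all(fit.se >= 0)
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        assert fit.n_obs == len(taper)

    def test_too_few_observations_rejected(self, small_stand):
        _, trees, taper, _ = small_stand
        data = join_sections(trees, taper).head(10)
        with pytest.raises(ValueError, match="observations"):
            fit_taper("kozakII2004", data)

    def test_recovery_bias_shrinks_with_sample_size(self):
        """Mean recovered b1 moves toward the generating value as the
        stand grows (Monte-Carlo over 6 seeds at n = 30 and n = 300)."""
        from larchbiomass.experiments import taper_recovery
        true_b1 = TAPER_PARAMS["kozakII2004"][0]
        small = taper_recovery(n_seeds=6, n_trees=30, master_seed=5)
        large = taper_recovery(n_seeds=6, n_trees=300, master_seed=5)
        assert large["b1"].std() < small["b1"].std()
        assert abs(large["b1"].mean() - true_b1) < 0.02
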