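"""Sinusoid + environment model fits and the MH Bayesian slope sampler."""

import numpy as np
import pandas as pd
import pytest

from pomstoich.models import (
    OMEGA,
    BayesLinearModel,
    EnvHarmonicModel,
    MHConfig,
    compare_predictors,
    fit_env_model,
    mh_linear_slope,
    regional_restriction_fit,
)


def gen_env_data(p1=2.0, p2=0.5, p3=10.0, p4=-0.1, n=100, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 72, n)
    x = rng.uniform(60, 130, n)
    y = p1 * np.sin(OMEGA * t + p2) + p3 + p4 * x + rng.normal(0, noise, n)
    return y, t, x


class TestEnvHarmonicModel:
    def test_noiseless_identifiability(self):
        y, t, x = gen_env_data()
        fit = fit_env_model(y, t, x)
        np.testing.assert_allclose(fit.params, [2.0, 0.5, 10.0, -0.1], atol=1e-8)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_refit_on_own_predictions_is_fixed_point(self):
        y, t, x = gen_env_data(noise=0.3, seed=2)
        fit = fit_env_model(y, t, x)
        refit = fit_env_model(fit.predict(t, x), t, x)
        np.testing.assert_allclose(refit.params, fit.params, atol=1e-8)

    def test_constant_response(self):
        _, t, x = gen_env_data()
        fit = fit_env_model(np.full_like(t, 5.0), t, x)
        assert fit.p1 == pytest.approx(0.0, abs=1e-10)
        assert fit.p4 == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(0.0, abs=1e-10)

    def test_permuted_predictor_loses_fit(self):
        rng = np.random.default_rng(9)
        y, t, x = gen_env_data(noise=0.2, seed=9)
        true_fit = fit_env_model(y, t, x)
        perm_fit = fit_env_model(y, t, rng.permutation(x))
        assert perm_fit.r2 < true_fit.r2

    def test_constant_predictor_errors(self):
        y, t, _ = gen_env_data()
        with pytest.raises(ValueError, match="constant"):
            fit_env_model(y, t, np.full_like(y, 3.0))

    def test_minimum_data_requirements(self):
        with pytest.raises(ValueError):
            EnvHarmonicModel([1, 2, 3], [0, 1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="24"):
            EnvHarmonicModel(np.arange(10.0), np.linspace(0, 10, 10), np.arange(10.0))

    def test_phase_wrapped_amplitude_nonnegative(self):
        for p2 in (-2.9, -0.5, 1.2, 3.0):
            y, t, x = gen_env_data(p2=p2)
            fit = fit_env_model(y, t, x)
            assert fit.p1 >= 0
            assert -np.pi < fit.p2 <= np.pi

    def test_r2_rss_tss_identity(self):
        y, t, x = gen_env_data(noise=0.5, seed=3)
        fit = fit_env_model(y, t, x)
        resid = y - fit.predict(t, x)
        rss = resid @ resid
        tss = np.sum((y - y.mean()) ** 2)
        assert fit.r2 + rss / tss == pytest.approx(1.0, rel=1e-12)

    def test_summary_mentions_parameters(self):
        y, t, x = gen_env_data()
        text = fit_env_model(y, t, x, variable="poc", predictor="znut").summary()
        assert "amplitude" in text and "slope" in text and "poc" in text


class TestComparePredictors:
    def test_single_fit_is_best(self):
        y, t, x = gen_env_data()
        table = compare_predictors([fit_env_model(y, t, x, "poc", "znut")])
        assert table["best"].all()

    def test_true_predictor_ranked_best(self):
        rng = np.random.default_rng(1)
        y, t, x = gen_env_data(noise=0.1, seed=1)
        fits = [
            fit_env_model(y, t, x, "poc", "znut"),
            fit_env_model(y, t, rng.permutation(x), "poc", "shuffled"),
        ]
        table = compare_predictors(fits)
        assert table.loc[table["best"], "predictor"].iloc[0] == "znut"
        assert not table.loc[table["predictor"] == "shuffled", "tied_with_best"].iloc[0]

    def test_identical_fits_tie(self):
        y, t, x = gen_env_data(noise=0.2, seed=4)
        f1 = fit_env_model(y, t, x, "poc", "a")
        f2 = fit_env_model(y, t, x, "poc", "b")
        table = compare_predictors([f1, f2])
        assert table["tied_with_best"].all()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            compare_predictors([])


class TestRegionalRestriction:
    def _frame(self, n=120, northern_offset=0.0, seed=0):
        y, t, x = gen_env_data(n=n, noise=0.05, seed=seed)
        lat = np.linspace(-30, 15, n)
        y = y + np.where(lat >= 5.0, northern_offset, 0.0)
        return pd.DataFrame({"poc": y, "tot_hrs": t, "znut_m": x, "latitude": lat})

    def test_cutoff_above_all_data_identical(self):
        df = self._frame()
        full = EnvHarmonicModel.from_dataframe(df, "poc", "znut_m").fit()
        restricted = regional_restriction_fit(df, "poc", "znut_m", lat_cutoff=90.0)
        np.testing.assert_allclose(restricted.params, full.params, rtol=1e-12)

    def test_northern_anomaly_shifts_slope(self):
        df = self._frame(northern_offset=3.0, seed=5)
        full = EnvHarmonicModel.from_dataframe(df, "poc", "znut_m").fit()
        south = regional_restriction_fit(df, "poc", "znut_m", lat_cutoff=5.0)
        # the uncontaminated southern fit is closer to the true slope -0.1
        assert abs(south.p4 - (-0.1)) < abs(full.p4 - (-0.1))

    def test_empty_subset_errors(self):
        df = self._frame()
        with pytest.raises(ValueError):
            regional_restriction_fit(df, "poc", "znut_m", lat_cutoff=-90.0)


class TestBayesLinearModel:
    def test_exact_line_after_normalization(self):
        x = np.linspace(1, 10, 40)
        post = mh_linear_slope(x, 2.0 * x, sigma=0.01,
                               config=MHConfig(steps=4000, seed=1))
        # after max-normalisation y/x are identical series: slope 1
        assert post.slope_mean == pytest.approx(1.0, abs=0.02)
        assert post.denormalize_slope() == pytest.approx(2.0, abs=0.05)

    def test_negative_slope_posterior_mass(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 5, 80)
        y = -x + rng.normal(0, 0.3, 80)
        post = mh_linear_slope(x, y, normalize=False,
                               config=MHConfig(steps=6000, seed=2))
        assert post.prob_slope_negative() > 0.975

    def test_acceptance_rate_reasonable(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 5, 60)
        y = 1 + 0.5 * x + rng.normal(0, 0.4, 60)
        post = mh_linear_slope(x, y, config=MHConfig(steps=6000, seed=3))
        assert 0.1 < post.acceptance_rate < 0.6

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 5, 40)
        y = 1 + x + rng.normal(0, 0.2, 40)
        cfg = MHConfig(steps=2000, seed=11)
        p1 = mh_linear_slope(x, y, config=cfg)
        p2 = mh_linear_slope(x, y, config=cfg)
        np.testing.assert_array_equal(p1.samples, p2.samples)

    def test_posterior_mean_within_sample_range(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 5, 40)
        y = 2 - 0.3 * x + rng.normal(0, 0.2, 40)
        post = mh_linear_slope(x, y, config=MHConfig(steps=4000, seed=4))
        lo, hi = post.samples[:, 1].min(), post.samples[:, 1].max()
        assert lo <= post.slope_mean <= hi
        assert post.slope_ci95[0] < post.slope_mean < post.slope_ci95[1]

    def test_zero_maximum_errors(self):
        with pytest.raises(ValueError):
            BayesLinearModel([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])

    def test_constant_x_errors(self):
        with pytest.raises(ValueError):
            BayesLinearModel([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
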