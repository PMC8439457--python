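import numpy as np
import pandas as pd
import pytest

from lakemp import synthetic_data as sd
from lakemp.models import (
    HurdleData,
    MCMCConfig,
    PosteriorFit,
    bayes_r2,
    build_cens_lnm_data,
    build_hurdle_data,
    fit_cens_lnm,
    fit_hurdle,
    habitat_contrast,
    habitat_contrasts,
    marginal_effect,
)


def manual_hurdle_fit(pi, beta0, beta, volume_m3=7.1):
    """Assemble a PosteriorFit from given draws (chains, samples[, p])."""
    pi, beta0, beta = np.asarray(pi, float), np.asarray(beta0, float), np.asarray(beta, float)
    draws = np.concatenate([pi[..., None], beta0[..., None], beta], axis=2)
    p = beta.shape[2]
    names = ["pi", "beta0"] + [f"beta[x{j}]" for j in range(p)]
    slices = {name: slice(j, j + 1) for j, name in enumerate(names)}
    slices["beta"] = slice(2, 2 + p)
    return PosteriorFit(
        model="hurdle",
        draws=draws,
        param_names=names,
        slices=slices,
        meta={"predictor_names": [f"x{j}" for j in range(p)], "volume_m3": volume_m3},
    )


class TestFitHurdle:
    def test_recovery_at_10x_sample_size(self):
        truth = (0.3, 0.2, -0.2, 0.0, -0.3, 0.0)
        config = sd.LakeSimConfig(n_lakes=670, beta=truth, seed=21)
        data = build_hurdle_data(sd.gen_lake_survey(config))
        fit = fit_hurdle(data, mcmc=MCMCConfig(chains=2, warmup=800, samples=800, seed=2))
        beta = fit.flat("beta")
        covered = 0
        for j, b in enumerate(truth):
            lo, hi = np.percentile(beta[:, j], [2.5, 97.5])
            if b != 0:
                assert np.sign(np.mean(beta[:, j])) == np.sign(b)
                assert lo > 0 or hi < 0 or abs(b) < 0.25
            covered += lo - 0.02 <= b <= hi + 0.02
        assert covered >= 5  # 95% intervals: allow one near-miss of six

    def test_pi_recovered(self):
        config = sd.LakeSimConfig(n_lakes=670, detect_prob=0.8, seed=22)
        data = build_hurdle_data(sd.gen_lake_survey(config))
        fit = fit_hurdle(data, mcmc=MCMCConfig(chains=2, warmup=600, samples=600, seed=3))
        lo, hi = fit.credible_interval("pi")
        assert lo <= 0.8 <= hi

    def test_record_order_exchangeable(self, survey_67, short_mcmc):
        data = build_hurdle_data(survey_67)
        rng = np.random.default_rng(0)
        perm = rng.permutation(data.n)
        permuted = HurdleData(
            counts=data.counts[perm],
            X=data.X[perm],
            volume_m3=data.volume_m3,
            predictor_names=data.predictor_names,
        )
        fit_a = fit_hurdle(data, mcmc=short_mcmc)
        fit_b = fit_hurdle(permuted, mcmc=short_mcmc)
        # the likelihood is permutation-invariant and the sampler seed fixed,
        # so the draws are bit-identical
        np.testing.assert_array_equal(fit_a.draws, fit_b.draws)


class TestFitCensLnm:
    @pytest.fixture(scope="class")
    def recovery_fit(self):
        config = sd.GlobalTowSimConfig(
            n_studies=9,
            tows_per_study=25,
            habitat_log_means={"lake": 0.0, "river": 0.405, "marine_estuarine": -0.693},
            mesh_effect=-0.3,
            study_sd=0.4,
            resid_sd=0.6,
            seed=31,
        )
        df = sd.gen_towdb(config)
        data = build_cens_lnm_data(df)
        fit = fit_cens_lnm(data, mcmc=MCMCConfig(chains=2, warmup=800, samples=800, seed=4))
        return config, fit

    def test_habitat_means_recovered(self, recovery_fit):
        config, fit = recovery_fit
        covered = 0
        for label, truth in config.habitat_log_means.items():
            lo, hi = fit.credible_interval(f"alpha[{label}]")
            covered += lo <= truth <= hi
        assert covered >= 2

    def test_mesh_effect_sign(self, recovery_fit):
        _, fit = recovery_fit
        lo, hi = fit.credible_interval("beta_mesh")
        assert lo <= -0.3 <= hi
        assert np.mean(fit.flat("beta_mesh")) < 0

    def test_sigma_positive_draws(self, recovery_fit):
        _, fit = recovery_fit
        assert (fit.flat("sigma") > 0).all()
        assert (fit.flat("sigma_study") > 0).all()

    def test_zero_study_sd_concentrates_near_zero(self):
        config = sd.GlobalTowSimConfig(
            n_studies=10,
            tows_per_study=30,
            habitat_log_means={"lake": 0.5, "river": 0.5, "marine_estuarine": 0.5},
            mesh_effect=0.0,
            study_sd=0.0,
            resid_sd=0.5,
            seed=32,
        )
        data = build_cens_lnm_data(sd.gen_towdb(config))
        fit = fit_cens_lnm(data, mcmc=MCMCConfig(chains=2, warmup=600, samples=600, seed=5))
        assert np.median(fit.flat("sigma_study")) < 0.25


class TestHabitatContrasts:
    @pytest.fixture(scope="class")
    def contrast_fit(self):
        # truth on the median scale: lake 1.0, marine 0.5 -> difference +0.5
        config = sd.GlobalTowSimConfig(
            n_studies=12,
            tows_per_study=30,
            habitat_log_means={"lake": 0.0, "river": 0.3, "marine_estuarine": float(np.log(0.5))},
            mesh_effect=-0.2,
            study_sd=0.3,
            resid_sd=0.5,
            seed=33,
        )
        data = build_cens_lnm_data(sd.gen_towdb(config))
        return fit_cens_lnm(data, mcmc=MCMCConfig(chains=2, warmup=700, samples=700, seed=6))

    def test_self_contrast_is_zero(self, contrast_fit):
        diff = habitat_contrast(contrast_fit, "lake", "lake")
        assert np.all(diff == 0)

    def test_antisymmetric_draw_by_draw(self, contrast_fit):
        ab = habitat_contrast(contrast_fit, "lake", "marine_estuarine")
        ba = habitat_contrast(contrast_fit, "marine_estuarine", "lake")
        np.testing.assert_allclose(ab, -ba)

    def test_synthetic_difference_recovered(self, contrast_fit):
        diff = habitat_contrast(contrast_fit, "lake", "marine_estuarine")
        lo, hi = np.percentile(diff, [2.5, 97.5])
        assert lo <= 0.5 <= hi

    def test_summary_table(self, contrast_fit):
        table = habitat_contrasts(contrast_fit)
        assert len(table) == 6  # ordered pairs of 3 habitats
        assert {"habitat_a", "habitat_b", "mean", "q2.5", "q97.5"} <= set(table.columns)

    def test_unknown_habitat_rejected(self, contrast_fit):
        with pytest.raises(ValueError, match="unknown habitat"):
            habitat_contrast(contrast_fit, "lake", "ocean")


class TestBayesR2:
    def test_matches_straight_formula_on_fixed_draws(self, rng):
        n, p = 20, 3
        X = rng.normal(size=(n, p))
        data = HurdleData(counts=rng.integers(0, 5, n), X=X)
        pi = rng.uniform(0.5, 0.9, size=(2, 5))
        beta0 = rng.normal(0.5, 0.1, size=(2, 5))
        beta = rng.normal(0, 0.3, size=(2, 5, p))
        fit = manual_hurdle_fit(pi, beta0, beta)
        r2 = bayes_r2(fit, data)
        # independent straight-formula implementation, looped per draw
        flat_pi, flat_b0 = pi.reshape(-1), beta0.reshape(-1)
        flat_beta = beta.reshape(-1, p)
        for d in range(10):
            lam = np.exp(flat_b0[d] + X @ flat_beta[d])
            m = flat_pi[d] * lam / (1 - np.exp(-lam))
            second = flat_pi[d] * (lam + lam**2) / (1 - np.exp(-lam))
            var_fit = np.var(m, ddof=1)
            var_res = np.mean(second - m**2)
            assert r2[d] == pytest.approx(var_fit / (var_fit + var_res), abs=1e-10)

    def test_null_signal_r2_near_zero(self, rng):
        n = 50
        data = HurdleData(counts=rng.integers(1, 4, n), X=rng.normal(size=(n, 2)))
        fit = manual_hurdle_fit(
            np.full((2, 20), 0.8), np.full((2, 20), 0.7), np.zeros((2, 20, 2))
        )
        r2 = bayes_r2(fit, data)
        np.testing.assert_allclose(r2, 0.0, atol=1e-12)

    def test_strong_signal_r2_near_one(self, rng):
        # huge coefficients: fitted-mean variance dwarfs residual variance
        n = 200
        X = rng.normal(size=(n, 1))
        data = HurdleData(counts=np.ones(n, dtype=int), X=X)
        fit = manual_hurdle_fit(
            np.full((2, 5), 0.999), np.full((2, 5), 8.0), np.full((2, 5, 1), 4.0)
        )
        assert bayes_r2(fit, data).mean() > 0.95


class TestMarginalEffect:
    def test_flat_curve_when_beta_zero(self, rng):
        n = 30
        data = HurdleData(counts=rng.integers(0, 4, n), X=rng.normal(size=(n, 2)))
        fit = manual_hurdle_fit(
            rng.uniform(0.6, 0.9, (2, 50)), rng.normal(0.5, 0.2, (2, 50)), np.zeros((2, 50, 2))
        )
        curve = marginal_effect(fit, data, 0)
        np.testing.assert_allclose(curve.mean, curve.mean[0])
        assert curve.endpoint_ratio == pytest.approx(1.0)

    def test_endpoint_ratio_closed_form(self, rng):
        # constant draws, lam large so truncation is negligible:
        # ratio == exp(beta1 * observed range)
        n = 40
        X = rng.normal(size=(n, 1))
        data = HurdleData(counts=np.ones(n, dtype=int), X=X)
        beta1 = 0.4
        fit = manual_hurdle_fit(
            np.full((2, 5), 0.8), np.full((2, 5), 3.0), np.full((2, 5, 1), beta1)
        )
        curve = marginal_effect(fit, data, 0)
        expected = np.exp(beta1 * (X[:, 0].max() - X[:, 0].min()))
        assert curve.endpoint_ratio == pytest.approx(expected, rel=5e-3)

    def test_monotone_when_posterior_one_signed(self, rng):
        n = 30
        data = HurdleData(counts=np.ones(n, dtype=int), X=rng.normal(size=(n, 1)))
        fit = manual_hurdle_fit(
            rng.uniform(0.7, 0.9, (2, 40)),
            rng.normal(1.0, 0.2, (2, 40)),
            rng.uniform(0.2, 0.6, (2, 40, 1)),  # strictly positive coefficient
        )
        curve = marginal_effect(fit, data, 0)
        assert (np.diff(curve.mean) > 0).all()

    def test_grid_outside_range_warns(self, rng):
        data = HurdleData(counts=np.ones(10, dtype=int), X=rng.normal(size=(10, 1)))
        fit = manual_hurdle_fit(np.full((2, 5), 0.8), np.zeros((2, 5)), np.zeros((2, 5, 1)))
        with pytest.warns(UserWarning, match="outside"):
            marginal_effect(fit, data, 0, grid=np.array([-100.0, 100.0]))

    def test_conditioning_on_detection_scales_by_pi(self, rng):
        data = HurdleData(counts=np.ones(10, dtype=int), X=rng.normal(size=(10, 1)))
        pi_val = 0.6
        fit = manual_hurdle_fit(
            np.full((2, 5), pi_val), np.full((2, 5), 2.0), np.full((2, 5, 1), 0.3)
        )
        marg = marginal_effect(fit, data, 0)
        cond = marginal_effect(fit, data, 0, marginalize_pi=False)
        np.testing.assert_allclose(marg.mean, pi_val * cond.mean, rtol=1e-10)


class TestBuildHurdleData:
    def test_columns_standardised(self, survey_67):
        data = build_hurdle_data(survey_67)
        np.testing.assert_allclose(data.X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(data.X.std(axis=0, ddof=1), 1.0, rtol=1e-10)
        assert data.volume_m3 == 7.1
        assert data.X.shape == (67, 6)

    def test_transforms_applied(self, survey_67):
        from lakemp.emissions import cube_root
        from lakemp.limnoassays import standardize

        data = build_hurdle_data(survey_67)
        expected, _, _ = standardize(cube_root(survey_67["plastic_input_tonnes"].to_numpy()))
        np.testing.assert_allclose(data.X[:, 0], expected)
        expected_slope, _, _ = standardize(np.log(survey_67["spectral_slope_nm"].to_numpy()))
        np.testing.assert_allclose(data.X[:, 5], expected_slope)
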