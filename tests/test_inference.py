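"""Priors, likelihood, convergence criteria and sampling behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cocoaferm import inference as inf
from cocoaferm import preprocessing as pp
from cocoaferm import synthetic_data as sd
from cocoaferm.model_core import build_variant, simulate


class TestLogPrior:
    def test_out_of_support_is_minus_inf(self):
        assert inf.log_prior([-0.1, 0.5], 1.0) == -np.inf
        assert inf.log_prior([0.5], -1.0) == -np.inf
        assert inf.log_prior([0.5], 0.0) == -np.inf

    def test_matches_scipy_truncated_normal(self):
        prior = inf.PriorSpec()
        a = (0 - prior.theta_mean) / prior.theta_sd
        for theta in (0.05, 0.5, 1.3):
            expected = stats.truncnorm.logpdf(
                theta, a, np.inf, loc=prior.theta_mean, scale=prior.theta_sd
            ) + stats.halfcauchy.logpdf(1.0)
            assert inf.log_prior([theta], 1.0) == pytest.approx(expected, rel=1e-10)

    def test_half_cauchy_density_near_zero(self):
        # subtract the theta contribution to isolate the sigma term
        lp = inf.log_prior([0.5], 1e-12) - inf.log_prior([0.5], 1.0)
        expected = stats.halfcauchy.logpdf(1e-12) - stats.halfcauchy.logpdf(1.0)
        assert lp == pytest.approx(expected, rel=1e-9)
        assert stats.halfcauchy.logpdf(0.0) == pytest.approx(math.log(2.0 / math.pi))

    def test_additive_over_parameters(self):
        single = inf.log_prior([0.4], 1.0)
        base = inf.log_prior([0.4, 0.4, 0.4], 1.0)
        sigma_part = stats.halfcauchy.logpdf(1.0)
        assert base - sigma_part == pytest.approx(3 * (single - sigma_part))


def _noise_free_dataset(params, n_times=10):
    variant = build_variant("MI(0)")
    times = np.linspace(0.0, 160.0, n_times)
    traj = simulate(variant, params, sd.DEFAULT_INITIAL_STATE, times)
    source = pp.FermentationDataset(
        code="exact", times=times, observations=traj, units="mass"
    )
    return pp.ScaledDataset(scaled=traj, scale_factors=np.ones(8), source=source)


class TestLogLikelihood:
    def test_zero_residuals_give_normalizer_only(self, baseline_params):
        dataset = _noise_free_dataset(baseline_params)
        total, pointwise = inf.log_likelihood(
            baseline_params, 1.0, build_variant("MI(0)"), dataset
        )
        assert pointwise.size == 80
        assert total == pytest.approx(-40.0 * math.log(2 * math.pi), rel=1e-9)

    def test_doubling_sigma_costs_nt_log2(self, baseline_params):
        dataset = _noise_free_dataset(baseline_params)
        variant = build_variant("MI(0)")
        t1, _ = inf.log_likelihood(baseline_params, 1.0, variant, dataset)
        t2, _ = inf.log_likelihood(baseline_params, 2.0, variant, dataset)
        assert t1 - t2 == pytest.approx(80 * math.log(2.0), rel=1e-9)

    def test_single_observation_closed_form(self):
        # residual 0.1 at sigma 0.2: -log(0.2 sqrt(2 pi)) - 0.125
        expected = -math.log(0.2 * math.sqrt(2 * math.pi)) - 0.125
        assert stats.norm.logpdf(0.6, 0.5, 0.2) == pytest.approx(expected)

    def test_pointwise_sums_to_total(self, baseline_params):
        dataset = _noise_free_dataset(baseline_params)
        perturbed = {k: v * 1.1 for k, v in baseline_params.items()}
        total, pointwise = inf.log_likelihood(
            perturbed, 0.1, build_variant("MI(0)"), dataset
        )
        assert total == pytest.approx(pointwise.sum(), abs=1e-10)

    def test_missing_observations_skipped(self, baseline_params):
        dataset = _noise_free_dataset(baseline_params)
        scaled = dataset.scaled.copy()
        scaled[3, 2] = np.nan
        scaled[7, 6] = np.nan
        holey = pp.ScaledDataset(
            scaled=scaled, scale_factors=dataset.scale_factors, source=dataset.source
        )
        _, pointwise = inf.log_likelihood(
            baseline_params, 1.0, build_variant("MI(0)"), holey
        )
        assert pointwise.size == 78

    def test_nonpositive_sigma_rejected(self, baseline_params):
        dataset = _noise_free_dataset(baseline_params)
        total, pw = inf.log_likelihood(baseline_params, 0.0, build_variant("MI(0)"), dataset)
        assert total == -np.inf and pw is None


def _fit_with_diag(diag, prior_default=True):
    return inf.PosteriorFit(
        variant_label="MI(0)", param_names=("a", "sigma"),
        draws=np.ones((10, 2)), chain_ids=np.zeros(10),
        pointwise_loglik=np.zeros((10, 1)), diagnostics=diag,
        success=False, reasons=(), summary=pd.DataFrame(), seed=0,
        prior_default=prior_default,
    )


class TestCheckConvergence:
    BASE = {
        "max_rhat": 1.01, "min_bulk_ess": 1500.0, "min_tail_ess": 1500.0,
        "mean_ess_ratio": 0.5, "n_draws": 8000,
    }

    def test_all_criteria_met(self):
        report = inf.check_convergence(_fit_with_diag(dict(self.BASE)))
        assert report.success and not report.reasons

    def test_rhat_violation_reported(self):
        report = inf.check_convergence(_fit_with_diag(dict(self.BASE, max_rhat=1.06)))
        assert not report.success
        assert any("R-hat" in r for r in report.reasons)

    @pytest.mark.parametrize("key, reason", [
        ("min_bulk_ess", "bulk-ESS"), ("min_tail_ess", "tail-ESS"),
    ])
    def test_ess_violations(self, key, reason):
        report = inf.check_convergence(_fit_with_diag(dict(self.BASE, **{key: 99.0})))
        assert not report.success
        assert any(reason in r for r in report.reasons)

    def test_ratio_boundary_is_strict(self):
        # exactly 12.5% (1000 ESS of 8000 draws) does not pass
        report = inf.check_convergence(_fit_with_diag(dict(self.BASE, mean_ess_ratio=0.125)))
        assert not report.success

    def test_non_default_prior_never_successful(self):
        report = inf.check_convergence(_fit_with_diag(dict(self.BASE), prior_default=False))
        assert not report.success
        assert any("prior" in r for r in report.reasons)

    def test_degenerate_chains_fail(self):
        # constant chains: arviz reports NaN/zero ESS, which must not pass
        chain = np.ones((4, 50, 2))
        diag = inf._diagnostics_from_chain(chain, ("a", "sigma"))
        report = inf.check_convergence(_fit_with_diag(diag))
        assert not report.success


class TestPriorOnlySampling:
    @pytest.fixture(scope="class")
    def prior_fit(self):
        sampler = inf.SamplerConfig(chains=4, iterations=2500, warmup=500, seed=11)
        return inf.fit("MI(0)", None, sampler=sampler)

    @staticmethod
    def _decorrelated(prior_fit, col, n_steps=10):
        """Pool all walkers at a few well-separated steps (weakly dependent)."""
        cube = prior_fit.draws_by_chain()  # (walkers, steps, ndim)
        steps = np.linspace(0, cube.shape[1] - 1, n_steps).astype(int)
        return cube[:, steps, col].ravel()

    def test_marginals_match_truncated_normal(self, prior_fit):
        """With a flat likelihood the sampler must reproduce the prior."""
        prior = inf.PriorSpec()
        a = -prior.theta_mean / prior.theta_sd
        rng = np.random.default_rng(0)
        cols = rng.choice(24, size=4, replace=False)
        for col in cols:
            sub = self._decorrelated(prior_fit, col)
            stat, pvalue = stats.kstest(
                sub, lambda x: stats.truncnorm.cdf(
                    x, a, np.inf, loc=prior.theta_mean, scale=prior.theta_sd
                ),
            )
            assert pvalue > 0.01, f"column {col}: KS p={pvalue}"
        # pooled dispersion matches the prior exactly
        expected_sd = stats.truncnorm.std(a, np.inf, loc=0.5, scale=0.3)
        assert prior_fit.draws[:, :24].std() == pytest.approx(expected_sd, rel=0.05)

    def test_sigma_marginal_is_half_cauchy(self, prior_fit):
        sub = self._decorrelated(prior_fit, -1)
        stat, pvalue = stats.kstest(sub, stats.halfcauchy.cdf)
        assert pvalue > 0.01

    def test_all_draws_positive(self, prior_fit):
        assert np.all(prior_fit.draws > 0)


class TestFitBehaviour:
    def test_determinism_same_seed(self, synthetic_trial):
        dataset, _ = synthetic_trial
        scaled = pp.max_scale(dataset)
        sampler = inf.SamplerConfig(iterations=250, warmup=100, seed=5)
        f1 = inf.fit("MI(0)", scaled, sampler=sampler)
        f2 = inf.fit("MI(0)", scaled, sampler=sampler)
        np.testing.assert_array_equal(f1.draws, f2.draws)
        pd.testing.assert_frame_equal(f1.summary, f2.summary)

    def test_fit_artifacts_are_consistent(self, quick_fit):
        assert quick_fit.draws.shape[1] == 25
        assert np.all(quick_fit.draws > 0)
        assert quick_fit.pointwise_loglik.shape[0] == quick_fit.n_draws
        # likelihood additivity holds for the stored pointwise matrix
        assert np.all(np.isfinite(quick_fit.pointwise_loglik))

    def test_sigma_recovered_within_factor_two(self, quick_fit, synthetic_trial):
        _, truth = synthetic_trial
        sigma_mean = quick_fit.summary.loc["sigma", "mean"]
        assert truth.sigma / 2 <= sigma_mean <= truth.sigma * 2

    def test_save_load_round_trip(self, quick_fit, tmp_path):
        stem = quick_fit.save(tmp_path)
        loaded = inf.PosteriorFit.load(tmp_path, stem)
        np.testing.assert_allclose(loaded.draws, quick_fit.draws)
        np.testing.assert_allclose(loaded.pointwise_loglik, quick_fit.pointwise_loglik)
        assert loaded.variant_label == quick_fit.variant_label
        assert loaded.success == quick_fit.success

    def test_sampler_config_validation(self):
        with pytest.raises(ValueError):
            inf.SamplerConfig(iterations=100, warmup=100)
        with pytest.raises(ValueError):
            inf.SamplerConfig(chains=1)


class TestPosteriorPredict:
    def test_band_contains_median_and_orders(self, quick_fit, synthetic_trial):
        dataset, _ = synthetic_trial
        scaled = pp.max_scale(dataset)
        pred = inf.posterior_predict(quick_fit, dataset=scaled, max_draws=100)
        assert np.all(pred["lower"] <= pred["median"] + 1e-12)
        assert np.all(pred["median"] <= pred["upper"] + 1e-12)

    def test_noise_free_band_narrower_than_predictive(self, quick_fit, synthetic_trial):
        dataset, _ = synthetic_trial
        scaled = pp.max_scale(dataset)
        latent = inf.posterior_predict(quick_fit, dataset=scaled, max_draws=100)
        noisy = inf.posterior_predict(
            quick_fit, dataset=scaled, include_noise=True, max_draws=100
        )
        width_latent = (latent["upper"] - latent["lower"]).mean()
        width_noisy = (noisy["upper"] - noisy["lower"]).mean()
        assert width_noisy > width_latent

    def test_predictive_band_covers_observations(self, quick_fit, synthetic_trial):
        dataset, _ = synthetic_trial
        scaled = pp.max_scale(dataset)
        pred = inf.posterior_predict(
            quick_fit, dataset=scaled, include_noise=True, max_draws=300
        )
        obs = scaled.scaled
        inside = (obs >= pred["lower"] - 1e-9) & (obs <= pred["upper"] + 1e-9)
        assert inside.mean() >= 0.9
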