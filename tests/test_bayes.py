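import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from cutroc import (
    BiomarkerSample,
    MCMCSettings,
    PriorSpec,
    bn_fit,
    covariate_specific_summary,
    gelman_rubin,
    gibbs_normal_regression,
    pv_fit,
)
from cutroc.scenarios import generate, get_scenario, truth

REDUCED = MCMCSettings.reduced()
QUICK = MCMCSettings(n_iter=1500, n_burn=500, n_chains=2, n_retained=1500)


class TestGibbsNormalRegression:
    def test_intercept_posterior_concentrates_at_mean(self):
        rng = np.random.default_rng(0)
        y = rng.normal(2.0, 1.0, 10_000)
        chains = gibbs_normal_regression(
            y, np.ones((y.size, 1)), n_iter=1500, n_burn=500, n_chains=1, seed=1
        )
        assert np.mean(chains[0][:, 0]) == pytest.approx(2.0, abs=0.05)

    def test_slope_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-0.5, 1.5, 3000)
        y = 1.5 + 2.0 * x + rng.normal(0, 1, x.size)
        X = np.column_stack([np.ones_like(x), x])
        chains = gibbs_normal_regression(
            y, X, n_iter=1500, n_burn=500, n_chains=1, seed=2
        )
        assert np.mean(chains[0][:, 1]) == pytest.approx(2.0, abs=0.1)

    def test_identical_seed_bit_identical(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        X = np.ones((50, 1))
        a = gibbs_normal_regression(y, X, n_iter=500, n_burn=100, n_chains=2, seed=7)
        b = gibbs_normal_regression(y, X, n_iter=500, n_burn=100, n_chains=2, seed=7)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca, cb)

    def test_rank_deficient_design_rejected(self):
        y = np.arange(10, dtype=float)
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError):
            gibbs_normal_regression(y, X, n_iter=100, n_burn=10)

    def test_matches_flat_prior_closed_form(self):
        # with nearly flat priors the posterior approaches the standard
        # noninformative normal-inverse-gamma form: E[beta] = OLS,
        # E[sigma^2] = SSR / (n - p - 2)
        rng = np.random.default_rng(4)
        x = rng.normal(size=10)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.8, 10)
        X = np.column_stack([np.ones(10), x])
        flat = PriorSpec(coef_variance=1e8, var_shape=1e-8, var_rate=1e-8)
        chains = gibbs_normal_regression(
            y, X, priors=flat, n_iter=60_000, n_burn=5_000, n_chains=1, seed=5
        )
        draws = chains[0]
        beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
        ssr = float(((y - X @ beta_hat) ** 2).sum())
        n, p = X.shape
        sigma2_mean = ssr / (n - p - 2)
        cov_beta = sigma2_mean * np.linalg.inv(X.T @ X) * (n - p - 2) / (n - p)
        # (marginal beta is multivariate t with n-p dof)
        assert np.allclose(draws[:, :2].mean(axis=0), beta_hat, atol=0.04)
        assert draws[:, 2].mean() == pytest.approx(sigma2_mean, rel=0.08)
        emp_var = draws[:, :2].var(axis=0)
        t_var = np.diag(cov_beta) * (n - p) / (n - p - 2)
        assert np.allclose(emp_var, t_var, rtol=0.15)


class TestGelmanRubin:
    def test_identical_chains_give_unity(self):
        # split-Rhat of identical stationary chains is 1 up to the (n-1)/n
        # within-variance shrinkage of the pooled-variance estimate
        c = np.random.default_rng(0).normal(size=1000)
        assert gelman_rubin([c, c.copy()]) == pytest.approx(1.0, abs=2e-3)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 500)
        b = rng.normal(10, 1, 500)
        assert gelman_rubin([a, b]) > 1.5

    def test_well_mixed_chains_near_unity(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 5000))
        assert gelman_rubin([a, b]) < 1.01

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.zeros(100)])

    def test_agrees_with_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 400)) + rng.normal(0, 0.2, size=(4, 1))
        ours = gelman_rubin(list(chains))
        theirs = float(arviz.rhat(arviz.convert_to_dataset(chains[None].transpose(1, 2, 0)))["x"]) \
            if False else float(arviz.rhat(chains))
        assert ours == pytest.approx(theirs, abs=0.01)


class TestBNFit:
    def test_recovers_equal_variance_truth(self, large_binormal_sample):
        fit = bn_fit(large_binormal_sample, mcmc=QUICK, seed=0)
        s = fit.summary()
        assert s.auc[0] == pytest.approx(float(ndtr(1 / np.sqrt(2))), abs=0.02)
        for k, (point, lo, hi) in s.cutoffs.items():
            assert point == pytest.approx(0.5, abs=0.05)
            assert lo <= point <= hi  # point estimate inside its own CI

    def test_null_case_auc_half(self):
        rng = np.random.default_rng(5)
        s = BiomarkerSample(rng.normal(0, 1, 2000), rng.normal(0, 1, 2000))
        fit = bn_fit(s, mcmc=REDUCED, seed=1)
        assert fit.summary().auc[0] == pytest.approx(0.5, abs=0.03)

    def test_covariate_fit_recovers_closed_form_auc(self):
        sc = get_scenario("Cov_BN", n_per_group=5000)
        fit = bn_fit(generate(sc, seed=3), use_covariates=True, mcmc=REDUCED, seed=2)
        s0, s1 = covariate_specific_summary(fit, [0.0, 1.0])
        assert s0.auc[0] == pytest.approx(float(ndtr(0.5 / np.sqrt(2))), abs=0.02)
        assert s1.auc[0] == pytest.approx(float(ndtr(1.5 / np.sqrt(2))), abs=0.03)

    def test_covariate_summary_requires_covariate_fit(self, binormal_sample):
        fit = bn_fit(binormal_sample, mcmc=REDUCED, seed=0)
        with pytest.raises(ValueError):
            covariate_specific_summary(fit, 0.0)

    def test_missing_covariates_error(self, binormal_sample):
        with pytest.raises(ValueError):
            bn_fit(binormal_sample, use_covariates=True, mcmc=REDUCED)

    def test_retains_requested_draw_count(self, binormal_sample):
        fit = bn_fit(binormal_sample, mcmc=MCMCSettings(), seed=0)
        assert len(fit.posterior.draws) == 5000
        assert np.all(fit.posterior.draws["sigma0"] > 0)
        assert set(fit.posterior.rhat) >= {"beta00", "beta01"}

    def test_interval_width_shrinks_with_n(self):
        widths = []
        for n in (50, 200, 800):
            rng = np.random.default_rng(n)
            s = BiomarkerSample(rng.normal(0, 1, n), rng.normal(1, 1, n))
            summ = bn_fit(s, mcmc=REDUCED, seed=n).summary()
            widths.append(summ.auc[2] - summ.auc[1])
        assert widths[0] > widths[1] > widths[2]
        # roughly root-n: quadrupling n should roughly halve the width
        assert widths[2] < 0.6 * widths[1]

    def test_identical_seed_identical_draws(self, binormal_sample):
        a = bn_fit(binormal_sample, mcmc=REDUCED, seed=11).posterior.draws
        b = bn_fit(binormal_sample, mcmc=REDUCED, seed=11).posterior.draws
        pd.testing.assert_frame_equal(a, b)


class TestPVFit:
    def test_matches_bn_on_binormal_data(self):
        # the probit-link PV model is a reparameterization of the binormal
        rng = np.random.default_rng(21)
        s = BiomarkerSample(rng.normal(0, 1, 2000), rng.normal(1, 0.8, 2000))
        sb = bn_fit(s, mcmc=REDUCED, seed=3).summary()
        sp = pv_fit(s, mcmc=REDUCED, seed=3).summary()
        assert sp.auc[0] == pytest.approx(sb.auc[0], abs=0.03)
        for k in sb.cutoffs:
            assert sp.cutoffs[k][0] == pytest.approx(sb.cutoffs[k][0], abs=0.03)

    def test_healthy_placement_values_uniform(self):
        # probability integral transform: PV of held-out healthy data under
        # the fitted healthy law should average 0.5
        rng = np.random.default_rng(22)
        y0 = rng.normal(0, 1, 1500)
        s = BiomarkerSample(y0[:1000], rng.normal(1, 1, 1000))
        fit = pv_fit(s, mcmc=REDUCED, seed=4)
        d = fit.posterior.draws
        mu0, s0 = d["beta00"].mean(), d["sigma0"].mean()
        z_heldout = 1.0 - ndtr((y0[1000:] - mu0) / s0)
        assert float(np.mean(z_heldout)) == pytest.approx(0.5, abs=0.03)

    def test_covariate_slope_interval_excludes_zero(self):
        sc = get_scenario("Cov_BN", n_per_group=1000)
        fit = pv_fit(generate(sc, seed=9), use_covariates=True, mcmc=REDUCED, seed=5)
        lo, hi = np.percentile(fit.posterior.draws["beta1"], [2.5, 97.5])
        assert hi < 0  # diseased separation grows with x, so the PV slope < 0

    def test_two_stage_variant_close_to_joint(self):
        rng = np.random.default_rng(23)
        s = BiomarkerSample(rng.normal(0, 1, 500), rng.normal(1, 1, 500))
        joint = pv_fit(s, mcmc=REDUCED, seed=6).summary()
        plug = pv_fit(s, mcmc=REDUCED, seed=6, two_stage=True).summary()
        assert plug.auc[0] == pytest.approx(joint.auc[0], abs=0.02)

    def test_identical_seed_identical_draws(self, binormal_sample):
        a = pv_fit(binormal_sample, mcmc=REDUCED, seed=13).posterior.draws
        b = pv_fit(binormal_sample, mcmc=REDUCED, seed=13).posterior.draws
        pd.testing.assert_frame_equal(a, b)
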