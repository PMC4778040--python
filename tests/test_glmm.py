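"""Laplace GLMM: exact limits, quadrature oracle, recovery, diagnostics."""

import subprocess

import numpy as np
import pytest
from scipy import special, stats
from scipy.special import logsumexp, roots_hermite

from spermcomp import (
    GLMMData,
    dispersion,
    dispersion_ratio,
    fit_glmm,
    glm_loglik,
    laplace_loglik,
    paired_binomial_dataset,
    residual_df,
    t_pvalue,
    wald_test,
)
from spermcomp.glmm import (
    GLMMError,
    _irls_glm,
    _laplace_1d,
    deviance_residuals,
)
from spermcomp.records import GLMMFit


def agq_loglik(b0, b1, sigma, data, n_nodes=51):
    """Independent oracle: adaptive Gauss-Hermite quadrature per group."""
    nodes, weights = roots_hermite(n_nodes)
    eta0 = b0 + b1 * data.x
    _, u_hat = _laplace_1d(b0, b1, sigma, data)
    total = 0.0
    for g in range(data.n_groups):
        mask = data.group == g
        eta = eta0[mask] + u_hat[g]
        w = data.m[mask] * special.expit(eta) * (1 - special.expit(eta))
        s = 1.0 / np.sqrt(w.sum() + 1 / sigma ** 2)
        u = u_hat[g] + np.sqrt(2) * s * nodes
        vals = []
        for ui in u:
            e = eta0[mask] + ui
            ll = (data.log_choose[mask] + data.k[mask] * e
                  - data.m[mask] * np.logaddexp(0, e)).sum()
            ll += -0.5 * np.log(2 * np.pi * sigma ** 2) - ui ** 2 / (2 * sigma ** 2)
            vals.append(ll)
        vals = np.array(vals) + nodes ** 2 + np.log(weights) \
            + 0.5 * np.log(2) + np.log(s)
        total += logsumexp(vals)
    return float(total)


def _toy(seed=0, n_groups=3, m=150, b0=0.0, b1=0.4, sigma=0.5):
    rng = np.random.default_rng(seed)
    obs = []
    for g in range(n_groups):
        u = rng.normal(0, sigma)
        for x in (0, 1):
            p = special.expit(b0 + b1 * x + u)
            obs.append((f"g{g}", x, int(rng.binomial(m, p)), m))
    return GLMMData.from_observations(obs)


class TestLaplaceLoglik:
    def test_sigma_zero_equals_binomial_pmf_sum(self):
        data = _toy(seed=1)
        for b0, b1 in [(0.0, 0.0), (0.2, 0.3), (-1.0, 0.8)]:
            p = special.expit(b0 + b1 * data.x)
            exact = sum(stats.binom.logpmf(int(k), int(m), pi)
                        for k, m, pi in zip(data.k, data.m, p))
            assert laplace_loglik(b0, b1, 0.0, data) == pytest.approx(exact, abs=1e-12)

    def test_matches_51_node_quadrature_on_toy(self):
        # Laplace error per group shrinks as 1/(m p q); m = 500 puts the
        # 3-group total well inside 1e-3
        data = _toy(seed=2, m=500)
        lap = laplace_loglik(0.1, 0.3, 0.5, data)
        agq = agq_loglik(0.1, 0.3, 0.5, data)
        assert lap == pytest.approx(agq, abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadrature_on_randomised_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(30, 150))
        data = _toy(seed=seed + 10, n_groups=int(rng.integers(3, 8)), m=m,
                    sigma=float(rng.uniform(0.2, 1.0)))
        sigma = float(rng.uniform(0.2, 1.0))
        b0, b1 = rng.normal(0, 0.4, 2)
        assert laplace_loglik(b0, b1, sigma, data) == pytest.approx(
            agq_loglik(b0, b1, sigma, data), abs=1e-2)

    def test_all_zero_successes_monotone_in_beta0(self):
        data = GLMMData.from_observations(
            [(g, x, 0, 10) for g in "abc" for x in (0, 1)])
        lls = [laplace_loglik(b0, 0.0, 0.3, data) for b0 in (0, -2, -4, -6)]
        assert np.all(np.diff(lls) > 0)


class TestFit:
    def test_identical_arms_give_null_coefficient(self):
        data = GLMMData.from_observations(
            [(g, x, 40, 100) for g in "abcd" for x in (0, 1)])
        fit = fit_glmm(data)
        assert abs(fit.beta1) < 1e-6

    def test_sigma_zero_boundary_matches_glm_oracle(self):
        """Pooled-looking data collapses sigma to 0; betas equal a logistic
        GLM fitted independently by statsmodels."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        data = paired_binomial_dataset(8, 100, 0.5, 0.05, rng)  # no pair effect
        beta = _irls_glm(data)
        X = np.column_stack([np.ones(data.n_obs), data.x])
        glm = sm.GLM(np.column_stack([data.k, data.m - data.k]), X,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(beta, glm.params, atol=1e-8)
        fit = fit_glmm(data)
        if fit.sigma_u == 0.0:
            np.testing.assert_allclose([fit.beta0, fit.beta1], glm.params,
                                       atol=1e-6)

    def test_matches_lme4_reference_fit(self):
        """Full comparison against glmer (Laplace) on one dataset."""
        rng = np.random.default_rng(7)
        data = paired_binomial_dataset(10, 100, 0.5, 0.06, rng,
                                       pair_sd=0.4, obs_sd=0.3)
        rows = "\n".join(
            f"{g},{int(x)},{int(k)},{int(m)}"
            for g, x, k, m in zip(data.group, data.x, data.k, data.m))
        script = (
            "suppressMessages(library(lme4));"
            "d <- read.csv(text='g,x,k,m\n%s');"
            "fit <- glmer(cbind(k, m-k) ~ x + (1|g), family=binomial, data=d);"
            "cat(fixef(fit), sqrt(unlist(VarCorr(fit))), logLik(fit))"
        ) % rows
        res = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        b0, b1, sig, ll = map(float, res.stdout.split())
        fit = fit_glmm(data)
        assert fit.beta0 == pytest.approx(b0, abs=2e-3)
        assert fit.beta1 == pytest.approx(b1, abs=2e-3)
        assert fit.sigma_u == pytest.approx(sig, abs=5e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)

    def test_treatment_recoding_mirrors_fit(self):
        rng = np.random.default_rng(11)
        data = paired_binomial_dataset(10, 100, 0.5, 0.08, rng, pair_sd=0.3)
        flipped = GLMMData(data.group, 1.0 - data.x, data.k, data.m,
                           data.group_labels)
        f1, f2 = fit_glmm(data), fit_glmm(flipped)
        assert f1.beta1 == pytest.approx(-f2.beta1, abs=1e-5)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        t1, t2 = wald_test(f1), wald_test(f2)
        assert abs(t1.statistic) == pytest.approx(abs(t2.statistic), abs=1e-4)

    def test_group_relabelling_invariant(self):
        rng = np.random.default_rng(13)
        data = paired_binomial_dataset(8, 80, 0.5, 0.05, rng, pair_sd=0.3)
        perm = np.random.default_rng(0).permutation(data.n_groups)
        relabeled = GLMMData(perm[data.group], data.x, data.k, data.m)
        assert fit_glmm(data).loglik == pytest.approx(
            fit_glmm(relabeled).loglik, abs=1e-6)

    def test_loglik_trace_monotone_on_accepted_steps(self):
        rng = np.random.default_rng(17)
        data = paired_binomial_dataset(10, 100, 0.5, 0.06, rng, pair_sd=0.4)
        fit = fit_glmm(data)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) > -1e-6)

    def test_parameter_recovery_on_simulated_design(self):
        """20 groups, m = 200, beta1 = 0.4, sigma_u = 0.5: estimates are
        unbiased within Monte-Carlo error over 200 replicates."""
        b1s, sigmas = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            obs = []
            for g in range(20):
                u = rng.normal(0, 0.5)
                for x in (0, 1):
                    p = special.expit(0.0 + 0.4 * x + u)
                    obs.append((g, x, int(rng.binomial(200, p)), 200))
            fit = fit_glmm(GLMMData.from_observations(obs))
            b1s.append(fit.beta1)
            sigmas.append(fit.sigma_u)
        assert abs(np.mean(b1s) - 0.4) < 0.05
        assert np.mean(b1s) == pytest.approx(
            0.4, abs=3 * np.std(b1s) / np.sqrt(len(b1s)) + 0.01)
        assert np.mean(sigmas) == pytest.approx(0.5, abs=0.12)

    def test_separation_flagged_with_finite_estimates(self):
        data = GLMMData.from_observations(
            [(g, 0, 5, 10) for g in "abcd"] + [(g, 1, 0, 10) for g in "abcd"])
        fit = fit_glmm(data)
        assert fit.separation
        assert np.isfinite(fit.beta1)


class TestWald:
    def test_printed_statistic_p_mappings(self):
        # the two statistic -> p pairs of the study's inference arithmetic
        assert t_pvalue(0.23, 17) == pytest.approx(0.821, abs=5e-4)
        assert round(t_pvalue(-0.62, 17), 2) == 0.54

    def test_null_coefficient_gives_p_one(self):
        fit = GLMMFit(beta0=0.0, beta1=0.0, sigma_u=0.1, loglik=-1.0,
                      se_beta0=0.1, se_beta1=0.1,
                      conditional_modes=np.zeros(10), n_obs=20, n_groups=10)
        t = wald_test(fit)
        assert t.statistic == 0.0 and t.p_value == 1.0
        assert t.df == 17  # 20 - 2 - 1

    def test_t_converges_to_z_for_large_df(self):
        fit = GLMMFit(beta0=0.0, beta1=0.2, sigma_u=0.1, loglik=-1.0,
                      se_beta0=0.1, se_beta1=0.1,
                      conditional_modes=np.zeros(10), n_obs=20, n_groups=10)
        p_t = wald_test(fit, df_policy=10 ** 6).p_value
        p_z = wald_test(fit, dist="z").p_value
        assert p_t == pytest.approx(p_z, abs=1e-6)

    def test_degenerate_se_raises(self):
        fit = GLMMFit(beta0=0.0, beta1=0.2, sigma_u=0.1, loglik=-1.0,
                      se_beta0=0.1, se_beta1=0.0,
                      conditional_modes=np.zeros(10), n_obs=20, n_groups=10)
        with pytest.raises(GLMMError, match="degenerate"):
            wald_test(fit)

    def test_residual_df_convention(self):
        assert residual_df(20, 2, 1) == 17
        with pytest.raises(ValueError):
            residual_df(3, 2, 1)


class TestDispersion:
    def test_dispersion_arithmetic_matches_printed_value(self):
        assert round(dispersion_ratio(53.18, 17), 2) == 3.13

    def test_saturated_fit_has_zero_deviance(self):
        k = np.array([3.0, 7.0, 0.0, 10.0])
        m = np.array([10.0, 10.0, 10.0, 10.0])
        d = deviance_residuals(k, m, k / np.maximum(m, 1))
        assert np.allclose(d, 0.0)

    def test_pure_binomial_dispersion_calibrates_to_one(self):
        """No overdispersion in the generator -> Pearson dispersion ~ 1."""
        disps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            data = paired_binomial_dataset(10, 100, 0.5, 0.0, rng)
            fit = fit_glmm(data)
            disps.append(dispersion(fit, data).dispersion_pearson)
        assert np.mean(disps) == pytest.approx(1.0, abs=0.15)

    def test_olre_reduces_dispersion_on_overdispersed_data(self):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            data = paired_binomial_dataset(10, 100, 0.5, 0.0, rng, obs_sd=0.5)
            base = fit_glmm(data)
            olre = fit_glmm(data, olre=True)
            d_base = dispersion(base, data).dispersion_pearson
            d_olre = dispersion(olre, data).dispersion_pearson
            assert d_olre < d_base

    def test_dispersion_increases_with_obs_noise(self):
        """Rank correlation between obs_sd and fitted dispersion is positive."""
        grid = [0.0, 0.2, 0.4, 0.6, 0.8]
        means = []
        for osd in grid:
            vals = []
            for seed in range(8):
                rng = np.random.default_rng(100 + seed)
                data = paired_binomial_dataset(10, 100, 0.5, 0.0, rng, obs_sd=osd)
                vals.append(dispersion(fit_glmm(data), data).dispersion_pearson)
            means.append(np.mean(vals))
        rho = stats.spearmanr(grid, means).statistic
        assert rho > 0.8
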