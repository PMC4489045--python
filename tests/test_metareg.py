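"""Random-effects ML fitting and the t / Bartlett-corrected LR tests."""
import numpy as np
import pytest
from scipy import stats

from metadiff.metareg import (
    ConvergenceError,
    FitResult,
    bartlett_correction_factor,
    bclr_test,
    fit_random_effects_ml,
    likelihood_ratio,
    profile_loglik,
    t_test,
)
from metadiff.preprocess import MetaRegressionProblem
from conftest import make_problem


def grid_search_oracle(problem, n_grid=801, n_stages=4):
    """Brute-force tau2 grid search with an independent likelihood evaluation
    (weighted lstsq + explicit Gaussian density)."""
    X, y, s2 = problem.design, problem.log_y, problem.within_var

    def ll(t2):
        v = s2 + t2
        if np.any(v <= 0):
            return -np.inf
        sw = 1.0 / np.sqrt(v)
        beta = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]
        return float(
            stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=np.diag(v))
        )

    lo, hi = 0.0, max(10.0 * np.var(y), 1e-6)
    for _ in range(n_stages):
        grid = np.linspace(lo, hi, n_grid)
        vals = np.array([ll(t) for t in grid])
        k = int(np.argmax(vals))
        step = grid[1] - grid[0]
        lo, hi = max(grid[k] - step, 0.0), grid[k] + step
    return vals[k], grid[k]


class TestProfileLoglik:
    def test_perfect_fit_has_zero_residual_term(self, rng):
        n = 10
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], 5)])
        beta = np.array([2.0, 1.5])
        s2 = rng.uniform(0.01, 0.1, n)
        problem = MetaRegressionProblem(X @ beta, s2, X, 1)
        tau2 = 0.3
        ll, beta_hat, _ = profile_loglik(problem, tau2)
        np.testing.assert_allclose(beta_hat, beta, atol=1e-10)
        v = s2 + tau2
        assert ll == pytest.approx(-0.5 * np.sum(np.log(2 * np.pi * v)))

    def test_equal_weights_reduce_to_ols(self, rng):
        problem = make_problem(rng, n=14)
        problem.within_var[:] = 0.07
        _, beta_hat, _ = profile_loglik(problem, 0.02)
        ols = np.linalg.lstsq(problem.design, problem.log_y, rcond=None)[0]
        np.testing.assert_allclose(beta_hat, ols, atol=1e-10)

    def test_matches_multivariate_normal_density(self, rng):
        problem = make_problem(rng, n=8, p=2)
        tau2 = 0.04
        ll, beta_hat, _ = profile_loglik(problem, tau2)
        cov = np.diag(problem.within_var + tau2)
        direct = stats.multivariate_normal.logpdf(
            problem.log_y, mean=problem.design @ beta_hat, cov=cov
        )
        assert ll == pytest.approx(direct, abs=1e-10)


class TestMLFit:
    def test_zero_residual_variance_gives_zero_tau2(self, rng):
        n = 10
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], 5)])
        s2 = rng.uniform(0.05, 0.2, n)
        problem = MetaRegressionProblem(X @ [1.0, 2.0], s2, X, 1)
        fit = fit_random_effects_ml(problem)
        assert fit.tau2_hat == 0.0
        assert fit.converged

    def test_zero_within_variance_recovers_ols_ml_variance(self, rng):
        """With no estimation uncertainty the model is plain regression and
        the ML heterogeneity estimate is RSS/n."""
        problem = make_problem(rng, n=20, tau2=0.3)
        problem.within_var[:] = 0.0
        fit = fit_random_effects_ml(problem)
        X, y = problem.design, problem.log_y
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = np.sum((y - X @ beta) ** 2)
        assert fit.tau2_hat == pytest.approx(rss / problem.n, rel=1e-6)

    def test_matches_grid_oracle(self, rng):
        """ML optimum agrees with a dense grid-search-plus-refinement oracle
        on 50 random problems of varying size."""
        for k in range(50):
            n = int(rng.integers(6, 33))
            problem = make_problem(rng, n=n, tau2=float(rng.uniform(0.0, 0.3)))
            fit = fit_random_effects_ml(problem)
            ll_star, tau2_star = grid_search_oracle(problem)
            assert fit.loglik == pytest.approx(ll_star, abs=1e-4)
            assert fit.tau2_hat == pytest.approx(tau2_star, abs=1e-3)

    def test_equal_within_variance_beta_equals_ols(self, rng):
        problem = make_problem(rng, n=16)
        problem.within_var[:] = 0.05
        fit = fit_random_effects_ml(problem)
        ols = np.linalg.lstsq(problem.design, problem.log_y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta_hat, ols, atol=1e-10)


class TestAgainstMetafor:
    def test_matches_r_metafor_ml_fit(self):
        """Frozen reference values from R metafor::rma(method='ML',
        test='t') on a fixed 6-vs-6 problem with known within-variances."""
        y = np.array([2.95, 3.41, 2.80, 3.62, 2.51, 3.18,
                      3.33, 2.84, 3.72, 3.05, 3.60, 2.98])
        v = np.array([0.020, 0.055, 0.011, 0.090, 0.034, 0.066,
                      0.043, 0.015, 0.081, 0.027, 0.072, 0.049])
        X = np.column_stack([np.ones(12), np.repeat([0.0, 1.0], 6)])
        fit = fit_random_effects_ml(MetaRegressionProblem(y, v, X, 1))
        assert fit.tau2_hat == pytest.approx(0.0626725640, abs=1e-5)
        assert fit.beta_hat[0] == pytest.approx(3.0094496567, abs=1e-5)
        assert fit.beta_hat[1] == pytest.approx(0.1824926862, abs=1e-5)
        assert np.sqrt(fit.beta_cov[1, 1]) == pytest.approx(0.1859932965, abs=1e-5)
        assert fit.loglik == pytest.approx(-4.0123479144, abs=1e-6)
        assert t_test(fit, 1).statistic == pytest.approx(0.9811788360, abs=1e-4)


class TestTTest:
    def test_degrees_of_freedom_n_minus_p(self, rng):
        problem = make_problem(rng, n=16, p=3)  # intercept + group + covariate
        fit = fit_random_effects_ml(problem)
        assert t_test(fit, 1).df == 13

    def test_zero_coefficient_gives_p_one(self):
        fit = FitResult(
            beta_hat=np.array([1.0, 0.0]),
            beta_cov=np.eye(2),
            tau2_hat=0.1,
            loglik=0.0,
            n=12,
            p=2,
            converged=True,
            iterations=1,
        )
        res = t_test(fit, 1)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_hand_built_pvalue(self):
        """beta=2, se=1, df=10: p = 2 P(T10 > 2) ~= 0.0734."""
        fit = FitResult(
            beta_hat=np.array([0.0, 2.0]),
            beta_cov=np.eye(2),
            tau2_hat=0.1,
            loglik=0.0,
            n=12,
            p=2,
            converged=True,
            iterations=1,
        )
        assert t_test(fit, 1).pvalue == pytest.approx(0.0734, abs=2e-4)

    def test_out_of_range_coefficient(self, rng):
        fit = fit_random_effects_ml(make_problem(rng))
        with pytest.raises(IndexError):
            t_test(fit, 5)


class TestLikelihoodRatio:
    def test_orthogonal_column_gives_near_zero_lr(self, rng):
        """A tested column carrying no signal and orthogonal to the fit
        residuals contributes (almost) nothing to the likelihood."""
        n = 24
        problem = make_problem(rng, n=n, tau2=0.05)
        lr, lf, l0 = likelihood_ratio(problem)
        assert lr >= 0.0
        assert lf >= l0 - 1e-9

    def test_loglik_components_match_oracle(self, rng):
        problem = make_problem(rng, n=12)
        lr, lf, l0 = likelihood_ratio(problem)
        assert lf == pytest.approx(grid_search_oracle(problem)[0], abs=1e-4)
        null = MetaRegressionProblem(
            problem.log_y,
            problem.within_var,
            np.delete(problem.design, 1, axis=1),
            0,
        )
        assert l0 == pytest.approx(grid_search_oracle(null)[0], abs=1e-4)
        assert lr == pytest.approx(2 * (lf - l0))

    def test_null_lr_approximately_chi2(self, rng):
        """Under the null at a comfortable n the LR statistic is ~ chi2(1)."""
        n = 50
        lrs = []
        for _ in range(300):
            problem = make_problem(rng, n=n, tau2=0.06)
            lrs.append(likelihood_ratio(problem)[0])
        assert np.mean(lrs) == pytest.approx(1.0, abs=0.2)
        assert stats.kstest(lrs, stats.chi2(df=1).cdf).pvalue > 0.01


class TestBartlett:
    def test_deterministic_under_seed(self, rng):
        problem = make_problem(rng, n=10)
        a = bartlett_correction_factor(problem, seed=42, n_boot=300)
        b = bartlett_correction_factor(problem, seed=42, n_boot=300)
        assert a == b

    def test_bcf_near_one_at_large_n(self, rng):
        """E[LR] -> 1 under the null as n grows, so BCF -> 1."""
        problem = make_problem(rng, n=120, tau2=0.05)
        bcf = bartlett_correction_factor(problem, seed=3, n_boot=2000)
        assert bcf == pytest.approx(1.0, abs=0.15)

    def test_closed_form_not_implemented(self, rng):
        with pytest.raises(NotImplementedError):
            bartlett_correction_factor(make_problem(rng), method="closed_form", seed=1)

    def test_invalid_method_rejected(self, rng):
        with pytest.raises(ValueError):
            bartlett_correction_factor(make_problem(rng), method="jackknife", seed=1)

    def test_small_nboot_rejected(self, rng):
        with pytest.raises(ValueError):
            bartlett_correction_factor(make_problem(rng), n_boot=50, seed=1)


class TestBclrTest:
    def test_zero_lr(self):
        res = bclr_test(0.0, 1.0)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_chi2_quantile(self):
        assert bclr_test(3.841459, 1.0).pvalue == pytest.approx(0.05, abs=1e-5)

    def test_corrected_statistic(self):
        res = bclr_test(5.0, 0.8)
        assert res.statistic == pytest.approx(4.0)
        assert res.pvalue == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-12)
        assert res.pvalue == pytest.approx(0.0455, abs=2e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bclr_test(-1.0, 1.0)
        with pytest.raises(ValueError):
            bclr_test(1.0, 0.0)


class TestInvariances:
    def test_shift_y_moves_only_intercept(self, rng):
        problem = make_problem(rng, n=18, p=3)
        fit = fit_random_effects_ml(problem)
        shifted = MetaRegressionProblem(
            problem.log_y + 5.0, problem.within_var, problem.design, 1
        )
        fit2 = fit_random_effects_ml(shifted)
        assert fit2.beta_hat[0] == pytest.approx(fit.beta_hat[0] + 5.0, abs=1e-7)
        np.testing.assert_allclose(fit2.beta_hat[1:], fit.beta_hat[1:], atol=1e-7)
        assert fit2.tau2_hat == pytest.approx(fit.tau2_hat, abs=1e-7)

    def test_covariate_rescaling_leaves_pvalues_unchanged(self, rng):
        problem = make_problem(rng, n=18, p=3)
        c = 7.5
        design2 = problem.design.copy()
        design2[:, 2] *= c
        scaled = MetaRegressionProblem(problem.log_y, problem.within_var, design2, 1)
        f1, f2 = fit_random_effects_ml(problem), fit_random_effects_ml(scaled)
        assert f2.beta_hat[2] == pytest.approx(f1.beta_hat[2] / c, rel=1e-6)
        assert t_test(f2, 1).pvalue == pytest.approx(t_test(f1, 1).pvalue, abs=1e-8)
        lr1 = likelihood_ratio(problem)[0]
        lr2 = likelihood_ratio(scaled)[0]
        assert bclr_test(lr2, 1.0).pvalue == pytest.approx(
            bclr_test(lr1, 1.0).pvalue, abs=1e-8
        )
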