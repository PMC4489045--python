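"""Random-effects meta-regression for one isoform.

The model for sample i is

    log(Y_i) = x_i' beta + u_i + e_i,
    u_i ~ N(0, sigma2_i)   (known estimation-uncertainty variance),
    e_i ~ N(0, tau2)       (between-sample heterogeneity),

with u_i and e_i independent, so marginally log(Y_i) ~ N(x_i' beta,
sigma2_i + tau2).  For fixed tau2 the profile likelihood is maximized by
weighted least squares with weights 1/(sigma2_i + tau2); tau2 itself is
estimated by maximum likelihood with a bounded one-dimensional search.

Two tests of a single coefficient (normally the group effect beta_1) are
provided: a Wald t-test on n - p degrees of freedom, and a Bartlett-corrected
likelihood-ratio test whose correction factor is calibrated by parametric
bootstrap under the fitted null so that E[BCF * LR] = 1 (df = 1).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .preprocess import MetaRegressionProblem

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


class ConvergenceError(RuntimeError):
    """The likelihood optimization did not reach a usable optimum."""


class SingularDesignError(np.linalg.LinAlgError):
    """The weighted normal equations are singular."""


@dataclass
class FitResult:
    beta_hat: np.ndarray
    beta_cov: np.ndarray
    tau2_hat: float
    loglik: float
    n: int
    p: int
    converged: bool
    iterations: int


@dataclass
class TestResult:
    statistic: float
    df: float
    pvalue: float
    test_name: str
    bcf: Optional[float] = None
    loglik_null: Optional[float] = None


def profile_loglik(problem: MetaRegressionProblem, tau2: float):
    """Profile log-likelihood at a fixed heterogeneity variance.

    Returns ``(loglik, beta_hat, beta_cov)`` where ``beta_hat`` is the WLS
    solution with weights 1/(sigma2_i + tau2), ``beta_cov`` the inverse of the
    weighted normal-equations matrix, and ``loglik`` the exact Gaussian
    log-likelihood at (beta_hat, tau2).
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    X, y = problem.design, problem.log_y
    v = problem.within_var + tau2
    if np.any(v <= 0):
        raise ValueError("all marginal variances sigma2_i + tau2 must be positive")
    w = 1.0 / v
    Xw = X * w[:, None]
    A = Xw.T @ X
    try:
        beta = np.linalg.solve(A, Xw.T @ y)
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(str(exc)) from exc
    resid = y - X @ beta
    loglik = -0.5 * float(np.sum(np.log(2.0 * np.pi * v) + resid**2 * w))
    return loglik, beta, cov


def _tau2_upper_bound(y: np.ndarray) -> float:
    return max(10.0 * float(np.var(y)), 1e-6)


def fit_random_effects_ml(problem: MetaRegressionProblem) -> FitResult:
    """Maximum-likelihood fit, profiling the likelihood over tau2 >= 0.

    A bounded Brent search on [0, 10 * var(y)] locates the optimum
    deterministically; the tau2 = 0 boundary is checked explicitly and wins
    ties, so boundary solutions are reported as exactly zero.
    """
    y = problem.log_y
    hi = _tau2_upper_bound(y)
    bad = np.inf

    def neg(t2: float) -> float:
        try:
            return -profile_loglik(problem, max(t2, 0.0))[0]
        except (ValueError, SingularDesignError):
            return bad

    res = minimize_scalar(
        neg, bounds=(0.0, hi), method="bounded",
        options={"xatol": 1e-10, "maxiter": 1000},
    )
    tau2 = float(max(res.x, 0.0))
    best = neg(tau2)
    zero = neg(0.0)
    if zero <= best + 1e-12:
        tau2, best = 0.0, zero
    if not np.isfinite(best):
        raise ConvergenceError("likelihood is not finite anywhere in the search range")
    loglik, beta, cov = profile_loglik(problem, tau2)
    return FitResult(
        beta_hat=beta,
        beta_cov=cov,
        tau2_hat=tau2,
        loglik=loglik,
        n=problem.n,
        p=problem.p,
        converged=bool(getattr(res, "success", True)),
        iterations=int(getattr(res, "nfev", 0)),
    )


def t_test(fit: FitResult, coef_index: int) -> TestResult:
    """Wald t-test of one coefficient on n - p degrees of freedom.

    With an intercept, a group indicator and one covariate this is the
    familiar n - 3.
    """
    if not fit.converged:
        raise ConvergenceError("cannot test an unconverged fit")
    if not 0 <= coef_index < fit.p:
        raise IndexError(f"coef_index {coef_index} out of range for p={fit.p}")
    se = float(np.sqrt(fit.beta_cov[coef_index, coef_index]))
    stat = float(fit.beta_hat[coef_index] / se)
    df = fit.n - fit.p
    pvalue = float(2.0 * stats.t.sf(abs(stat), df))
    return TestResult(statistic=stat, df=df, pvalue=pvalue, test_name="t")


def _null_problem(problem: MetaRegressionProblem, coef_index: int) -> MetaRegressionProblem:
    if coef_index == 0:
        raise ValueError("cannot drop the intercept column")
    design0 = np.delete(problem.design, coef_index, axis=1)
    return MetaRegressionProblem(
        log_y=problem.log_y,
        within_var=problem.within_var,
        design=design0,
        coef_of_interest=0,
    )


def likelihood_ratio(problem: MetaRegressionProblem, coef_index: int | None = None):
    """LR statistic 2(l - l0) for dropping one design column.

    Both the full and the null model re-estimate tau2.  Small negative values
    (within 1e-6, optimizer noise) are clipped to zero; larger ones raise
    :class:`ConvergenceError`.
    """
    ci = problem.coef_of_interest if coef_index is None else coef_index
    full = fit_random_effects_ml(problem)
    null = fit_random_effects_ml(_null_problem(problem, ci))
    if not (full.converged and null.converged):
        raise ConvergenceError("full or null fit did not converge")
    lr = 2.0 * (full.loglik - null.loglik)
    if lr < -1e-6:
        raise ConvergenceError(f"negative LR statistic {lr:.3g} beyond tolerance")
    return max(lr, 0.0), full.loglik, null.loglik


# ---------------------------------------------------------------------------
# vectorized machinery for the parametric bootstrap


def _batch_loglik(X: np.ndarray, s2: np.ndarray, Y: np.ndarray, tau2: np.ndarray):
    """Profile log-likelihood for B datasets sharing X and s2.

    ``Y`` is (n, B) and ``tau2`` is (B,); each column gets its own WLS fit.
    """
    v = s2[:, None] + tau2[None, :]
    w = 1.0 / v
    A = np.einsum("ni,nb,nj->bij", X, w, X)
    b = np.einsum("ni,nb,nb->bi", X, w, Y)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    resid = Y - X @ beta.T
    return -0.5 * (np.log(2.0 * np.pi * v).sum(axis=0) + (resid**2 * w).sum(axis=0))


def _batch_max_loglik(X: np.ndarray, s2: np.ndarray, Y: np.ndarray, n_iter: int = 40):
    """Per-column maximized log-likelihood via vectorized golden-section
    search over tau2, with the tau2 ~ 0 boundary checked explicitly."""
    B = Y.shape[1]
    lo0 = 0.0 if s2.min() > 0 else 1e-12
    a = np.full(B, lo0)
    b = np.maximum(10.0 * Y.var(axis=0), 1e-6)
    best = _batch_loglik(X, s2, Y, a)
    for _ in range(n_iter):
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        fc = _batch_loglik(X, s2, Y, c)
        fd = _batch_loglik(X, s2, Y, d)
        take = fc > fd
        b = np.where(take, d, b)
        a = np.where(take, a, c)
        best = np.maximum(best, np.maximum(fc, fd))
    return np.maximum(best, _batch_loglik(X, s2, Y, 0.5 * (a + b)))


def bartlett_correction_factor(
    problem: MetaRegressionProblem,
    tau2_hat: float | None = None,
    coef_index: int | None = None,
    method: str = "bootstrap",
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Bartlett correction factor for the single-coefficient LR test.

    ``method="bootstrap"`` simulates ``n_boot`` datasets from the fitted null
    model (null-model WLS mean, marginal variances sigma2_i + tau2_hat),
    recomputes the LR statistic for each, and returns ``1 / mean(LR*)`` - the
    factor that makes the corrected statistic's null mean equal its single
    degree of freedom.  ``tau2_hat`` defaults to the null-model ML estimate.

    ``method="closed_form"`` (an analytic small-sample expansion) is not
    implemented; the bootstrap is the supported estimator.
    """
    if method == "closed_form":
        raise NotImplementedError(
            "closed-form Bartlett factor is not implemented; use method='bootstrap'"
        )
    if method != "bootstrap":
        raise ValueError(f"unknown BCF method {method!r}")
    if n_boot < 200:
        raise ValueError("bootstrap BCF needs n_boot >= 200")
    if seed is None:
        raise ValueError("bootstrap BCF needs an explicit seed for reproducibility")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ci = problem.coef_of_interest if coef_index is None else coef_index
    null = _null_problem(problem, ci)
    if tau2_hat is None:
        tau2_hat = fit_random_effects_ml(null).tau2_hat
    if tau2_hat < 0:
        raise ValueError("tau2_hat must be non-negative")
    t2 = tau2_hat if (tau2_hat > 0 or null.within_var.min() > 0) else 1e-12
    _, beta0, _ = profile_loglik(null, t2)

    n = problem.n
    mu = null.design @ beta0
    sd = np.sqrt(problem.within_var + tau2_hat)
    Ystar = mu[:, None] + rng.standard_normal((n, n_boot)) * sd[:, None]
    ll_full = _batch_max_loglik(problem.design, problem.within_var, Ystar)
    ll_null = _batch_max_loglik(null.design, problem.within_var, Ystar)
    lr = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
    mean_lr = float(lr.mean())
    if mean_lr <= 0:
        raise ConvergenceError("bootstrap LR statistics are degenerate (mean <= 0)")
    return 1.0 / mean_lr


def bclr_test(lr: float, bcf: float) -> TestResult:
    """Bartlett-corrected LR test: statistic BCF * LR against chi2(1)."""
    if not (np.isfinite(lr) and np.isfinite(bcf)):
        raise ValueError("lr and bcf must be finite")
    if lr < 0 or bcf <= 0:
        raise ValueError("lr must be >= 0 and bcf > 0")
    stat = float(bcf * lr)
    return TestResult(
        statistic=stat,
        df=1,
        pvalue=float(stats.chi2.sf(stat, df=1)),
        test_name="bclr",
        bcf=float(bcf),
    )
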