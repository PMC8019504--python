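"""Hypothesis tests for the treatment effect in a balanced-CRT mixed model.

Implements the Wald test t* = beta1_hat / SE(beta1_hat) under four
degrees-of-freedom rules (residual, between-within, Satterthwaite — with
Kenward-Roger as a documented alias — and infinite, i.e. 't as z'), the
likelihood ratio test against chi-square with 1 DF, the two-sample t-test on
cluster means, and the design-effect utility.

All tests are two-sided.  Every statistic depends on the data only through
ratios of mean squares, so multiplying the outcomes by any c > 0 leaves
every (statistic, DF, p-value) triple unchanged — Type I error behaviour
depends on the variance components only through their relative size (the
ICC), not their absolute scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dgp import NullDataset
from .lmm import FitResult, anova_decompose

__all__ = [
    "TestResult",
    "WALD_METHODS",
    "ALL_METHODS",
    "df_residual",
    "df_between_within",
    "df_satterthwaite",
    "wald_test",
    "lrt",
    "cluster_means_ttest",
    "run_all_tests",
    "design_effect",
    "design_effect_se_multiplier",
]

#: Wald DF rule labels, ordered from smallest to largest DF (hence from most
#: to least conservative p-value at a fixed statistic).
WALD_METHODS = ("wald_between_within", "wald_satterthwaite", "wald_residual", "wald_z")

ALL_METHODS = WALD_METHODS + ("lrt", "cluster_means_ttest")


@dataclass(frozen=True)
class TestResult:
    """One two-sided hypothesis test of H0: beta1 = 0.

    ``df`` is a positive real for t-reference tests, ``math.inf`` for the
    normal-reference Wald test, and 1 for the likelihood ratio test
    (chi-square reference).
    """

    statistic: float
    df: float
    p_value: float
    method: str


def df_residual(K: int, N: int) -> int:
    """Residual DF: total observations minus the p = 2 fixed effects."""
    if K * N <= 2:
        raise ValueError(f"need K*N > 2 observations, got {K * N}")
    return K * N - 2


def df_between_within(K: int) -> int:
    """Between-within DF: residual DF partitioned at the cluster level, K - 2."""
    if K <= 2:
        raise ValueError(f"need K > 2 clusters, got {K}")
    return K - 2


def df_satterthwaite(fit: FitResult, K: int, N: int) -> float:
    """Satterthwaite DF for the treatment effect from a full-model REML fit.

    DF = 2 * Var(beta1_hat)^2 / Var[Var(beta1_hat)], with the variance of
    the variance obtained by the delta method from the inverse expected REML
    information of (sigma_b2, sigma2).  Var(beta1_hat) = g(sigma_b2, sigma2)
    = 4 (sigma2 + N sigma_b2) / (K N); the information is assembled in the
    orthogonal (sigma2, tau) parametrization, where the restricted
    likelihood splits into independent chi-square pieces on K(N-1) and K-2
    DF, and mapped back through the Jacobian.  In this balanced design the
    result collapses to K - 2 for interior fits; for boundary fits the model
    degenerates to an iid regression and the same construction (single
    parameter sigma2, K*N - 2 error DF) gives K*N - 2.
    """
    if fit.null_model:
        raise ValueError("Satterthwaite DF is undefined for null-model fits")
    if fit.method != "REML":
        raise ValueError("Satterthwaite DF requires a REML fit")
    n = K * N
    var_b1 = 4.0 * (fit.sigma2_hat + N * fit.sigma_b2_hat) / n
    # gradient of g with respect to (sigma_b2, sigma2)
    grad = np.array([4.0 / K, 4.0 / n])
    if fit.boundary:
        # constrained model: only sigma2 is free, on n - 2 residual DF
        var_sigma2 = 2.0 * fit.sigma2_hat**2 / (n - 2)
        var_var_b1 = grad[1] ** 2 * var_sigma2
    else:
        sigma2 = fit.sigma2_hat
        tau = fit.sigma2_hat + N * fit.sigma_b2_hat
        info_st = np.diag([K * (N - 1) / (2.0 * sigma2**2), (K - 2) / (2.0 * tau**2)])
        jac = np.array([[0.0, 1.0], [N, 1.0]])  # (sigma2, tau) <- (sigma_b2, sigma2)
        info = jac.T @ info_st @ jac
        cov = np.linalg.inv(info)
        var_var_b1 = float(grad @ cov @ grad)
    return 2.0 * var_b1**2 / var_var_b1


def wald_test(fit: FitResult, df_method: str, K: int, N: int) -> TestResult:
    """Two-sided Wald test of the treatment effect from a full-model REML fit.

    ``df_method`` is one of ``wald_residual``, ``wald_between_within``,
    ``wald_satterthwaite``, ``wald_kenward_roger`` or ``wald_z``.
    Kenward-Roger is an alias of Satterthwaite: with a single cluster-level
    treatment effect and a random intercept, the Kenward-Roger DF equal the
    Satterthwaite DF (no covariance inflation is applied; the alias is not
    valid for more general designs).
    """
    if fit.null_model:
        raise ValueError("Wald test requires the full-model fit")
    t_star = fit.t_statistic
    if df_method == "wald_residual":
        df: float = df_residual(K, N)
        p = 2.0 * stats.t.sf(abs(t_star), df)
    elif df_method == "wald_between_within":
        df = df_between_within(K)
        p = 2.0 * stats.t.sf(abs(t_star), df)
    elif df_method in ("wald_satterthwaite", "wald_kenward_roger"):
        df = df_satterthwaite(fit, K, N)
        p = 2.0 * stats.t.sf(abs(t_star), df)
    elif df_method == "wald_z":
        df = math.inf
        p = 2.0 * stats.norm.sf(abs(t_star))
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    return TestResult(statistic=float(t_star), df=float(df), p_value=float(p), method=df_method)


def lrt(fit_null: FitResult, fit_full: FitResult) -> TestResult:
    """Likelihood ratio test lambda = -2 (l0 - l1) against chi-square, 1 DF.

    Both fits must be by full ML on the same data: REML likelihoods are not
    comparable across fixed-effect structures and are rejected.  The
    statistic is clamped below at zero (it can go fractionally negative only
    through floating-point error).
    """
    if fit_null.method != "ML" or fit_full.method != "ML":
        raise ValueError("LRT requires ML fits; REML likelihoods are not comparable")
    if not fit_null.null_model or fit_full.null_model:
        raise ValueError("lrt expects (null-model fit, full-model fit) in that order")
    lam = -2.0 * (fit_null.loglik - fit_full.loglik)
    lam = max(lam, 0.0)
    p = stats.chi2.sf(lam, df=1)
    return TestResult(statistic=float(lam), df=1.0, p_value=float(p), method="lrt")


def cluster_means_ttest(data: NullDataset, validate: bool = True) -> TestResult:
    """Pooled two-sample t-test on the K cluster means, DF = K - 2.

    Valid here because the design is balanced with no covariates; it is
    almost equivalent to the between-within Wald test, differing only in
    that the mixed model estimates two variance components while the t-test
    estimates their sum.
    """
    if validate:
        data.validate()
    K = data.K
    if K < 4:
        raise ValueError("need at least 2 clusters per arm")
    means = data.cluster_means()
    half = K // 2
    if np.ptp(means[:half]) == 0.0 and np.ptp(means[half:]) == 0.0:
        # degenerate zero-variance case: no evidence against H0 when the
        # arm means coincide, overwhelming evidence otherwise
        diff = means[half:].mean() - means[:half].mean()
        t_star = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t_star, p = stats.ttest_ind(means[half:], means[:half], equal_var=True)
    return TestResult(
        statistic=float(t_star), df=float(K - 2), p_value=float(p), method="cluster_means_ttest"
    )


def run_all_tests(
    data: NullDataset,
    fit_reml_full: FitResult,
    fit_ml_null: FitResult,
    fit_ml_full: FitResult,
    validate: bool = False,
) -> dict[str, TestResult]:
    """All six tests of the treatment effect on one dataset, keyed by label."""
    K, N = data.K, data.N
    out = {m: wald_test(fit_reml_full, m, K, N) for m in WALD_METHODS}
    out["lrt"] = lrt(fit_ml_null, fit_ml_full)
    out["cluster_means_ttest"] = cluster_means_ttest(data, validate=validate)
    return out


def design_effect(n: int, rho: float) -> float:
    """Design effect (n - 1) rho + 1: variance inflation from clustering.

    ``n`` is the number of subjects per cluster and ``rho`` the intraclass
    correlation.  Multiplies the sampling variance of the treatment-effect
    estimator relative to an unclustered design of the same size.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    return (n - 1) * rho + 1.0


def design_effect_se_multiplier(n: int, rho: float) -> float:
    """Square root of the design effect: the standard-error multiplier."""
    return math.sqrt(design_effect(n, rho))
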