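"""Random-intercept linear mixed model fitting for balanced two-arm CRTs.

The analysis model is

    y_ij = beta0 + beta1 * x_i + b_i + e_ij,
    b_i ~ N(0, sigma_b2),  e_ij ~ N(0, sigma2),

with a single cluster-level treatment indicator x_i.  In this balanced
design the likelihood factorizes through a one-way ANOVA decomposition:
writing tau = sigma2 + N*sigma_b2 for the variance of a cluster total's
mean direction,

    -2 loglik = const + K(N-1) log sigma2 + K log tau + SSW/sigma2 + SSB/tau

where SSW is the pooled within-cluster sum of squares and SSB is N times
the sum of squared deviations of cluster means from their (GLS-fitted)
cluster-level means — arm means for the full model, the grand mean for the
null model.  Both ML and REML therefore have closed-form maximizers, with
the nonnegativity constraint on sigma_b2 handled by truncation at the
boundary and a constrained refit of the residual variance (mirroring what
standard mixed-model software does).

GLS fixed-effect estimates do not depend on the variance components here:
for any weights, beta1_hat is the difference of arm means.  ML and REML thus
share identical fixed-effect estimates and differ only in the variance
components and the likelihood value.

An independent numeric oracle (:func:`numeric_oracle_fit`) maximizes the
same criteria by dense-matrix evaluation and bounded scalar optimization
over theta = sigma_b2/sigma2, sharing no closed forms with the main path;
it exists for verification and is never used by the simulation pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dgp import NullDataset

__all__ = [
    "ANOVADecomposition",
    "FitResult",
    "FitConvergenceError",
    "anova_decompose",
    "fit_reml",
    "fit_ml",
    "numeric_oracle_fit",
]

LOG_2PI = math.log(2.0 * math.pi)


class FitConvergenceError(RuntimeError):
    """Raised when a numeric optimizer fails to converge.

    Carries the final gradient norm (or bracket width) so the failure is
    diagnosable rather than silent.
    """

    def __init__(self, message: str, gradient_norm: float):
        super().__init__(f"{message} (final gradient norm {gradient_norm:.3e})")
        self.gradient_norm = gradient_norm


@dataclass(frozen=True)
class ANOVADecomposition:
    """Sufficient statistics of the balanced design.

    ``msw`` is the within-cluster mean square on K(N-1) degrees of freedom;
    ``msb`` is N times the between-cluster (within-arm) mean square of
    cluster means, on K-2 degrees of freedom.  ``ssw``/``ssb`` are the
    corresponding sums of squares.
    """

    K: int
    N: int
    mean_ctrl: float
    mean_trt: float
    ssw: float
    ssb: float

    @property
    def df_within(self) -> int:
        return self.K * (self.N - 1)

    @property
    def df_between(self) -> int:
        return self.K - 2

    @property
    def msw(self) -> float:
        return self.ssw / self.df_within

    @property
    def msb(self) -> float:
        return self.ssb / self.df_between


@dataclass(frozen=True)
class FitResult:
    """State of a fitted random-intercept model.

    ``boundary`` is True iff the unconstrained between-cluster variance
    estimate was negative and was truncated to zero (with the residual
    variance refit under the constraint).  ``null_model`` is True for the
    intercept-only comparison model used by the likelihood ratio test;
    ``beta1_hat`` and ``se_beta1`` are None in that case.
    """

    beta0_hat: float
    beta1_hat: float | None
    sigma_b2_hat: float
    sigma2_hat: float
    se_beta1: float | None
    loglik: float
    method: str  # "REML" or "ML"
    boundary: bool
    null_model: bool = False

    @property
    def t_statistic(self) -> float:
        """Wald statistic t* = beta1_hat / SE(beta1_hat)."""
        if self.null_model:
            raise ValueError("null-model fit has no treatment effect")
        return self.beta1_hat / self.se_beta1

    def summary(self) -> str:
        """Aligned plain-text fit summary."""
        lines = [
            f"method          {self.method}{' (null model)' if self.null_model else ''}",
            f"beta0_hat       {self.beta0_hat: .6g}",
        ]
        if not self.null_model:
            lines += [
                f"beta1_hat       {self.beta1_hat: .6g}",
                f"SE(beta1_hat)   {self.se_beta1: .6g}",
            ]
        lines += [
            f"sigma_b2_hat    {self.sigma_b2_hat: .6g}{'  (boundary)' if self.boundary else ''}",
            f"sigma2_hat      {self.sigma2_hat: .6g}",
            f"loglik          {self.loglik: .10g}",
        ]
        return "\n".join(lines)


def anova_decompose(data: NullDataset, validate: bool = True) -> ANOVADecomposition:
    """One-way ANOVA sufficient statistics of a balanced two-arm dataset."""
    if validate:
        data.validate()
    K, N = data.K, data.N
    ymat = data.y.reshape(K, N)
    cl_means = ymat.mean(axis=1)
    ssw = float(((ymat - cl_means[:, None]) ** 2).sum())
    half = K // 2
    mean_ctrl = float(cl_means[:half].mean())
    mean_trt = float(cl_means[half:].mean())
    dev = cl_means.copy()
    dev[:half] -= mean_ctrl
    dev[half:] -= mean_trt
    ssb = float(N * (dev**2).sum())
    return ANOVADecomposition(K=K, N=N, mean_ctrl=mean_ctrl, mean_trt=mean_trt, ssw=ssw, ssb=ssb)


def _reml_loglik(K: int, N: int, ssw: float, ssb: float, sigma2: float, tau: float) -> float:
    # Restricted log-likelihood with fixed effects profiled out, including
    # all constants and the log|X' V^-1 X| term, so values are comparable
    # across implementations that use the same convention.
    # log|V| = K(N-1) log sigma2 + K log tau;
    # log|X' V^-1 X| = 2 log(N/tau) + log(K^2/4) for the two-column design.
    n = K * N
    val = (
        (n - 2) * LOG_2PI
        + K * (N - 1) * math.log(sigma2)
        + (K - 2) * math.log(tau)
        + 2.0 * math.log(N)
        + math.log(K * K / 4.0)
        + ssw / sigma2
        + ssb / tau
    )
    return -0.5 * val


def _ml_loglik(K: int, N: int, ssw: float, ssb_fit: float, sigma2: float, tau: float) -> float:
    n = K * N
    val = (
        n * LOG_2PI
        + K * (N - 1) * math.log(sigma2)
        + K * math.log(tau)
        + ssw / sigma2
        + ssb_fit / tau
    )
    return -0.5 * val


def fit_reml(data: NullDataset, validate: bool = True) -> FitResult:
    """REML fit of the full analysis model on balanced data, in closed form.

    Interior solution: sigma2_hat = MSW, sigma_b2_hat = (MSB - MSW)/N.  When
    MSB < MSW the unconstrained solution is negative, so sigma_b2 is
    truncated to zero and sigma2 refit as the pooled residual variance about
    the arm means (divisor K*N - 2); ``boundary`` is flagged.  The standard
    error of the treatment effect is sqrt(4 * (sigma2 + N*sigma_b2) / (K*N)).
    """
    d = anova_decompose(data, validate=validate)
    K, N = d.K, d.N
    beta1 = d.mean_trt - d.mean_ctrl
    if d.msb >= d.msw:
        sigma2 = d.msw
        sigma_b2 = (d.msb - d.msw) / N
        boundary = False
    else:
        sigma_b2 = 0.0
        sigma2 = (d.ssw + d.ssb) / (K * N - 2)
        boundary = True
    tau = sigma2 + N * sigma_b2
    se_beta1 = math.sqrt(4.0 * tau / (K * N))
    loglik = _reml_loglik(K, N, d.ssw, d.ssb, sigma2, tau)
    return FitResult(
        beta0_hat=d.mean_ctrl,
        beta1_hat=beta1,
        sigma_b2_hat=sigma_b2,
        sigma2_hat=sigma2,
        se_beta1=se_beta1,
        loglik=loglik,
        method="REML",
        boundary=boundary,
    )


def fit_ml(data: NullDataset, include_treatment: bool = True, validate: bool = True) -> FitResult:
    """ML fit of the full (or intercept-only) model on balanced data.

    The Gaussian log-likelihood is maximized over (beta, sigma_b2 >= 0,
    sigma2 > 0) with fixed effects profiled out by GLS — which in this
    balanced design are the arm means (full model) or the grand mean (null
    model) for any variance weights.  Interior maximizer: sigma2_hat =
    SSW / (K(N-1)), tau_hat = SSB_fit / K; boundary handled by truncation
    and a constrained refit exactly as in :func:`fit_reml`.
    """
    d = anova_decompose(data, validate=validate)
    K, N = d.K, d.N
    n = K * N
    if include_treatment:
        ssb_fit = d.ssb
        beta0 = d.mean_ctrl
        beta1 = d.mean_trt - d.mean_ctrl
    else:
        grand = 0.5 * (d.mean_ctrl + d.mean_trt)  # balanced arms
        # SSB about the grand mean = SSB about arm means + N * K * (arm offsets)^2
        half = K // 2
        ssb_fit = d.ssb + N * half * ((d.mean_ctrl - grand) ** 2 + (d.mean_trt - grand) ** 2)
        beta0 = grand
        beta1 = None

    sigma2_unc = d.ssw / (K * (N - 1))
    tau_unc = ssb_fit / K
    if tau_unc >= sigma2_unc:
        sigma2 = sigma2_unc
        sigma_b2 = (tau_unc - sigma2_unc) / N
        boundary = False
    else:
        sigma_b2 = 0.0
        sigma2 = (d.ssw + ssb_fit) / n
        boundary = True
    tau = sigma2 + N * sigma_b2
    se_beta1 = math.sqrt(4.0 * tau / n) if include_treatment else None
    loglik = _ml_loglik(K, N, d.ssw, ssb_fit, sigma2, tau)
    return FitResult(
        beta0_hat=beta0,
        beta1_hat=beta1,
        sigma_b2_hat=sigma_b2,
        sigma2_hat=sigma2,
        se_beta1=se_beta1,
        loglik=loglik,
        method="ML",
        boundary=boundary,
        null_model=not include_treatment,
    )


def numeric_oracle_fit(
    data: NullDataset,
    criterion: str = "REML",
    include_treatment: bool = True,
) -> FitResult:
    """Brute-force fit by dense-matrix likelihood and 1-D bounded optimization.

    Profiles the fixed effects (GLS) and the residual variance at each value
    of theta = sigma_b2 / sigma2, then minimizes the profiled deviance over
    theta in [0, 1e8] by bounded scalar search (tolerance 1e-10 on theta).
    Shares no closed forms with :func:`fit_reml` / :func:`fit_ml`; intended
    for verification on small fixtures only (cost is O((K*N)^3) per
    evaluation).
    """
    if criterion not in ("REML", "ML"):
        raise ValueError(f"criterion must be 'REML' or 'ML', got {criterion!r}")
    data.validate()
    K, N = data.K, data.N
    n = K * N
    y = np.asarray(data.y, dtype=float)
    if include_treatment:
        X = np.column_stack([np.ones(n), np.asarray(data.arm, dtype=float)])
    else:
        X = np.ones((n, 1))
    p = X.shape[1]
    Z = (data.cluster[:, None] == np.arange(1, K + 1)[None, :]).astype(float)
    ZZt = Z @ Z.T
    dof = n - p if criterion == "REML" else n

    def profiled(theta):
        # complex-safe so the deviance derivative is available by complex step
        W = np.linalg.inv(np.eye(n) + theta * ZZt)  # V = sigma2 * (I + theta ZZ')
        XtW = X.T @ W
        XtWX = XtW @ X
        beta = np.linalg.solve(XtWX, XtW @ y)
        r = y - X @ beta
        rss = r @ W @ r
        sigma2 = rss / dof
        sign, logdet_v0 = np.linalg.slogdet(np.eye(n) + theta * ZZt)
        # slogdet returns log|det|; add log(sign) so the complex-step
        # imaginary part survives
        dev = dof * LOG_2PI + dof * np.log(sigma2) + logdet_v0 + np.log(sign) + rss / sigma2
        if criterion == "REML":
            # log|X'V^-1 X| = log|X'WX| - p log sigma2; the -p log sigma2 is
            # already absorbed by using dof = n - p in the sigma2 terms above
            sign_x, logdet_x = np.linalg.slogdet(XtWX)
            dev += logdet_x + np.log(sign_x)
        return dev, beta, sigma2, XtWX

    res = optimize.minimize_scalar(
        lambda t: profiled(t)[0],
        bounds=(0.0, 1e8),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    if not res.success:
        raise FitConvergenceError("numeric oracle failed to converge", float(res.x))
    theta = float(res.x)

    def dev_deriv(t: float) -> float:
        # complex-step differentiation: exact to machine precision, no
        # subtractive cancellation
        h = 1e-30 * max(t, 1.0)
        return float(np.imag(profiled(t + 1j * h)[0]) / h)

    # polish the derivative-free solution (limited to ~sqrt(eps) by function
    # flatness) with Newton steps on the complex-step derivative
    for _ in range(10):
        if theta <= 0.0:
            break
        d1 = dev_deriv(theta)
        h2 = 1e-6 * max(theta, 1e-6)
        d2 = (dev_deriv(theta + h2) - dev_deriv(theta - h2)) / (2.0 * h2)
        if d2 <= 0.0:
            break
        step = -d1 / d2
        new_theta = max(theta + step, 0.0)
        if abs(new_theta - theta) <= 1e-14 * max(theta, 1.0):
            theta = new_theta
            break
        theta = new_theta
    # the bounded search cannot land exactly on 0; accept the boundary when
    # it is at least as good as the interior candidate
    dev0 = profiled(0.0)[0]
    dev_t = profiled(theta)[0]
    if dev0 <= dev_t + 1e-12:
        theta = 0.0
    dev, beta, sigma2, XtWX = profiled(theta)
    sigma_b2 = theta * sigma2
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    return FitResult(
        beta0_hat=float(beta[0]),
        beta1_hat=float(beta[1]) if include_treatment else None,
        sigma_b2_hat=sigma_b2,
        sigma2_hat=sigma2,
        se_beta1=math.sqrt(float(cov_beta[1, 1])) if include_treatment else None,
        loglik=-0.5 * dev,
        method=criterion,
        boundary=(theta == 0.0),
        null_model=not include_treatment,
    )
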