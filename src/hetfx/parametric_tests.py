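"""Normal-theory tests of variance homogeneity between trial arms.

Under a constant treatment effect the treated-arm outcome is a shifted
copy of the control-arm outcome, so the two arms share a variance.  The
three tests here detect effect heterogeneity as a variance difference,
each through a different normal model:

``t_gamma``
    A location-scale regression: the mean and the *log variance* of the
    outcome are both linear in treatment.  The z-statistic of the
    treatment coefficient in the log-variance model tests homogeneity;
    with no covariates the coefficient is exactly the log of the
    sample-variance ratio.
``t_lr``
    A likelihood-ratio comparison of two-group normal models with free
    means and either free or equal variances (the multiple-group
    structural-equation formulation), referred to chi-squared on 1 df.
``t_beta``
    A random-coefficient (Hildreth–Houck) model in which the treatment
    slope varies across units with variance sigma^2_u, so
    Var[y | A] = A * sigma^2_u + sigma^2_eps.  A Wald z-test of
    sigma^2_u, left unconstrained in sign, tests homogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trial_core import TrialData, TestResult, summarize

_MAX_ITER = 100
_TOL = 1e-12


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge; the message carries the trace."""


def _mean_design(data: TrialData, use_covariates: bool) -> np.ndarray:
    cols = [np.ones(data.n), data.treatment.astype(float)]
    if use_covariates:
        if data.covariates is None:
            raise ValueError("use_covariates=True but the trial has no covariates")
        cols.append(data.covariates)
    return np.column_stack(cols)


def _check_arm_variances(data: TrialData) -> None:
    g = summarize(data)
    if g.s2_0 <= 0.0 or g.s2_1 <= 0.0:
        raise ValueError(
            f"zero within-arm variance (s2_0={g.s2_0}, s2_1={g.s2_1}); "
            "variance-model fits are undefined"
        )


# --------------------------------------------------------------------------
# T_gamma: log-linear variance regression fit by REML scoring
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaFit:
    """Converged location-scale fit: mean coefficients, log-variance
    coefficients, and the Wald pieces for the treatment scale effect."""

    beta: np.ndarray
    gamma0: float
    gamma1: float
    se_gamma1: float
    n_iter: int

    @property
    def z(self) -> float:
        return self.gamma1 / self.se_gamma1


def fit_gamma(data: TrialData, use_covariates: bool = False) -> GammaFit:
    """Fit y ~ N(X beta, exp(g0 + g1*A)) by restricted-likelihood scoring.

    The REML score for gamma uses the leverage-corrected squared
    residuals, so in the saturated case (no covariates) the fitted
    variances are the usual n-1 sample variances and
    exp(gamma1) = s2_1 / s2_0 exactly.
    """
    _check_arm_variances(data)
    X = _mean_design(data, use_covariates)
    Z = np.column_stack([np.ones(data.n), data.treatment.astype(float)])
    y = data.outcome

    gamma = np.array([np.log(np.var(y, ddof=1)), 0.0])
    trace: list[str] = []
    for it in range(1, _MAX_ITER + 1):
        sigma2 = np.exp(Z @ gamma)
        w = 1.0 / sigma2
        xtwx = X.T @ (X * w[:, None])
        beta = np.linalg.solve(xtwx, X.T @ (y * w))
        resid = y - X @ beta
        # weighted hat-matrix diagonal
        h = np.einsum("ij,jk,ik->i", X, np.linalg.inv(xtwx), X) * w
        score = 0.5 * Z.T @ (resid**2 / sigma2 - (1.0 - h))
        info = 0.5 * Z.T @ (Z * (1.0 - h)[:, None])
        step = np.linalg.solve(info, score)
        gamma = gamma + step
        trace.append(f"iter {it}: gamma={gamma}, |step|={np.abs(step).max():.3e}")
        if np.abs(step).max() < _TOL:
            se = float(np.sqrt(np.linalg.inv(info)[1, 1]))
            return GammaFit(
                beta=beta,
                gamma0=float(gamma[0]),
                gamma1=float(gamma[1]),
                se_gamma1=se,
                n_iter=it,
            )
    raise ConvergenceError(
        "REML scoring did not converge in "
        f"{_MAX_ITER} iterations:\n" + "\n".join(trace)
    )


def t_gamma(data: TrialData, use_covariates: bool = False, alpha: float = 0.05) -> TestResult:
    """Heteroscedastic-regression z-test of the treatment scale effect."""
    fit = fit_gamma(data, use_covariates)
    z = fit.z
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(
        test_name="t_gamma",
        statistic=float(z),
        p_value=float(p),
        alpha=alpha,
        settings={
            "gamma1": fit.gamma1,
            "se_gamma1": fit.se_gamma1,
            "use_covariates": use_covariates,
            "n_iter": fit.n_iter,
        },
    )


# --------------------------------------------------------------------------
# T_LR: two-group normal likelihood-ratio test of equal variances
# --------------------------------------------------------------------------

def t_lr(data: TrialData, use_covariates: bool = False, alpha: float = 0.05) -> TestResult:
    """LR test comparing free vs. equal residual variances across arms.

    Both models leave the per-arm means (and covariate slopes, if
    requested) free, so per-arm OLS is the ML mean fit under either
    variance structure and the statistic has the closed form
    ``n0*log(s2p/s2ml_0) + n1*log(s2p/s2ml_1)`` with ML (n-denominator)
    variances and ``s2p`` their count-weighted pooled value.
    """
    _check_arm_variances(data)
    rss = {}
    counts = {}
    for a in (0, 1):
        mask = data.treatment == a
        y = data.outcome[mask]
        if use_covariates:
            if data.covariates is None:
                raise ValueError("use_covariates=True but the trial has no covariates")
            design = np.column_stack([np.ones(mask.sum()), data.covariates[mask]])
        else:
            design = np.ones((int(mask.sum()), 1))
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ coef
        rss[a] = float(r @ r)
        counts[a] = int(mask.sum())
    n0, n1 = counts[0], counts[1]
    s2ml_0, s2ml_1 = rss[0] / n0, rss[1] / n1
    if s2ml_0 <= 0.0 or s2ml_1 <= 0.0:
        raise ValueError("zero residual variance in an arm; LR test undefined")
    s2p = (rss[0] + rss[1]) / (n0 + n1)
    lr = n0 * np.log(s2p / s2ml_0) + n1 * np.log(s2p / s2ml_1)
    lr = max(float(lr), 0.0)  # clip tiny negative rounding
    p = float(stats.chi2.sf(lr, df=1))
    return TestResult(
        test_name="t_lr",
        statistic=lr,
        p_value=p,
        alpha=alpha,
        settings={"use_covariates": use_covariates},
    )


# --------------------------------------------------------------------------
# T_beta: random-coefficient (Hildreth-Houck) Wald test
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaFit:
    """ML fit of the heteroscedastic model Var[y|A] = A*s2_u + s2_eps."""

    beta: np.ndarray
    sigma2_u: float
    sigma2_eps: float
    se_sigma2_u: float
    n_iter: int

    @property
    def z(self) -> float:
        return self.sigma2_u / self.se_sigma2_u


def fit_beta(data: TrialData, use_covariates: bool = False) -> BetaFit:
    """Maximum-likelihood fit of the random-treatment-slope variance model.

    sigma^2_u is unconstrained in sign (it is the treated-minus-control
    ML variance difference in the saturated case); the standard error
    comes from the observed information over all parameters at the
    optimum.
    """
    _check_arm_variances(data)
    X = _mean_design(data, use_covariates)
    A = data.treatment.astype(float)
    y = data.outcome
    g = summarize(data)
    theta = np.array([g.s2ml_1 - g.s2ml_0, g.s2ml_0])  # (s2_u, s2_eps)

    def variances(th):
        return th[1] + A * th[0]

    for it in range(1, _MAX_ITER + 1):
        v = variances(theta)
        w = 1.0 / v
        xtwx = X.T @ (X * w[:, None])
        beta = np.linalg.solve(xtwx, X.T @ (y * w))
        resid = y - X @ beta
        # score and expected information for (s2_u, s2_eps); dV/ds2_u = A, dV/ds2_eps = 1
        r2 = resid**2
        sA = 0.5 * np.sum((r2 / v**2 - w) * A)
        s1 = 0.5 * np.sum(r2 / v**2 - w)
        iAA = 0.5 * np.sum(A / v**2)  # A^2 = A
        i11 = 0.5 * np.sum(1.0 / v**2)
        info = np.array([[iAA, iAA], [iAA, i11]])
        step = np.linalg.solve(info, np.array([sA, s1]))
        # keep both arm variances positive
        scale = 1.0
        while scale > 1e-8:
            cand = theta + scale * step
            if cand[1] > 0 and cand[0] + cand[1] > 0:
                break
            scale *= 0.5
        else:
            raise ConvergenceError("step halving exhausted; variances collapse to zero")
        theta = theta + scale * step
        if np.abs(scale * step).max() < _TOL * max(1.0, np.abs(theta).max()):
            break
    else:
        raise ConvergenceError(f"ML scoring did not converge in {_MAX_ITER} iterations")

    # observed information over (beta, s2_u, s2_eps) at the optimum
    v = variances(theta)
    w = 1.0 / v
    xtwx = X.T @ (X * w[:, None])
    beta = np.linalg.solve(xtwx, X.T @ (y * w))
    resid = y - X @ beta
    r2 = resid**2
    p = X.shape[1]
    J = np.zeros((p + 2, p + 2))
    J[:p, :p] = xtwx
    dv = [A, np.ones(data.n)]
    for k in range(2):
        cross = X.T @ (resid * dv[k] / v**2)
        J[:p, p + k] = cross
        J[p + k, :p] = cross
        for l in range(2):
            J[p + k, p + l] = np.sum((r2 / v**3 - 0.5 / v**2) * dv[k] * dv[l])
    cov = np.linalg.inv(J)
    se = float(np.sqrt(cov[p, p]))
    if not np.isfinite(se):
        raise ConvergenceError("singular observed information at the optimum")
    return BetaFit(
        beta=beta,
        sigma2_u=float(theta[0]),
        sigma2_eps=float(theta[1]),
        se_sigma2_u=se,
        n_iter=it,
    )


def t_beta(data: TrialData, use_covariates: bool = False, alpha: float = 0.05) -> TestResult:
    """Wald z-test of the random-slope variance sigma^2_u (two-sided)."""
    fit = fit_beta(data, use_covariates)
    z = fit.z
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(
        test_name="t_beta",
        statistic=float(z),
        p_value=float(p),
        alpha=alpha,
        settings={
            "sigma2_u": fit.sigma2_u,
            "sigma2_eps": fit.sigma2_eps,
            "se_sigma2_u": fit.se_sigma2_u,
            "use_covariates": use_covariates,
        },
    )
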