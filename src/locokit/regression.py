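"""Curve-fit primitives used across the analyses: ordinary least-squares
linear regression with Pearson R and a two-sided P value, and 3-parameter
logistic (sigmoid) least squares with an R goodness value and delta-method
95% prediction intervals.

For nonlinear fits R is reported as sqrt(max(0, 1 - SS_res / SS_tot)),
the convention used by common curve-fitting software for its nonlinear "R".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["LinearFit", "SigmoidFit", "linear_fit", "sigmoid_fit",
           "logistic3", "sigmoid_prediction_interval"]


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r: float  # signed Pearson correlation
    p: float  # two-sided p-value for slope != 0
    n: int
    slope_ci95: tuple[float, float]
    degenerate: bool = False


@dataclass(frozen=True)
class SigmoidFit:
    a: float  # asymptote
    x0: float  # midpoint
    b: float  # slope parameter
    r: float  # sqrt(1 - SS_res / SS_tot), in [0, 1]
    converged: bool
    n: int
    rss: float
    cov: np.ndarray | None = None
    degenerate: bool = False
    message: str = ""


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares of y on x.

    R is the signed Pearson correlation; P is the two-sided p-value of the
    slope from the t statistic with n - 2 degrees of freedom. A zero-variance
    x yields a flagged degenerate result rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 2:
        raise ValueError("linear_fit needs at least two points")
    if np.ptp(x) == 0:
        return LinearFit(np.nan, np.nan, np.nan, np.nan, n,
                         (np.nan, np.nan), degenerate=True)
    res = stats.linregress(x, y)
    if n > 2 and np.isfinite(res.stderr) and res.stderr > 0:
        tcrit = stats.t.ppf(0.975, n - 2)
        ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
        p = float(res.pvalue)
    else:
        ci = (np.nan, np.nan)
        p = float(res.pvalue) if n > 2 else np.nan
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.rvalue), p, int(n), ci)


def logistic3(x, a, x0, b):
    """3-parameter logistic y = a / (1 + exp(-(x - x0) / b))."""
    return a / (1.0 + np.exp(-(np.asarray(x, dtype=float) - x0) / b))


def sigmoid_fit(x, y, init: tuple[float, float, float] | None = None) -> SigmoidFit:
    """Least-squares fit of the 3-parameter logistic.

    Default initialization: a = max(y), x0 = median(x), b = range(x) / 4.
    Non-convergence is reported in the result, not raised. A constant y
    (SS_tot = 0) yields R = 0 with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("sigmoid_fit needs at least four points")
    if np.ptp(x) == 0:
        raise ValueError("sigmoid_fit needs x to span a nonzero range")

    if init is None:
        init = (float(np.max(y)), float(np.median(x)), float(np.ptp(x)) / 4.0)

    def resid(theta):
        return logistic3(x, *theta) - y

    sol = optimize.least_squares(resid, init, method="lm", xtol=1e-12,
                                 ftol=1e-12, gtol=1e-12, max_nfev=10000)
    a, x0, b = (float(v) for v in sol.x)
    rss = float(np.sum(sol.fun ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    degenerate = sst == 0.0
    r = 0.0 if degenerate else float(np.sqrt(max(0.0, 1.0 - rss / sst)))
    converged = bool(sol.success) and np.isfinite([a, x0, b]).all() and b != 0

    cov = None
    if converged and n > 3:
        # covariance from the Jacobian at the optimum, sigma^2 = rss / (n - p)
        J = sol.jac
        try:
            JTJ_inv = np.linalg.inv(J.T @ J)
            cov = JTJ_inv * (rss / (n - 3))
        except np.linalg.LinAlgError:
            cov = None
    return SigmoidFit(a, x0, b, r, converged, int(n), rss, cov,
                      degenerate=degenerate, message=str(sol.message))


def sigmoid_prediction_interval(fit: SigmoidFit, x_new, level: float = 0.95):
    """Delta-method prediction interval for new observations at ``x_new``.

    Returns (y_hat, lower, upper). Requires a converged fit with covariance.
    """
    x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
    y_hat = logistic3(x_new, fit.a, fit.x0, fit.b)
    if fit.cov is None or fit.n <= 3:
        nanarr = np.full_like(y_hat, np.nan)
        return y_hat, nanarr, nanarr
    a, x0, b = fit.a, fit.x0, fit.b
    z = np.exp(-(x_new - x0) / b)
    denom = (1 + z) ** 2
    # gradients of logistic3 w.r.t. (a, x0, b)
    g = np.stack([
        1.0 / (1 + z),
        -a * z / (b * denom),
        -a * z * (x_new - x0) / (b ** 2 * denom),
    ], axis=1)
    var_mean = np.einsum("ij,jk,ik->i", g, fit.cov, g)
    sigma2 = fit.rss / (fit.n - 3)
    se_pred = np.sqrt(np.maximum(var_mean + sigma2, 0.0))
    tcrit = stats.t.ppf(0.5 + level / 2, fit.n - 3)
    return y_hat, y_hat - tcrit * se_pred, y_hat + tcrit * se_pred
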