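"""Maximum-likelihood fitting of beta distributions on sufficient statistics.

The beta log-likelihood depends on the data only through the (weighted)
means of log(x) and log(1-x), so the fit reduces to a two-parameter
optimisation that is independent of sample size.  Optimisation is a
quasi-Newton (BFGS) search on log-shape parameters with the analytic
gradient, initialised by method-of-moments.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, digamma

from .errors import ValidationError

__all__ = ["beta_mom", "fit_beta_ml", "fit_beta_suffstats"]

_SHAPE_MIN = 1e-4
_SHAPE_MAX = 1e6


def beta_mom(mean: float, var: float) -> tuple[float, float]:
    """Method-of-moments beta shapes for a given mean/variance.

    Falls back to (1, 1) when the variance is incompatible with a beta
    distribution (var >= mean(1-mean)).
    """
    mean = float(np.clip(mean, 1e-6, 1 - 1e-6))
    bound = mean * (1.0 - mean)
    if not np.isfinite(var) or var <= 0 or var >= bound:
        return 1.0, 1.0
    nu = bound / var - 1.0
    return max(mean * nu, _SHAPE_MIN), max((1.0 - mean) * nu, _SHAPE_MIN)


def fit_beta_suffstats(
    mean_log_x: float,
    mean_log_1mx: float,
    init: tuple[float, float],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, float, bool]:
    """Maximise the per-observation beta log-likelihood.

    Parameters are the weighted means of log x and log(1-x); returns
    (alpha, beta, converged).
    """

    def nll(t: np.ndarray) -> float:
        a, b = np.exp(t)
        return -((a - 1.0) * mean_log_x + (b - 1.0) * mean_log_1mx - betaln(a, b))

    def grad(t: np.ndarray) -> np.ndarray:
        a, b = np.exp(t)
        d = digamma(a + b)
        ga = -(mean_log_x - (digamma(a) - d)) * a
        gb = -(mean_log_1mx - (digamma(b) - d)) * b
        return np.array([ga, gb])

    t0 = np.log(np.clip(init, _SHAPE_MIN, _SHAPE_MAX))
    res = minimize(
        nll,
        t0,
        jac=grad,
        method="BFGS",
        options={"gtol": tol, "maxiter": max_iter},
    )
    a, b = np.exp(np.clip(res.x, np.log(_SHAPE_MIN), np.log(_SHAPE_MAX)))
    # BFGS reports "precision loss" near machine-precision optima; judge
    # convergence by the gradient itself rather than the status flag
    converged = bool(res.success) or float(np.abs(grad(res.x)).max()) < 1e-4
    return float(a), float(b), converged


def fit_beta_ml(
    x: np.ndarray,
    weights: np.ndarray | None = None,
    init: tuple[float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, float, bool]:
    """Fit Beta(alpha, beta) to x in (0,1) by (weighted) maximum likelihood."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot fit a beta distribution to zero observations")
    if np.any((x <= 0) | (x >= 1)):
        raise ValidationError("beta observations must lie strictly inside (0, 1)")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w < 0):
            raise ValidationError("weights must be nonnegative and match x in shape")
    wsum = w.sum()
    if wsum <= 0:
        raise ValidationError("total weight must be positive")
    mean_log_x = float(np.dot(w, np.log(x)) / wsum)
    mean_log_1mx = float(np.dot(w, np.log1p(-x)) / wsum)
    if init is None:
        m = float(np.dot(w, x) / wsum)
        v = float(np.dot(w, (x - m) ** 2) / wsum)
        init = beta_mom(m, v)
    return fit_beta_suffstats(mean_log_x, mean_log_1mx, init, tol=tol, max_iter=max_iter)
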