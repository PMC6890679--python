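"""Frequentist fits and parameter sampling distributions.

Point estimates for the three input distributions and the sampling
distributions used to propagate estimation uncertainty into the risk:

* lognormal moments on the natural-log scale, with the mean drawn from
  ``N(mu_hat, sigma_hat/sqrt(n))`` and the variance from the scaled
  chi-square ``sigma_hat^2/(n-1) * chi2(n-1)``;
* exponential rate 1/mean with asymptotic (or user-supplied) SE;
* interval-censored Weibull / lognormal maximum likelihood for DBPCFC
  threshold data, with SEs from the inverse observed information;
* generic normal sampling of regression coefficients with optional
  positivity by rejection.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .types import (
    ChallengeRecord,
    ConvergenceError,
    ExponentialParams,
    InvalidParameterError,
    LognormalParams,
    NonIdentifiableError,
    WeibullParams,
)

REJECTION_LIMIT = 0.49  # max tolerated P(draw <= 0) under positivity

__all__ = [
    "fit_lognormal",
    "fit_exponential",
    "fit_interval_censored",
    "draw_lognormal_params",
    "draw_normal_params",
]


def fit_lognormal(
    sample: Sequence[float], n_override: Optional[int] = None
) -> LognormalParams:
    """Moment fit of a lognormal on the natural-log scale.

    Location = mean of logs, scale = SD of logs (n-1 denominator).
    ``n_override`` substitutes the effective sample size used for the
    standard errors (e.g. when the sample is itself a resample).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("need at least 2 observations")
    if np.any(x <= 0):
        raise InvalidParameterError("lognormal fit requires strictly positive values")
    logs = np.log(x)
    location = float(np.mean(logs))
    scale = float(np.std(logs, ddof=1))
    if scale == 0.0:
        raise InvalidParameterError("degenerate sample: zero log-scale variance")
    n = int(n_override) if n_override is not None else int(x.size)
    if n < 2:
        raise InvalidParameterError("effective sample size must be >= 2")
    return LognormalParams(
        location=location,
        scale=scale,
        n=n,
        se_location=scale / math.sqrt(n),
        se_scale_sq=scale**2 * math.sqrt(2.0 / (n - 1)),
    )


def fit_exponential(
    sample: Sequence[float], se_rate: Optional[float] = None
) -> ExponentialParams:
    """MLE of the exponential rate, lambda = 1 / sample mean.

    The default SE is the asymptotic ``lambda_hat/sqrt(n)``; pass
    ``se_rate`` to override it with an externally determined value.
    """
    y = np.asarray(sample, dtype=float)
    if y.size < 1:
        raise InvalidParameterError("empty sample")
    if np.any(y <= 0):
        raise InvalidParameterError("exponential fit requires strictly positive values")
    total = float(np.sum(y))
    rate = y.size / total
    se = float(se_rate) if se_rate is not None else rate / math.sqrt(y.size)
    if se <= 0:
        raise InvalidParameterError("se_rate must be > 0")
    return ExponentialParams(rate=rate, n=int(y.size), se_rate=se, data_sum=total)


# ---------------------------------------------------------------------------
# interval-censored threshold MLE
# ---------------------------------------------------------------------------


def _censored_arrays(records: Sequence[ChallengeRecord]):
    """Split records into (interval l,u), (left u), (right l) arrays."""
    il, iu, lu, rl = [], [], [], []
    for r in records:
        if r.censor == "interval":
            il.append(r.lower_mg)
            iu.append(r.upper_mg)
        elif r.censor == "left":
            lu.append(r.upper_mg)
        else:
            rl.append(r.lower_mg)
    return (
        np.asarray(il, dtype=float),
        np.asarray(iu, dtype=float),
        np.asarray(lu, dtype=float),
        np.asarray(rl, dtype=float),
    )


def _weibull_negloglik(theta, il, iu, lu, rl):
    """Negative censored log-likelihood; theta = (log shape, log scale)."""
    a, b = np.exp(theta)
    with np.errstate(over="ignore"):
        # survival S(x) = exp(-(x/b)^a); interval term S(l) - S(u)
        ll = 0.0
        if il.size:
            s_lo = np.exp(-np.power(il / b, a))
            s_hi = np.exp(-np.power(iu / b, a))
            ll += np.sum(np.log(np.maximum(s_lo - s_hi, 1e-300)))
        if lu.size:
            ll += np.sum(np.log(np.maximum(-np.expm1(-np.power(lu / b, a)), 1e-300)))
        if rl.size:
            ll += -np.sum(np.power(rl / b, a))
    return -ll


def _lognormal_negloglik(theta, il, iu, lu, rl):
    """theta = (mu, log sigma); F is the lognormal CDF."""
    mu, sigma = theta[0], np.exp(theta[1])
    ll = 0.0
    if il.size:
        p = stats.norm.cdf((np.log(iu) - mu) / sigma) - stats.norm.cdf(
            (np.log(il) - mu) / sigma
        )
        ll += np.sum(np.log(np.maximum(p, 1e-300)))
    if lu.size:
        ll += np.sum(
            np.log(np.maximum(stats.norm.cdf((np.log(lu) - mu) / sigma), 1e-300))
        )
    if rl.size:
        ll += np.sum(
            np.log(np.maximum(stats.norm.sf((np.log(rl) - mu) / sigma), 1e-300))
        )
    return -ll


def _numerical_hessian(f, theta, args, step=1e-4):
    """Central-difference Hessian of f at theta."""
    p = len(theta)
    h = step * (1.0 + np.abs(theta))
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(theta + ei + ej, *args)
            fpm = f(theta + ei - ej, *args)
            fmp = f(theta - ei + ej, *args)
            fmm = f(theta - ei - ej, *args)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def _pseudo_midpoints(il, iu, lu, rl):
    """Crude uncensored stand-ins for moment-based starting values."""
    vals = []
    if il.size:
        vals.append(np.sqrt(np.maximum(il, 1e-3) * iu))  # geometric midpoint
    if lu.size:
        vals.append(lu / 2.0)
    if rl.size:
        vals.append(rl * 2.0)
    return np.concatenate(vals)


def fit_interval_censored(
    records: Sequence[ChallengeRecord], family: str = "weibull"
):
    """Maximum likelihood threshold fit from interval-censored challenges.

    Maximizes ``sum log[F(upper) - F(lower)]`` with ``F(lower)=0`` for
    left- and ``F(upper)=1`` for right-censored subjects, optimizing on
    an unconstrained scale (log shape/log scale for Weibull; mu/log
    sigma for lognormal) with three starts: moment-based, unit, and the
    best point of a coarse grid scan — the shape<1 Weibull likelihood is
    flat enough that a single start is not trustworthy.  Standard errors
    come from the inverse observed information, delta-method
    back-transformed to the natural parameter scale.
    """
    if family not in ("weibull", "lognormal"):
        raise InvalidParameterError(f"unknown threshold family {family!r}")
    records = list(records)
    if len(records) < 2:
        raise InvalidParameterError("need at least 2 challenge records")
    il, iu, lu, rl = _censored_arrays(records)
    n_informative = il.size + lu.size + rl.size
    if il.size == 0 and (lu.size == 0 or rl.size == 0):
        raise NonIdentifiableError(
            "all records censored in the same direction: threshold "
            "distribution not identifiable"
        )

    pseudo = _pseudo_midpoints(il, iu, lu, rl)
    logs = np.log(pseudo)
    negloglik = _weibull_negloglik if family == "weibull" else _lognormal_negloglik
    args = (il, iu, lu, rl)

    if family == "weibull":
        # moment start: lognormal-ish scale from pseudo data
        sd_log = max(np.std(logs), 0.1)
        moment = np.array([np.log(1.2 / sd_log), np.mean(logs) + 0.5772 * sd_log])
        unit = np.array([0.0, np.log(max(np.median(pseudo), 1.0))])
        grid_pts = [
            np.array([np.log(a0), np.log(b0)])
            for a0 in (0.2, 0.5, 1.0, 2.0)
            for b0 in np.exp(np.quantile(logs, [0.25, 0.5, 0.75]))
        ]
    else:
        moment = np.array([np.mean(logs), np.log(max(np.std(logs), 0.1))])
        unit = np.array([np.median(logs), 0.0])
        grid_pts = [
            np.array([m0, np.log(s0)])
            for m0 in np.quantile(logs, [0.25, 0.5, 0.75])
            for s0 in (0.5, 1.5, 3.0)
        ]
    grid_best = min(grid_pts, key=lambda th: negloglik(th, *args))

    results = [
        optimize.minimize(
            negloglik, start, args=args, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        for start in (moment, unit, grid_best)
    ]
    converged = [r for r in results if r.success and np.isfinite(r.fun)]
    best = min(converged or results, key=lambda r: r.fun)
    if not np.isfinite(best.fun):
        raise ConvergenceError("censored MLE failed", diagnostics=best)
    if not best.success:
        raise ConvergenceError(
            f"censored MLE did not converge: {best.message}", diagnostics=best
        )

    theta = best.x
    hess = _numerical_hessian(negloglik, theta, args)
    try:
        cov_theta = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(
            "observed information singular at the optimum", diagnostics=hess
        ) from exc
    if np.any(np.diag(cov_theta) <= 0):
        raise ConvergenceError(
            "negative variance from observed information: optimum suspect",
            diagnostics=cov_theta,
        )

    if family == "weibull":
        a, b = np.exp(theta)
        jac = np.diag([a, b])  # back-transform from (log a, log b)
        cov = jac @ cov_theta @ jac.T
        return WeibullParams(
            shape=float(a),
            scale=float(b),
            se_shape=float(np.sqrt(cov[0, 0])),
            se_scale=float(np.sqrt(cov[1, 1])),
            cov_shape_scale=float(cov[0, 1]),
        )
    mu, sigma = theta[0], float(np.exp(theta[1]))
    jac = np.diag([1.0, sigma])
    cov = jac @ cov_theta @ jac.T
    se_mu = float(np.sqrt(cov[0, 0]))
    return LognormalParams(
        location=float(mu),
        scale=sigma,
        n=n_informative,
        se_location=se_mu,
        se_scale_sq=2 * sigma**2 * float(np.sqrt(cov[1, 1])) / sigma,
    )


# ---------------------------------------------------------------------------
# parameter sampling distributions
# ---------------------------------------------------------------------------


def draw_lognormal_params(
    fit: LognormalParams, K: int, seed: int
) -> np.ndarray:
    """K joint draws of (location, scale) from the sampling distributions.

    Location ~ N(mu_hat, sigma_hat/sqrt(n)); variance ~ sigma_hat^2/(n-1)
    * chi2(n-1), whose square root is used as the scale.  Returns a
    (K, 2) array.
    """
    if K < 1:
        raise InvalidParameterError(f"K must be >= 1, got {K}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    locations = rng.normal(fit.location, fit.scale / math.sqrt(fit.n), size=K)
    variances = fit.variance / (fit.n - 1) * rng.chisquare(fit.n - 1, size=K)
    return np.column_stack([locations, np.sqrt(variances)])


def draw_normal_params(
    estimate: float,
    se: float,
    K: int,
    seed: int,
    positive: bool = False,
) -> np.ndarray:
    """K i.i.d. normal draws of a fitted coefficient, a ~ N(a_hat, se).

    With ``positive=True``, non-positive draws are rejected and
    resampled; if the expected rejection rate exceeds 50% (estimate
    less than zero SDs above 0) the parameterization is unsuitable and
    an error is raised rather than silently biasing the draws.
    """
    if se <= 0:
        raise InvalidParameterError(f"se must be > 0, got {se}")
    if K < 1:
        raise InvalidParameterError(f"K must be >= 1, got {K}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if not positive:
        return rng.normal(estimate, se, size=K)
    # the 50% boundary carries a small margin so an estimate numerically
    # indistinguishable from zero is flagged too
    if stats.norm.cdf(0.0, loc=estimate, scale=se) > REJECTION_LIMIT:
        raise InvalidParameterError(
            "rejection rate above 50%: normal sampling with positivity "
            "is unsuitable for this estimate/se"
        )
    draws = rng.normal(estimate, se, size=K)
    bad = draws <= 0
    while np.any(bad):
        draws[bad] = rng.normal(estimate, se, size=int(bad.sum()))
        bad = draws <= 0
    return draws
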