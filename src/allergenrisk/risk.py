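"""Risk of allergic reaction p_u = P(Z < X*Y) by closed form and simulation.

The quantity of interest is the probability that an allergic consumer's
reaction threshold Z (mg protein) is exceeded by the exposure X*Y on one
eating occasion, where X is the amount of product consumed (kg) and Y
the allergen concentration in the product (ppm = mg/kg), so X*Y is in mg.

Two Monte Carlo estimators are provided, equal in expectation:

* indicator — draw (X, Y, Z) and count exceedances 1{Z < XY};
* dose-response — draw (X, Y) and average the threshold CDF F_Z(XY),
  each consumer's individual reaction probability.

Parameter (estimation) uncertainty is separated from population
variability by a second-order scheme: the outer loop draws K parameter
sets from their sampling/posterior distributions, the inner loop runs n
iterations per set, yielding K per-replication risks whose spread is the
uncertainty of the risk estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .bayesian import GammaPosterior, PosteriorDraws
from .frequentist import REJECTION_LIMIT
from .types import (
    InvalidParameterError,
    LognormalParams,
    RiskDistribution,
)

__all__ = [
    "closed_form_risk",
    "simulate_risk_indicator",
    "simulate_risk_doseresponse",
    "run_case",
    "CaseSpec",
    "LognormalInput",
    "ExponentialInput",
    "WeibullInput",
    "EmpiricalInput",
]


def _loc_scale(p) -> tuple:
    """Accept a LognormalParams or a plain (location, scale) pair."""
    if isinstance(p, LognormalParams):
        return p.location, p.scale
    loc, scale = float(p[0]), float(p[1])
    return loc, scale


def closed_form_risk(x, y, z) -> float:
    """Triple-lognormal risk in closed form.

    With X, Y, Z lognormal, log Z - log X - log Y is normal, so

        p_u = 1 - Phi((mu_z - mu_x - mu_y) / sqrt(sigma_x^2 + sigma_y^2 + sigma_z^2)).

    Arguments are (location, scale) pairs or LognormalParams in
    consistent log units (log-kg + log-ppm vs log-mg).
    """
    mx, sx = _loc_scale(x)
    my, sy = _loc_scale(y)
    mz, sz = _loc_scale(z)
    if min(sx, sy, sz) < 0:
        raise InvalidParameterError("scales must be non-negative")
    s2 = sx**2 + sy**2 + sz**2
    if s2 == 0.0:
        raise InvalidParameterError(
            "all scales zero: standardized difference undefined"
        )
    return float(stats.norm.sf((mz - mx - my) / math.sqrt(s2)))


def _closed_form_risk_vec(xp, yp, zp) -> np.ndarray:
    """Vectorized closed form over (K,2) parameter arrays."""
    num = zp[:, 0] - xp[:, 0] - yp[:, 0]
    s = np.sqrt(xp[:, 1] ** 2 + yp[:, 1] ** 2 + zp[:, 1] ** 2)
    if np.any(s == 0):
        raise InvalidParameterError("zero total scale in a parameter draw")
    return stats.norm.sf(num / s)


def simulate_risk_indicator(
    x_sampler: Callable, y_sampler: Callable, z_sampler: Callable,
    n: int, seed: int = 0, rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte Carlo risk by counting exceedances 1{Z < X*Y}.

    Samplers are callables ``f(n, rng) -> array``.  The inequality is
    strict: a tie (measure zero for continuous inputs) is no reaction.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.asarray(x_sampler(n, rng), dtype=float)
    y = np.asarray(y_sampler(n, rng), dtype=float)
    z = np.asarray(z_sampler(n, rng), dtype=float)
    return float(np.mean(z < x * y))


def simulate_risk_doseresponse(
    x_sampler: Callable, y_sampler: Callable, threshold_cdf: Callable,
    n: int, seed: int = 0, rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte Carlo risk as the mean individual reaction probability.

    ``threshold_cdf`` maps exposures (mg) to P(Z <= dose); the returned
    value is the average of F_Z(X*Y) over n simulated exposures.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.asarray(x_sampler(n, rng), dtype=float)
    y = np.asarray(y_sampler(n, rng), dtype=float)
    f = np.asarray(threshold_cdf(x * y), dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise InvalidParameterError("threshold_cdf returned values outside [0, 1]")
    return float(np.mean(f))


# ---------------------------------------------------------------------------
# input models: variability distribution + optional parameter uncertainty
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LognormalInput:
    """Lognormal input with optional frequentist parameter sampling.

    When ``n`` is given and uncertainty is active, the location is drawn
    from N(location, scale/sqrt(n)) and the variance from the scaled
    chi-square scale^2/(n-1) * chi2(n-1) per replication.
    """

    location: float
    scale: float
    n: Optional[int] = None

    def __post_init__(self):
        if self.scale <= 0:
            raise InvalidParameterError("scale must be > 0")

    @classmethod
    def from_fit(cls, fit: LognormalParams) -> "LognormalInput":
        return cls(fit.location, fit.scale, fit.n)

    def draw_params(self, K: int, rng: np.random.Generator, active: bool) -> np.ndarray:
        if not active or self.n is None:
            return np.tile([self.location, self.scale], (K, 1))
        loc = rng.normal(self.location, self.scale / math.sqrt(self.n), size=K)
        var = self.scale**2 / (self.n - 1) * rng.chisquare(self.n - 1, size=K)
        return np.column_stack([loc, np.sqrt(var)])

    def sample(self, params: np.ndarray, n: int, rng: np.random.Generator):
        return rng.lognormal(mean=params[0], sigma=params[1], size=n)

    def cdf(self, params: np.ndarray, x: np.ndarray) -> np.ndarray:
        return stats.norm.cdf((np.log(np.maximum(x, 1e-300)) - params[0]) / params[1])

    is_lognormal = True


@dataclass(frozen=True)
class ExponentialInput:
    """Exponential input (concentration); rate in 1/ppm.

    ``param_draw`` selects the uncertainty model for the rate:
    ``None`` (fixed), ``("normal", se)`` (frequentist sampling
    distribution, positive draws enforced by rejection), or a
    :class:`GammaPosterior` (Bayesian).
    """

    rate: float
    param_draw: Union[None, tuple, GammaPosterior] = None

    def __post_init__(self):
        if self.rate <= 0:
            raise InvalidParameterError("rate must be > 0")

    def draw_params(self, K: int, rng: np.random.Generator, active: bool) -> np.ndarray:
        if not active or self.param_draw is None:
            return np.full((K, 1), self.rate)
        if isinstance(self.param_draw, GammaPosterior):
            return self.param_draw.sample(K, rng).reshape(-1, 1)
        kind, se = self.param_draw
        if kind != "normal":
            raise InvalidParameterError(f"unknown param_draw {kind!r}")
        if stats.norm.cdf(0.0, self.rate, se) > REJECTION_LIMIT:
            raise InvalidParameterError("rejection rate above 50% for positive rate")
        draws = rng.normal(self.rate, se, size=K)
        bad = draws <= 0
        while np.any(bad):
            draws[bad] = rng.normal(self.rate, se, size=int(bad.sum()))
            bad = draws <= 0
        return draws.reshape(-1, 1)

    def sample(self, params: np.ndarray, n: int, rng: np.random.Generator):
        return rng.exponential(scale=1.0 / params[0], size=n)

    is_lognormal = False


@dataclass(frozen=True)
class WeibullInput:
    """Weibull threshold input (shape, scale in mg protein).

    ``param_draw`` is ``None`` (fixed), ``("normal", se_shape, se_scale)``
    — independent normal sampling distributions with positivity by
    rejection, as in the frequentist survival-regression case — or a
    :class:`PosteriorDraws` whose rows are resampled per replication.
    """

    shape: float
    scale: float
    param_draw: Union[None, tuple, PosteriorDraws] = None

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise InvalidParameterError("Weibull shape and scale must be > 0")

    def draw_params(self, K: int, rng: np.random.Generator, active: bool) -> np.ndarray:
        if not active or self.param_draw is None:
            return np.tile([self.shape, self.scale], (K, 1))
        if isinstance(self.param_draw, PosteriorDraws):
            idx = rng.integers(0, self.param_draw.draws.shape[0], size=K)
            return self.param_draw.draws[idx]
        kind, se_shape, se_scale = self.param_draw
        if kind != "normal":
            raise InvalidParameterError(f"unknown param_draw {kind!r}")
        out = np.empty((K, 2))
        for j, (est, se) in enumerate(((self.shape, se_shape), (self.scale, se_scale))):
            if stats.norm.cdf(0.0, est, se) > REJECTION_LIMIT:
                raise InvalidParameterError(
                    "rejection rate above 50% for positive parameter"
                )
            d = rng.normal(est, se, size=K)
            bad = d <= 0
            while np.any(bad):
                d[bad] = rng.normal(est, se, size=int(bad.sum()))
                bad = d <= 0
            out[:, j] = d
        return out

    def sample(self, params: np.ndarray, n: int, rng: np.random.Generator):
        return params[1] * rng.weibull(params[0], size=n)

    def cdf(self, params: np.ndarray, x: np.ndarray) -> np.ndarray:
        return -np.expm1(-np.power(np.maximum(x, 0.0) / params[1], params[0]))

    is_lognormal = False


@dataclass(frozen=True)
class EmpiricalInput:
    """Nonparametric input: sampling with replacement from survey data.

    With uncertainty active, each replication first draws a bootstrap
    resample of the dataset (respecting survey weights) and the inner
    iterations sample from that resample — the bootstrap expresses the
    sampling uncertainty of the survey itself.
    """

    data: tuple
    weights: Optional[tuple] = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.size == 0:
            raise InvalidParameterError("empty sample")
        object.__setattr__(self, "data", tuple(float(v) for v in d))
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.size != d.size or np.any(w < 0) or w.sum() == 0:
                raise InvalidParameterError("invalid weights")
            object.__setattr__(self, "weights", tuple(float(v) for v in w))

    def _p(self):
        if self.weights is None:
            return None
        w = np.asarray(self.weights)
        return w / w.sum()

    def draw_params(self, K: int, rng: np.random.Generator, active: bool):
        arr = np.asarray(self.data)
        if not active:
            return [arr] * K
        m = arr.size
        return [
            rng.choice(arr, size=m, replace=True, p=self._p()) for _ in range(K)
        ]

    def sample(self, params, n: int, rng: np.random.Generator):
        return rng.choice(np.asarray(params), size=n, replace=True)

    is_lognormal = False


# ---------------------------------------------------------------------------
# second-order Monte Carlo driver
# ---------------------------------------------------------------------------

RiskMethod = Literal["indicator", "dose_response", "closed_form"]


@dataclass(frozen=True)
class CaseSpec:
    """One fully specified risk-assessment case.

    ``risk_method``: "indicator" counts simulated exceedances;
    "dose_response" averages the threshold CDF over exposures;
    "closed_form" evaluates the triple-lognormal formula per parameter
    draw (no inner loop — the analytic 'calculated' mode).
    ``uncertainty_active`` toggles the parameter-uncertainty dimension
    per input (consumption, concentration, threshold) and drives the
    one-at-a-time decomposition.
    """

    case_id: str
    consumption: object
    concentration: object
    threshold: object
    risk_method: RiskMethod = "indicator"
    K: int = 1000
    n: int = 10_000
    seed: int = 0
    uncertainty_active: tuple = (True, True, True)
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.K < 1 or self.n < 1:
            raise InvalidParameterError("K and n must be >= 1")
        if self.risk_method not in ("indicator", "dose_response", "closed_form"):
            raise InvalidParameterError(f"unknown risk_method {self.risk_method!r}")
        if self.risk_method == "closed_form":
            for inp in (self.consumption, self.concentration, self.threshold):
                if not getattr(inp, "is_lognormal", False):
                    raise InvalidParameterError(
                        "closed_form requires all three inputs lognormal"
                    )
        if self.risk_method == "dose_response" and not hasattr(self.threshold, "cdf"):
            raise InvalidParameterError("threshold input provides no CDF")

    def with_uncertainty(self, consumption: bool, concentration: bool,
                         threshold: bool) -> "CaseSpec":
        return replace(
            self, uncertainty_active=(consumption, concentration, threshold)
        )


def run_case(spec: CaseSpec) -> RiskDistribution:
    """Run the second-order Monte Carlo for one case.

    Outer loop: K parameter sets drawn from each input's uncertainty
    model (point estimates where inactive).  Inner loop: n iterations
    per set via the spec's risk method.  Sub-streams are derived
    deterministically from ``spec.seed``, so the result is reproducible
    and per-replication streams are independent.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_x, ss_y, ss_z, ss_rep = root.spawn(4)
    ax, ay, az = spec.uncertainty_active
    px = spec.consumption.draw_params(spec.K, np.random.default_rng(ss_x), ax)
    py = spec.concentration.draw_params(spec.K, np.random.default_rng(ss_y), ay)
    pz = spec.threshold.draw_params(spec.K, np.random.default_rng(ss_z), az)

    if spec.risk_method == "closed_form":
        risks = _closed_form_risk_vec(np.asarray(px), np.asarray(py), np.asarray(pz))
        return RiskDistribution(risks)

    rep_seeds = ss_rep.spawn(spec.K)
    risks = np.empty(spec.K)
    for k in range(spec.K):
        rng = np.random.default_rng(rep_seeds[k])
        x = spec.consumption.sample(px[k], spec.n, rng)
        y = spec.concentration.sample(py[k], spec.n, rng)
        exposure = x * y
        if spec.risk_method == "indicator":
            z = spec.threshold.sample(pz[k], spec.n, rng)
            risks[k] = np.mean(z < exposure)
        else:
            risks[k] = np.mean(spec.threshold.cdf(pz[k], exposure))
    no_uncertainty = not (ax or ay or az) or spec.case_id.upper() == "A"
    return RiskDistribution(risks, sd_is_simulation_error_only=no_uncertainty)
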