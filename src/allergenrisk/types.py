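"""Shared domain types for the allergen risk-assessment framework.

Units convention (used consistently across the package):

* consumption X — kg of product per eating occasion,
* concentration Y — ppm, i.e. mg allergen protein per kg product,
* threshold Z — mg allergen protein,
* exposure = X * Y — mg allergen protein.

Log-scale parameters are natural-log moments of these quantities
(log-kg, log-ppm, log-mg respectively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

CensorType = Literal["interval", "left", "right"]


class InvalidParameterError(ValueError):
    """Raised when a distribution parameter violates its constraints."""


class NonIdentifiableError(ValueError):
    """Raised when censored data cannot identify the threshold distribution."""


class ConvergenceError(RuntimeError):
    """Raised when an optimizer fails to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: object = None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class LognormalParams:
    """Fitted log-normal: location/scale on the natural-log scale.

    ``se_location`` is the standard error of the location estimate
    (sigma/sqrt(n) for a moment fit); ``se_scale_sq`` the standard
    deviation of the variance estimator, sigma^2 * sqrt(2/(n-1)).
    """

    location: float
    scale: float
    n: int
    se_location: float
    se_scale_sq: float

    def __post_init__(self):
        if self.scale <= 0:
            raise InvalidParameterError(f"scale must be > 0, got {self.scale}")
        if self.n < 2:
            raise InvalidParameterError(f"n must be >= 2, got {self.n}")

    @property
    def variance(self) -> float:
        return self.scale**2

    def median_natural(self) -> float:
        """Median on the natural (anti-log) scale."""
        return math.exp(self.location)

    def mean_natural(self) -> float:
        return math.exp(self.location + 0.5 * self.scale**2)


@dataclass(frozen=True)
class ExponentialParams:
    """Fitted exponential rate (1/ppm) with data sufficient statistics.

    ``data_sum`` (sum of observations) is retained so a conjugate
    Gamma update can be formed later without re-reading the data.
    """

    rate: float
    n: int
    se_rate: float
    data_sum: float

    def __post_init__(self):
        if self.rate <= 0:
            raise InvalidParameterError(f"rate must be > 0, got {self.rate}")
        if self.data_sum <= 0:
            raise InvalidParameterError("data_sum must be > 0")

    @property
    def mean(self) -> float:
        return 1.0 / self.rate


@dataclass(frozen=True)
class WeibullParams:
    """Fitted Weibull threshold distribution: shape a, scale b (mg protein)."""

    shape: float
    scale: float
    se_shape: float
    se_scale: float
    cov_shape_scale: Optional[float] = None

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise InvalidParameterError("Weibull shape and scale must be > 0")
        if self.se_shape <= 0 or self.se_scale <= 0:
            raise InvalidParameterError("standard errors must be > 0")

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return -np.expm1(-np.power(np.maximum(x, 0.0) / self.scale, self.shape))


@dataclass(frozen=True)
class ChallengeRecord:
    """One DBPCFC subject's interval-censored reaction threshold.

    ``lower_mg``/``upper_mg`` bracket the latent threshold: the NOAEL
    (highest tolerated dose) and LOAEL (lowest reactive dose).  For
    left-censored records (reaction at the first dose) ``lower_mg`` is
    None; for right-censored records (no reaction at the top dose)
    ``upper_mg`` is None.  ``latent_mg`` is a debug field used only by
    the synthetic generator; fitting code must ignore it.
    """

    lower_mg: Optional[float]
    upper_mg: Optional[float]
    censor: CensorType
    latent_mg: Optional[float] = None

    def __post_init__(self):
        if self.censor == "interval":
            if self.lower_mg is None or self.upper_mg is None:
                raise InvalidParameterError("interval record needs both bounds")
            if not (0 <= self.lower_mg < self.upper_mg):
                raise InvalidParameterError(
                    f"interval record needs 0 <= lower < upper, got "
                    f"({self.lower_mg}, {self.upper_mg})"
                )
        elif self.censor == "left":
            if self.upper_mg is None or self.upper_mg <= 0:
                raise InvalidParameterError("left-censored record needs upper > 0")
        elif self.censor == "right":
            if self.lower_mg is None or self.lower_mg < 0:
                raise InvalidParameterError("right-censored record needs lower >= 0")
        else:
            raise InvalidParameterError(f"unknown censor type {self.censor!r}")


@dataclass(frozen=True)
class DoseGrid:
    """Strictly increasing positive challenge doses (mg protein)."""

    doses: tuple

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        if d.size < 2:
            raise InvalidParameterError("dose grid needs at least 2 doses")
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise InvalidParameterError("doses must be positive and strictly increasing")
        object.__setattr__(self, "doses", tuple(float(x) for x in d))

    @classmethod
    def default(cls) -> "DoseGrid":
        # 10 geometric doses 0.1 .. 1000 mg: spans the fitted threshold
        # scale (~230 mg) with realistic low-dose DBPCFC spacing.
        return cls(tuple(np.geomspace(0.1, 1000.0, 10)))


@dataclass(frozen=True)
class GroundTruth:
    """Known generating parameters for the synthetic datasets.

    Defaults are the peanut-in-cereal-bars configuration: lognormal
    consumption (log-kg), exponential contamination (1/ppm), Weibull
    thresholds (mg protein), with the survey/assay/challenge sample sizes.
    """

    consumption_params: tuple = (-3.719, 0.747)
    concentration_family: str = "exponential"
    concentration_params: tuple = (0.013,)
    threshold_family: str = "weibull"
    threshold_params: tuple = (0.38, 229.6)
    n_x: int = 350
    n_y: int = 24
    n_z: int = 158

    def __post_init__(self):
        if self.consumption_params[1] <= 0:
            raise InvalidParameterError("consumption scale must be > 0")
        if self.concentration_family not in ("exponential", "lognormal"):
            raise InvalidParameterError(
                f"unknown concentration family {self.concentration_family!r}"
            )
        if self.threshold_family not in ("weibull", "lognormal"):
            raise InvalidParameterError(
                f"unknown threshold family {self.threshold_family!r}"
            )
        for p in (*self.concentration_params, ):
            if self.concentration_family == "exponential" and p <= 0:
                raise InvalidParameterError("exponential rate must be > 0")
        if self.threshold_family == "weibull":
            if any(p <= 0 for p in self.threshold_params):
                raise InvalidParameterError("Weibull parameters must be > 0")
        for n in (self.n_x, self.n_y, self.n_z):
            if n < 2:
                raise InvalidParameterError("sample sizes must be >= 2")


@dataclass
class RiskDistribution:
    """K per-replication risks with their summary statistics.

    Risks are probabilities in [0, 1]; reporting code converts to
    percentages.  ``sd_is_simulation_error_only`` marks the plug-in case
    where the replication spread reflects Monte Carlo noise, not input
    uncertainty.
    """

    risks: np.ndarray
    sd_is_simulation_error_only: bool = False

    def __post_init__(self):
        r = np.asarray(self.risks, dtype=float)
        if r.ndim != 1 or r.size < 1:
            raise InvalidParameterError("risks must be a non-empty 1-D array")
        if np.any((r < 0) | (r > 1)):
            raise InvalidParameterError("risks must lie in [0, 1]")
        self.risks = r

    @property
    def mean(self) -> float:
        return float(np.mean(self.risks))

    @property
    def sd(self) -> float:
        if self.risks.size < 2:
            return 0.0
        return float(np.std(self.risks, ddof=1))

    def percentile(self, q: float) -> float:
        # median-unbiased interpolation; quantile convention is a
        # documented choice (differences are within stochastic tolerance)
        return float(np.quantile(self.risks, q / 100.0, method="median_unbiased"))

    @property
    def p2_5(self) -> float:
        return self.percentile(2.5)

    @property
    def median(self) -> float:
        return self.percentile(50.0)

    @property
    def p97_5(self) -> float:
        return self.percentile(97.5)

    def summary(self, as_percent: bool = True) -> dict:
        f = 100.0 if as_percent else 1.0
        return {
            "mean": f * self.mean,
            "sd": f * self.sd,
            "p2.5": f * self.p2_5,
            "median": f * self.median,
            "p97.5": f * self.p97_5,
        }


@dataclass
class UncertaintyDecomposition:
    """Per-input contributions to Var(p_u) on the proportion scale.

    ``var_joint`` is the variance with all parameter uncertainties
    active; for the delta method it equals the sum by construction.
    """

    var_consumption: float
    var_contamination: float
    var_threshold: float
    var_joint: float
    method: Literal["delta", "simulation"]

    def __post_init__(self):
        for v in (self.var_consumption, self.var_contamination, self.var_threshold):
            if v < 0:
                raise InvalidParameterError("variance components must be >= 0")

    @property
    def sum_individual(self) -> float:
        return self.var_consumption + self.var_contamination + self.var_threshold
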