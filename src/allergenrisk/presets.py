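"""Ready-made case specifications for the peanut-in-cereal-bars example.

Four estimation cases share the same three inputs (consumption X,
contamination Y, threshold Z) and differ in how parameter uncertainty
enters:

* **Case A** — plug-in: triple lognormal at the point estimates, no
  parameter uncertainty; the replication spread is simulation error only.
* **Case B** — triple lognormal with frequentist sampling distributions
  (normal for log-locations, scaled chi-square for log-variances);
  risk either "simulated" (indicator MC) or "calculated" (closed form
  per parameter draw).
* **Case C** — frequentist with exponential contamination and Weibull
  thresholds; parameters drawn from normal sampling distributions;
  dose-response risk.
* **Case D** — Bayesian: bootstrap consumption, conjugate Gamma
  posterior for the contamination rate, MCMC posterior for the Weibull
  threshold; dose-response risk.

The ``PEANUT_*`` constants are the published point estimates and
standard errors for the worked example (consumption in log-kg,
concentration in ppm, thresholds in mg protein).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .bayesian import (
    GammaPosterior,
    MCMCConfig,
    PosteriorDraws,
    VAGUE_PRIOR,
    exponential_gamma_posterior,
    weibull_threshold_mcmc,
)
from .frequentist import fit_exponential, fit_interval_censored, fit_lognormal
from .risk import (
    CaseSpec,
    EmpiricalInput,
    ExponentialInput,
    LognormalInput,
    WeibullInput,
)
from .types import ChallengeRecord, InvalidParameterError, LognormalParams

__all__ = [
    "PEANUT_CASE_A",
    "PEANUT_CASE_B",
    "PEANUT_CASE_C",
    "case_a",
    "case_b",
    "case_c",
    "case_d",
    "case_c_from_data",
    "case_d_from_data",
]

# Published point estimates (rounded to 3 decimals in the source tables).
PEANUT_CASE_A = {
    "x": (-3.718, 0.745),   # log-kg
    "y": (3.504, 1.296),    # log-ppm
    "z": (4.092, 2.982),    # log-mg
}
PEANUT_CASE_B = {
    "x": (-3.719, 0.747, 350),
    "y": (3.496, 1.283, 24),
    "z": (4.088, 2.987, 158),
}
PEANUT_CASE_C = {
    "x": (-3.719, 0.747, 350),
    "y_rate": 0.013,
    # published sampling SD of lambda_Y for this case (not the asymptotic
    # rate/sqrt(n), which would be ~0.0027; provenance unexplained there)
    "y_se": 0.001,
    "z_shape": (0.382, 0.027),
    "z_scale": (229.621, 55.099),
}


def case_a(params: Optional[dict] = None, K: int = 1, n: int = 10_000,
           seed: int = 0, risk_method: str = "indicator") -> CaseSpec:
    """Plug-in triple-lognormal case (no parameter uncertainty)."""
    p = params or PEANUT_CASE_A
    return CaseSpec(
        case_id="A",
        consumption=LognormalInput(*p["x"][:2]),
        concentration=LognormalInput(*p["y"][:2]),
        threshold=LognormalInput(*p["z"][:2]),
        risk_method=risk_method,
        K=K,
        n=n,
        seed=seed,
        uncertainty_active=(False, False, False),
        metadata={"label": "case A (plug-in)"},
    )


def case_b(params: Optional[dict] = None, mode: str = "simulated",
           K: int = 1000, n: int = 10_000, seed: int = 0) -> CaseSpec:
    """Triple-lognormal case with frequentist parameter sampling.

    ``mode="simulated"`` uses the indicator Monte Carlo; ``"calculated"``
    evaluates the closed-form risk per parameter draw (no inner loop).
    """
    if mode not in ("simulated", "calculated"):
        raise InvalidParameterError(f"unknown case B mode {mode!r}")
    p = params or PEANUT_CASE_B
    return CaseSpec(
        case_id="B",
        consumption=LognormalInput(*p["x"]),
        concentration=LognormalInput(*p["y"]),
        threshold=LognormalInput(*p["z"]),
        risk_method="indicator" if mode == "simulated" else "closed_form",
        K=K,
        n=n,
        seed=seed,
        metadata={"label": f"case B ({mode})"},
    )


def case_c(params: Optional[dict] = None, K: int = 1000, n: int = 10_000,
           seed: int = 0) -> CaseSpec:
    """Frequentist case: exponential contamination, Weibull thresholds."""
    p = params or PEANUT_CASE_C
    return CaseSpec(
        case_id="C",
        consumption=LognormalInput(*p["x"]),
        concentration=ExponentialInput(p["y_rate"], ("normal", p["y_se"])),
        threshold=WeibullInput(
            p["z_shape"][0], p["z_scale"][0],
            ("normal", p["z_shape"][1], p["z_scale"][1]),
        ),
        risk_method="dose_response",
        K=K,
        n=n,
        seed=seed,
        metadata={"label": "case C (frequentist)"},
    )


def case_c_from_data(
    consumption: Sequence[float],
    concentration: Sequence[float],
    challenges: Sequence[ChallengeRecord],
    K: int = 1000,
    n: int = 10_000,
    seed: int = 0,
    se_rate: Optional[float] = None,
) -> CaseSpec:
    """Build case C by fitting the three datasets.

    ``se_rate`` overrides the asymptotic SE of the exponential rate.
    """
    x_fit = fit_lognormal(consumption)
    y_fit = fit_exponential(concentration, se_rate=se_rate)
    z_fit = fit_interval_censored(challenges, family="weibull")
    spec = case_c(
        params={
            "x": (x_fit.location, x_fit.scale, x_fit.n),
            "y_rate": y_fit.rate,
            "y_se": y_fit.se_rate,
            "z_shape": (z_fit.shape, z_fit.se_shape),
            "z_scale": (z_fit.scale, z_fit.se_scale),
        },
        K=K, n=n, seed=seed,
    )
    spec.metadata["fits"] = {"x": x_fit, "y": y_fit, "z": z_fit}
    return spec


def case_d(
    consumption_sample: Sequence[float],
    concentration_posterior: GammaPosterior,
    threshold_posterior: PosteriorDraws,
    consumption_weights: Optional[Sequence[float]] = None,
    K: int = 1000,
    n: int = 10_000,
    seed: int = 0,
) -> CaseSpec:
    """Bayesian case from pre-computed posteriors.

    Consumption is drawn by bootstrap of the (survey-weighted) sample;
    because the original survey data are not public, callers typically
    pass a synthetic sample — recorded in the metadata.
    """
    post_means = threshold_posterior.draws.mean(axis=0)
    return CaseSpec(
        case_id="D",
        consumption=EmpiricalInput(tuple(consumption_sample),
                                   tuple(consumption_weights)
                                   if consumption_weights is not None else None),
        concentration=ExponentialInput(
            concentration_posterior.mean, concentration_posterior
        ),
        threshold=WeibullInput(
            float(post_means[0]), float(post_means[1]), threshold_posterior
        ),
        risk_method="dose_response",
        K=K,
        n=n,
        seed=seed,
        metadata={
            "label": "case D (Bayesian)",
            "consumption_note": (
                "bootstrap of the provided sample stands in for the "
                "original survey's empirical distribution"
            ),
        },
    )


def case_d_from_data(
    consumption: Sequence[float],
    concentration: Sequence[float],
    challenges: Sequence[ChallengeRecord],
    consumption_weights: Optional[Sequence[float]] = None,
    K: int = 1000,
    n: int = 10_000,
    seed: int = 0,
    mcmc_config: Optional[MCMCConfig] = None,
) -> CaseSpec:
    """Build case D end-to-end: conjugate update + threshold MCMC."""
    gamma_post = exponential_gamma_posterior(*VAGUE_PRIOR, concentration)
    mcmc_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    posterior = weibull_threshold_mcmc(
        challenges, K=max(K, 1000), seed=mcmc_seed, mcmc_config=mcmc_config
    )
    spec = case_d(
        consumption, gamma_post, posterior,
        consumption_weights=consumption_weights, K=K, n=n, seed=seed,
    )
    spec.metadata["gamma_posterior"] = gamma_post
    spec.metadata["threshold_posterior"] = posterior
    return spec
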