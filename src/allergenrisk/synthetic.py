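"""Synthetic consumption, contamination and challenge datasets.

The original worked example's raw inputs (three national consumption surveys, 24 published
peanut concentrations in cereal bars, 158 DBPCFC outcomes) are not
public, so this module generates datasets with *known* ground truth that
emulate them: lognormal single-occasion consumption, exponential (or
lognormal) allergen concentration, and Weibull (or lognormal) reaction
thresholds observed only through the dose grid of a challenge protocol.

Reproducibility contract: one integer seed per generator call; per-subject
streams are derived by counter offset (``SeedSequence(seed).spawn``) so
increasing ``n`` extends a dataset without reshuffling earlier subjects.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import (
    ChallengeRecord,
    DoseGrid,
    GroundTruth,
    InvalidParameterError,
)

__all__ = [
    "generate_consumption",
    "generate_concentration",
    "generate_challenge_data",
    "generate_all",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def generate_consumption(
    params: Sequence[float],
    n: int,
    seed: int,
    heavy_tail_weight: float = 0.0,
    heavy_tail_scale_factor: float = 3.0,
) -> np.ndarray:
    """Draw ``n`` single-occasion consumption amounts (kg of product).

    ``params`` is the (location, scale) pair of the natural-log amount.
    The optional two-component mixture replaces a fraction
    ``heavy_tail_weight`` of draws with a wider-scale lognormal
    (scale multiplied by ``heavy_tail_scale_factor``), mimicking the
    heavier-than-lognormal upper tail of survey consumption data;
    the default is the pure lognormal.
    """
    location, scale = float(params[0]), float(params[1])
    if scale <= 0:
        raise InvalidParameterError(f"lognormal scale must be > 0, got {scale}")
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if not 0.0 <= heavy_tail_weight < 1.0:
        raise InvalidParameterError("heavy_tail_weight must be in [0, 1)")
    rng = _rng(seed)
    draws = rng.lognormal(mean=location, sigma=scale, size=n)
    if heavy_tail_weight > 0.0:
        mask = rng.random(n) < heavy_tail_weight
        n_tail = int(mask.sum())
        if n_tail:
            draws[mask] = rng.lognormal(
                mean=location, sigma=scale * heavy_tail_scale_factor, size=n_tail
            )
    return draws


def generate_concentration(
    family: str,
    params: Sequence[float],
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw ``n`` allergen concentrations (ppm) in contaminated product.

    ``family`` is ``"exponential"`` (params: rate, 1/ppm) or
    ``"lognormal"`` (params: log-scale location, scale).
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    rng = _rng(seed)
    if family == "exponential":
        (rate,) = (float(params[0]),)
        if rate <= 0:
            raise InvalidParameterError(f"exponential rate must be > 0, got {rate}")
        return rng.exponential(scale=1.0 / rate, size=n)
    if family == "lognormal":
        location, scale = float(params[0]), float(params[1])
        if scale <= 0:
            raise InvalidParameterError(f"lognormal scale must be > 0, got {scale}")
        return rng.lognormal(mean=location, sigma=scale, size=n)
    raise InvalidParameterError(f"unknown concentration family {family!r}")


def _draw_latent_threshold(
    family: str, params: Sequence[float], rng: np.random.Generator
) -> float:
    if family == "weibull":
        shape, scale = float(params[0]), float(params[1])
        if shape <= 0 or scale <= 0:
            raise InvalidParameterError("Weibull parameters must be > 0")
        return float(scale * rng.weibull(shape))
    if family == "lognormal":
        location, scale = float(params[0]), float(params[1])
        if scale <= 0:
            raise InvalidParameterError("lognormal scale must be > 0")
        return float(rng.lognormal(mean=location, sigma=scale))
    raise InvalidParameterError(f"unknown threshold family {family!r}")


def censor_threshold(t: float, grid: DoseGrid) -> ChallengeRecord:
    """Reduce a latent threshold to the interval a challenge would report.

    The subject tolerates every dose strictly below ``t`` and reacts at
    the first dose >= ``t``: the NOAEL is the largest grid dose < t, the
    LOAEL the smallest grid dose >= t.  A threshold at or below the
    first dose is left-censored; one above the last dose right-censored.
    """
    doses = np.asarray(grid.doses)
    below = doses[doses < t]
    at_or_above = doses[doses >= t]
    if below.size == 0:
        return ChallengeRecord(None, float(doses[0]), "left", latent_mg=t)
    if at_or_above.size == 0:
        return ChallengeRecord(float(doses[-1]), None, "right", latent_mg=t)
    return ChallengeRecord(
        float(below[-1]), float(at_or_above[0]), "interval", latent_mg=t
    )


def generate_challenge_data(
    threshold_family: str,
    params: Sequence[float],
    n_subjects: int,
    grid: Optional[DoseGrid] = None,
    seed: int = 0,
) -> list[ChallengeRecord]:
    """Simulate ``n_subjects`` DBPCFC outcomes on a dose grid.

    Each subject's latent threshold (mg protein) is drawn from the
    requested family, then censored to the grid interval containing it
    via :func:`censor_threshold`.  The latent value is retained in the
    record's ``latent_mg`` debug field; fitting code ignores it.
    """
    if n_subjects < 1:
        raise InvalidParameterError(f"n_subjects must be >= 1, got {n_subjects}")
    grid = grid if grid is not None else DoseGrid.default()
    # one child stream per subject: stable under growing n_subjects
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    records = []
    for child in children:
        rng = np.random.default_rng(child)
        t = _draw_latent_threshold(threshold_family, params, rng)
        records.append(censor_threshold(t, grid))
    return records


def generate_all(
    truth: GroundTruth, seed: int, grid: Optional[DoseGrid] = None
) -> dict:
    """Generate the three datasets of one study world from a single seed.

    Returns ``{"consumption": array (kg), "concentration": array (ppm),
    "challenges": list[ChallengeRecord], "truth": GroundTruth}``.
    Sub-seeds for the three generators are derived from ``seed`` by
    fixed offsets, so the datasets are independent but reproducible.
    """
    base = np.random.SeedSequence(seed).generate_state(3)
    return {
        "consumption": generate_consumption(
            truth.consumption_params, truth.n_x, int(base[0] % (2**31))
        ),
        "concentration": generate_concentration(
            truth.concentration_family,
            truth.concentration_params,
            truth.n_y,
            int(base[1] % (2**31)),
        ),
        "challenges": generate_challenge_data(
            truth.threshold_family,
            truth.threshold_params,
            truth.n_z,
            grid=grid,
            seed=int(base[2] % (2**31)),
        ),
        "truth": truth,
    }
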