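"""Dataset I/O, run configuration and report tables.

CSV schemas (header row, full decimal precision, round-trip exact):

* ``consumption.csv`` — ``amount_kg`` (positive), optional ``weight``
  (non-negative survey weight);
* ``concentration.csv`` — ``ppm`` (positive);
* ``challenges.csv`` — ``lower_mg``, ``upper_mg``,
  ``censor`` in {interval, left, right}, optional ``latent_mg`` (debug
  column written by the synthetic generator, ignored by all fitting).

``run_pipeline`` ties the stages together: load (or synthesize) the
three datasets, fit the input distributions, run the requested case,
decompose the uncertainty, and write the report tables plus a manifest
sufficient to reproduce every output bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import presets
from .bayesian import exponential_gamma_posterior, VAGUE_PRIOR
from .frequentist import (
    draw_lognormal_params,
    draw_normal_params,
    fit_exponential,
    fit_interval_censored,
    fit_lognormal,
)
from .risk import CaseSpec, run_case
from .synthetic import generate_all
from .types import (
    ChallengeRecord,
    GroundTruth,
    InvalidParameterError,
    LognormalParams,
)
from .uncertainty import (
    REPORT_UNIT,
    decomposition_report,
    delta_method_variance,
    oat_decomposition,
)

__all__ = [
    "read_consumption",
    "read_concentration",
    "read_challenges",
    "write_consumption",
    "write_concentration",
    "write_challenges",
    "RunConfig",
    "run_pipeline",
]

_FLOAT_FMT = "%.17g"  # round-trip exact for IEEE doubles


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    # round_trip: exact re-parsing of the %.17g values we write
    return pd.read_csv(path, float_precision="round_trip")


def read_consumption(path) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Read single-occasion consumption amounts (kg), optional weights.

    Returns ``(amounts, weights)`` with ``weights=None`` when the column
    is absent (uniform weighting).  Malformed rows are reported with
    their 1-based data row number.
    """
    df = _read_csv(path)
    if "amount_kg" not in df.columns:
        raise InvalidParameterError(f"{path}: missing column 'amount_kg'")
    amounts = df["amount_kg"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(amounts > 0))
    if bad.size:
        raise InvalidParameterError(
            f"{path}: non-positive amount_kg at data row(s) {(bad + 1).tolist()}"
        )
    weights = None
    if "weight" in df.columns:
        weights = df["weight"].to_numpy(dtype=float)
        bad = np.flatnonzero(weights < 0)
        if bad.size:
            raise InvalidParameterError(
                f"{path}: negative weight at data row(s) {(bad + 1).tolist()}"
            )
    return amounts, weights


def read_concentration(path) -> np.ndarray:
    """Read allergen concentrations (ppm) of contaminated product."""
    df = _read_csv(path)
    if "ppm" not in df.columns:
        raise InvalidParameterError(f"{path}: missing column 'ppm'")
    ppm = df["ppm"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(ppm > 0))
    if bad.size:
        raise InvalidParameterError(
            f"{path}: non-positive ppm at data row(s) {(bad + 1).tolist()}"
        )
    return ppm


def read_challenges(path) -> list[ChallengeRecord]:
    """Read interval-censored DBPCFC records.

    The latent_mg debug column, if present, is carried along but has no
    effect on fitting.  Bound/censor inconsistencies raise with the
    offending row number.
    """
    df = _read_csv(path)
    for col in ("lower_mg", "upper_mg", "censor"):
        if col not in df.columns:
            raise InvalidParameterError(f"{path}: missing column '{col}'")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        lower = None if pd.isna(row.lower_mg) else float(row.lower_mg)
        upper = None if pd.isna(row.upper_mg) else float(row.upper_mg)
        latent = (
            float(row.latent_mg)
            if hasattr(row, "latent_mg") and not pd.isna(row.latent_mg)
            else None
        )
        try:
            records.append(
                ChallengeRecord(lower, upper, str(row.censor), latent_mg=latent)
            )
        except InvalidParameterError as exc:
            raise InvalidParameterError(f"{path}: data row {i}: {exc}") from exc
    return records


def write_consumption(path, amounts: Sequence[float],
                      weights: Optional[Sequence[float]] = None) -> Path:
    df = pd.DataFrame({"amount_kg": np.asarray(amounts, dtype=float)})
    if weights is not None:
        df["weight"] = np.asarray(weights, dtype=float)
    path = Path(path)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_concentration(path, ppm: Sequence[float]) -> Path:
    path = Path(path)
    pd.DataFrame({"ppm": np.asarray(ppm, dtype=float)}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def write_challenges(path, records: Sequence[ChallengeRecord],
                     include_latent: bool = True) -> Path:
    rows = {
        "lower_mg": [r.lower_mg for r in records],
        "upper_mg": [r.upper_mg for r in records],
        "censor": [r.censor for r in records],
    }
    if include_latent and any(r.latent_mg is not None for r in records):
        rows["latent_mg"] = [r.latent_mg for r in records]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run.

    Either the three CSV paths or ``synthesize=True`` (with an optional
    ``truth``) must be given.  ``seed`` drives every stochastic stage.
    """

    out_dir: str = "out"
    case_id: str = "B"
    K: int = 1000
    n: int = 10_000
    seed: int = 0
    consumption_path: Optional[str] = None
    concentration_path: Optional[str] = None
    challenges_path: Optional[str] = None
    synthesize: bool = False
    truth: GroundTruth = field(default_factory=GroundTruth)
    case_b_mode: str = "simulated"
    percent_decimals: int = 2
    param_decimals: int = 3

    def __post_init__(self):
        if self.case_id not in ("A", "B", "C", "D"):
            raise InvalidParameterError(f"unknown case {self.case_id!r}")
        if not self.synthesize and not all(
            (self.consumption_path, self.concentration_path, self.challenges_path)
        ):
            raise InvalidParameterError(
                "provide the three input CSV paths or set synthesize=True"
            )


def _param_rows(label: str, dist: str, names, draws: np.ndarray,
                point: Sequence[float]) -> list[dict]:
    """Summaries of K parameter draws, one row per parameter."""
    rows = []
    for j, name in enumerate(names):
        col = draws[:, j]
        rows.append({
            "distribution": dist,
            "parameter": f"{name} - {label}",
            "mean": float(point[j]),
            "sd": float(np.std(col, ddof=1)),
            "p2.5": float(np.quantile(col, 0.025, method="median_unbiased")),
            "median": float(np.quantile(col, 0.5, method="median_unbiased")),
            "p97.5": float(np.quantile(col, 0.975, method="median_unbiased")),
        })
    return rows


def run_pipeline(config: RunConfig) -> Path:
    """Run synth/load -> fit -> risk -> uncertainty and write reports.

    Writes ``fitted_params.csv``, ``risk_summary.csv``,
    ``uncertainty_report.csv`` (cases B/C/D) and ``manifest.json`` under
    ``config.out_dir``; returns that directory.  Identical config and
    seed produce byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_root = np.random.SeedSequence(config.seed)
    sub = [int(s % (2**31)) for s in seed_root.generate_state(8)]

    if config.synthesize:
        world = generate_all(config.truth, seed=sub[0])
        consumption, weights = world["consumption"], None
        concentration = world["concentration"]
        challenges = world["challenges"]
        write_consumption(out / "consumption.csv", consumption)
        write_concentration(out / "concentration.csv", concentration)
        write_challenges(out / "challenges.csv", challenges)
    else:
        consumption, weights = read_consumption(config.consumption_path)
        concentration = read_concentration(config.concentration_path)
        challenges = read_challenges(config.challenges_path)

    # --- fits and their sampling distributions -----------------------------
    x_fit = fit_lognormal(consumption)
    y_ln_fit = fit_lognormal(concentration)
    y_exp_fit = fit_exponential(concentration)
    z_ln_fit = fit_interval_censored(challenges, family="lognormal")
    z_wb_fit = fit_interval_censored(challenges, family="weibull")

    Kp = config.K
    rows = []
    rows += _param_rows(
        "consumption", "Log normal", ("mu_X", "sigma_X"),
        draw_lognormal_params(x_fit, Kp, sub[1]),
        (x_fit.location, x_fit.scale),
    )
    rows += _param_rows(
        "concentration", "Log normal", ("mu_Y", "sigma_Y"),
        draw_lognormal_params(y_ln_fit, Kp, sub[2]),
        (y_ln_fit.location, y_ln_fit.scale),
    )
    rows += _param_rows(
        "concentration", "Exponential", ("lambda_Y",),
        draw_normal_params(y_exp_fit.rate, y_exp_fit.se_rate, Kp, sub[3],
                           positive=True).reshape(-1, 1),
        (y_exp_fit.rate,),
    )
    rows += _param_rows(
        "threshold", "Log normal", ("mu_Z", "sigma_Z"),
        draw_lognormal_params(z_ln_fit, Kp, sub[4]),
        (z_ln_fit.location, z_ln_fit.scale),
    )
    rows += _param_rows(
        "threshold", "Weibull", ("a_Z", "b_Z"),
        np.column_stack([
            draw_normal_params(z_wb_fit.shape, z_wb_fit.se_shape, Kp, sub[5],
                               positive=True),
            draw_normal_params(z_wb_fit.scale, z_wb_fit.se_scale, Kp, sub[6],
                               positive=True),
        ]),
        (z_wb_fit.shape, z_wb_fit.scale),
    )
    params_df = pd.DataFrame(rows)
    rounded = params_df.copy()
    num_cols = ["mean", "sd", "p2.5", "median", "p97.5"]
    rounded[num_cols] = rounded[num_cols].round(config.param_decimals)
    for c in num_cols:
        rounded[f"{c}_raw"] = params_df[c]
    rounded.to_csv(out / "fitted_params.csv", index=False, float_format=_FLOAT_FMT)

    # --- risk --------------------------------------------------------------
    if config.case_id == "A":
        spec = presets.case_a(
            params={"x": (x_fit.location, x_fit.scale),
                    "y": (y_ln_fit.location, y_ln_fit.scale),
                    "z": (z_ln_fit.location, z_ln_fit.scale)},
            K=config.K, n=config.n, seed=sub[7],
        )
    elif config.case_id == "B":
        spec = presets.case_b(
            params={"x": (x_fit.location, x_fit.scale, x_fit.n),
                    "y": (y_ln_fit.location, y_ln_fit.scale, y_ln_fit.n),
                    "z": (z_ln_fit.location, z_ln_fit.scale, z_ln_fit.n)},
            mode=config.case_b_mode, K=config.K, n=config.n, seed=sub[7],
        )
    elif config.case_id == "C":
        spec = presets.case_c_from_data(
            consumption, concentration, challenges,
            K=config.K, n=config.n, seed=sub[7],
        )
    else:
        spec = presets.case_d_from_data(
            consumption, concentration, challenges,
            consumption_weights=weights,
            K=config.K, n=config.n, seed=sub[7],
        )

    dist = run_case(spec)
    summary = dist.summary(as_percent=True)
    risk_df = pd.DataFrame([{
        "case": spec.metadata.get("label", config.case_id),
        **{k: round(v, config.percent_decimals) for k, v in summary.items()},
        **{f"{k}_raw": v for k, v in summary.items()},
        "sd_is_simulation_error_only": dist.sd_is_simulation_error_only,
    }])
    risk_df.to_csv(out / "risk_summary.csv", index=False, float_format=_FLOAT_FMT)

    # --- uncertainty -------------------------------------------------------
    if config.case_id in ("B", "C", "D"):
        delta = None
        if config.case_id == "B":
            delta = delta_method_variance(x_fit, y_ln_fit, z_ln_fit)
        sim = oat_decomposition(spec)
        report = decomposition_report(delta, sim)
        report.index.name = f"variance unit = {REPORT_UNIT:g} (proportion scale)"
        report.round(4).to_csv(out / "uncertainty_report.csv",
                               float_format=_FLOAT_FMT)

    # --- manifest ----------------------------------------------------------
    from . import __version__

    cfg = asdict(config)
    cfg["truth"] = asdict(config.truth)
    manifest = {
        "config": cfg,
        "derived_seeds": sub,
        "versions": {
            "allergenrisk": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
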