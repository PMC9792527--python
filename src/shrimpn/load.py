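"""Constituent-load estimation for the farm outlet channel.

Two estimators are provided for the seasonal nutrient load carried past the
outlet cross-section:

* direct integration — daily discharge x concentration summed over the
  period; and
* a rating-curve regression in the classical seven-term form used by
  load-calculation software: ln(load) regressed on centered ln discharge,
  its square, annual sine/cosine terms and a quadratic time trend, fitted by
  ordinary least squares with Duan's smearing factor correcting the
  back-transformation bias of the log model.

The rating curve lets loads be estimated for days with discharge but no
concentration measurement. A removal-efficiency report compares the
mass-balance input load with the estimated outlet load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .budget import removal_efficiency
from .units import flow_concentration_to_tons_per_day

__all__ = [
    "OutletRecord",
    "RatingCurveModel",
    "instantaneous_load",
    "direct_period_load",
    "fit_rating_curve",
    "estimate_period_load",
    "seasonal_report",
]

#: names of the six non-intercept regressors, in design-matrix order
_TERMS = ("lnq", "lnq2", "sin2piT", "cos2piT", "T", "T2")

#: minimum usable records for a seven-parameter fit
MIN_RECORDS = 14

#: days per year used to convert a breeding-day index to decimal time
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class OutletRecord:
    """One daily outlet observation: breeding-day index, discharge (L/s),
    total-N concentration (mg/l)."""

    day: int
    discharge_lps: float
    concentration_mgl: float

    def __post_init__(self) -> None:
        if self.discharge_lps < 0:
            raise ValueError(f"negative discharge on day {self.day}")
        if self.concentration_mgl < 0:
            raise ValueError(f"negative concentration on day {self.day}")


def instantaneous_load(discharge_lps: float, concentration_mgl: float) -> float:
    """Daily load (tons/day) from discharge (L/s) and concentration (mg/l)."""
    if discharge_lps < 0 or concentration_mgl < 0:
        raise ValueError("discharge and concentration must be >= 0")
    return flow_concentration_to_tons_per_day(discharge_lps, concentration_mgl)


def direct_period_load(series: Sequence[OutletRecord], interpolate_gaps: bool = False) -> float:
    """Total load (tons) over a period by summing daily loads.

    Gaps longer than one day raise a warning; with ``interpolate_gaps`` the
    missing days' loads are filled by linear interpolation between the
    bracketing observed daily loads.
    """
    if not series:
        raise ValueError("empty series")
    recs = sorted(series, key=lambda r: r.day)
    days = np.array([r.day for r in recs], dtype=float)
    loads = np.array([instantaneous_load(r.discharge_lps, r.concentration_mgl) for r in recs])
    gaps = np.diff(days)
    if np.any(gaps > 1):
        warnings.warn(
            f"{int(np.sum(gaps > 1))} gap(s) longer than one day in the series",
            stacklevel=2,
        )
        if interpolate_gaps:
            full_days = np.arange(days[0], days[-1] + 1)
            loads = np.interp(full_days, days, loads)
    return float(loads.sum())


@dataclass(frozen=True)
class RatingCurveModel:
    """A fitted seven-term log-load rating curve.

    ``coefficients`` maps term names (const, lnq, lnq2, sin2piT, cos2piT, T,
    T2) to OLS estimates; terms dropped as degenerate are absent.
    ``lnq_center``/``t_center`` are the centering constants applied before
    fitting and reused at prediction time. ``smearing_factor`` is Duan's
    back-transformation bias correction, the mean of exp(residuals).
    """

    coefficients: dict[str, float]
    lnq_center: float
    t_center: float
    residual_variance: float
    smearing_factor: float
    n_used: int
    n_excluded: int = 0
    dropped_terms: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.coefficients.values()))):
            raise ValueError("non-finite coefficients")


def _decimal_time(day: np.ndarray) -> np.ndarray:
    return np.asarray(day, dtype=float) / DAYS_PER_YEAR


def _design(lnq_c: np.ndarray, t_c: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnq": lnq_c,
            "lnq2": lnq_c**2,
            "sin2piT": np.sin(2 * np.pi * t_c),
            "cos2piT": np.cos(2 * np.pi * t_c),
            "T": t_c,
            "T2": t_c**2,
        }
    )


def fit_rating_curve(series: Sequence[OutletRecord]) -> RatingCurveModel:
    """Fit the seven-term rating curve to a daily outlet series by OLS.

    Records with zero discharge or concentration cannot enter the log model
    and are excluded (their count is reported on the model). Regressors that
    are (numerically) constant over the usable records — e.g. ln discharge
    under constant flow — are dropped before fitting.
    """
    recs = [r for r in series if r.discharge_lps > 0 and r.concentration_mgl > 0]
    n_excluded = len(series) - len(recs)
    if len(recs) < MIN_RECORDS:
        raise ValueError(
            f"need at least {MIN_RECORDS} records with positive discharge and "
            f"concentration, got {len(recs)}"
        )
    day = np.array([r.day for r in recs], dtype=float)
    q = np.array([r.discharge_lps for r in recs])
    c = np.array([r.concentration_mgl for r in recs])
    ln_load = np.log(flow_concentration_to_tons_per_day(q, c))
    lnq_center = float(np.log(q).mean())
    t_center = float(_decimal_time(day).mean())
    X = _design(np.log(q) - lnq_center, _decimal_time(day) - t_center)
    dropped = tuple(col for col in X.columns if np.ptp(X[col].to_numpy()) < 1e-12)
    if dropped:
        X = X.drop(columns=list(dropped))
    fit = sm.OLS(ln_load, sm.add_constant(X, has_constant="add")).fit()
    resid = np.asarray(fit.resid)
    dof = max(1, len(recs) - len(fit.params))
    return RatingCurveModel(
        coefficients={str(k): float(v) for k, v in fit.params.items()},
        lnq_center=lnq_center,
        t_center=t_center,
        residual_variance=float(resid @ resid / dof),
        smearing_factor=float(np.mean(np.exp(resid))),
        n_used=len(recs),
        n_excluded=n_excluded,
        dropped_terms=dropped,
    )


def predict_daily_load(
    model: RatingCurveModel, day: np.ndarray, discharge_lps: np.ndarray
) -> np.ndarray:
    """Smearing-corrected daily loads (tons/day) for given days and discharges.

    Zero-discharge days contribute zero load.
    """
    day = np.asarray(day, dtype=float)
    q = np.asarray(discharge_lps, dtype=float)
    if np.any(q < 0):
        raise ValueError("negative discharge")
    out = np.zeros_like(q)
    pos = q > 0
    if not np.any(pos):
        return out
    X = _design(np.log(q[pos]) - model.lnq_center, _decimal_time(day[pos]) - model.t_center)
    pred = np.full(pos.sum(), model.coefficients.get("const", 0.0))
    for term in _TERMS:
        if term in model.coefficients:
            pred += model.coefficients[term] * X[term].to_numpy()
    out[pos] = model.smearing_factor * np.exp(pred)
    return out


def estimate_period_load(
    model: RatingCurveModel,
    discharge_series: Iterable[tuple[int, float]] | Sequence[OutletRecord],
) -> float:
    """Total period load (tons): sum of bias-corrected daily predictions.

    ``discharge_series`` is either (day, discharge) pairs or outlet records
    (whose concentrations are ignored) covering every day of the period.
    """
    pairs = [
        (r.day, r.discharge_lps) if isinstance(r, OutletRecord) else (r[0], r[1])
        for r in discharge_series
    ]
    if not pairs:
        raise ValueError("empty discharge series")
    day = np.array([p[0] for p in pairs], dtype=float)
    q = np.array([p[1] for p in pairs], dtype=float)
    return float(predict_daily_load(model, day, q).sum())


def seasonal_report(model_input_load_t: float, estimated_output_load_t: float) -> dict:
    """Removal-efficiency report for one breeding season.

    Compares the mass-balance input load at the culture site with the
    estimated load leaving the outlet channel; the difference is attributed
    to retention and processing in the lagoon and channel.
    """
    eff = removal_efficiency(model_input_load_t, estimated_output_load_t)
    return {
        "input_load_t": float(model_input_load_t),
        "output_load_t": float(estimated_output_load_t),
        "removal_efficiency": eff,
        "removal_pct": int(round(eff * 100)),
    }
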