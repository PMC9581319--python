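"""Three-parameter logistic growth model for stem height / internode series.

The model is

    y(t) = k * y0 / (y0 + (k - y0) * exp(-r * t))

with ``y0`` the value at t = 0, ``k`` the carrying capacity (final
height in cm, or final internode count) and ``r`` the intrinsic growth
rate in 1/time (per day when t is day-of-year).  Fitting re-origins time
so that t = 0 is the first measurement day; this changes only the
implied ``y0``, never ``k`` or ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, FitFailureError, InvalidInputError

__all__ = [
    "GrowthSeries",
    "LogisticParams",
    "logistic_value",
    "fit_logistic",
    "summarize_growth",
]

#: positivity bound for y0 — fitted initial values can be vanishingly small
_EPS_Y0 = 1e-12


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic growth curve plus fit diagnostics."""

    k: float
    y0: float
    r: float
    r_squared: float = float("nan")
    converged: bool = True
    t_origin: float = 0.0  # day-of-year subtracted before fitting

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.y0 > 0 and self.r > 0):
            raise InvalidInputError(
                f"logistic parameters must be positive, got k={self.k}, "
                f"y0={self.y0}, r={self.r}"
            )
        if self.k <= self.y0:
            raise InvalidInputError(
                f"carrying capacity k={self.k} must exceed initial value y0={self.y0}"
            )


@dataclass(frozen=True)
class GrowthSeries:
    """One replicate's time series of a growth trait."""

    times: np.ndarray  # day-of-year
    values: np.ndarray  # cm or internode count
    plant_id: str = ""
    trait: str = "height"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", y)
        if t.ndim != 1 or t.shape != y.shape:
            raise InvalidInputError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(y < 0):
            raise InvalidInputError("growth values must be >= 0")


def _logistic(t, k, y0, r):
    return k * y0 / (y0 + (k - y0) * np.exp(-r * t))


def logistic_value(t, params: LogisticParams):
    """Evaluate the logistic curve; ``t`` is scalar or array, same origin
    as ``params`` (use ``t - params.t_origin`` for fitted parameters)."""
    return _logistic(np.asarray(t, dtype=float), params.k, params.y0, params.r)


def _initial_guesses(t: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    k0 = 1.05 * y.max()
    y00 = max(y[0], _EPS_Y0)
    # log-slope of the central segment as a rate guess
    pos = y > 0
    r0 = 0.1
    if pos.sum() >= 2:
        tp, yp = t[pos], np.log(y[pos])
        mid = slice(max(0, len(tp) // 4), max(2, 3 * len(tp) // 4))
        if len(tp[mid]) >= 2 and np.ptp(tp[mid]) > 0:
            slope = np.polyfit(tp[mid], yp[mid], 1)[0]
            if np.isfinite(slope) and slope > 0:
                r0 = float(slope)
    guesses = [(k0, y00, r0)]
    for r_alt in (0.02, 0.05, 0.1, 0.2, 0.5):
        guesses.append((k0, y00, r_alt))
        guesses.append((k0, max(0.01 * y.max(), _EPS_Y0), r_alt))
    return guesses


def fit_logistic(series: GrowthSeries) -> LogisticParams:
    """Ordinary-least-squares fit of the logistic model to one series.

    Requires at least 4 time points (three parameters plus one residual
    degree of freedom) and non-constant values.  Time is re-origined to
    the first measurement day; the returned ``t_origin`` records the
    shift so the curve can be evaluated on the original axis.
    """
    t_raw = series.times
    y = series.values
    if t_raw.size < 4:
        raise DegenerateDataError(
            f"logistic fit needs >= 4 time points, got {t_raw.size}"
        )
    if np.ptp(y) == 0:
        raise DegenerateDataError("constant series: logistic fit is degenerate")
    t0 = float(t_raw[0])
    t = t_raw - t0

    bounds = ([_EPS_Y0, _EPS_Y0, _EPS_Y0], [np.inf, np.inf, np.inf])
    best = None
    last_err: Exception | None = None
    for p0 in _initial_guesses(t, y):
        try:
            popt, _ = curve_fit(
                _logistic, t, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:  # no convergence for this start
            last_err = exc
            continue
        resid = y - _logistic(t, *popt)
        sse = float(np.sum(resid**2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise FitFailureError(
            "logistic fit failed to converge from any start",
            diagnostics={"n_points": int(t.size), "last_error": repr(last_err)},
        )
    (k, y0, r), sse = best
    if k <= y0:
        # decreasing-curve solution; rejected by default parameter validity
        raise FitFailureError(
            "fit converged to a non-growing curve (k <= y0)",
            diagnostics={"k": float(k), "y0": float(y0), "r": float(r)},
        )
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return LogisticParams(
        k=float(k), y0=float(y0), r=float(r),
        r_squared=max(0.0, min(1.0, r2)), converged=True, t_origin=t0,
    )


def summarize_growth(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean and SD of the fitted logistic parameters.

    ``fits`` is long-format with one row per fitted replicate and columns
    ``factorA``, ``factorB``, ``k``, ``y0``, ``r`` (extra columns pass
    through ungrouped).  Returns one row per (factorA, factorB) group
    with ``<param>_mean``, ``<param>_sd`` and ``n`` — the shape used to
    feed the two-way ANOVA on growth parameters.
    """
    required = {"factorA", "factorB", "k", "y0", "r"}
    missing = required - set(fits.columns)
    if missing:
        raise InvalidInputError(f"fit table missing columns: {sorted(missing)}")
    if fits.empty:
        raise InvalidInputError("empty fit table")
    grouped = fits.groupby(["factorA", "factorB"], sort=True)
    rows = []
    for (fa, fb), grp in grouped:
        row = {"factorA": fa, "factorB": fb, "n": len(grp)}
        for par in ("k", "y0", "r"):
            row[f"{par}_mean"] = grp[par].mean()
            row[f"{par}_sd"] = grp[par].std(ddof=1) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
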