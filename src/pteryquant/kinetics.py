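"""Exponential healing kinetics and the derived comparison statistics.

Longitudinal lesion measurements in this model follow a single-exponential
decay y = A * exp(k * t) with k < 0 for a healing lesion (units: per day).
The default fit is log-linear -- ordinary least squares of ln(y) on t -- which
recovers (A, k) exactly on noiseless exponential data; a nonlinear
least-squares fit on the original scale, initialized from the log-linear
solution, is available for noisy or near-zero series.

The comparison statistics turn pairs of fits into the quantities reported in
treatment studies: the percent reduction of the fitted initial lesion size,
the percent slowdown of the healing rate, the percent decrease over an
observation interval, relative fold change against a baseline, and the ratio
of two linear trend slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class DecayFit:
    """Fitted y = A * exp(k * t)."""

    amplitude: float  # A, same units as the measurement
    rate: float  # k, per day; negative = healing
    r2: float
    n_points: int
    method: str  # "log-linear" or "nonlinear"


@dataclass
class LinearTrend:
    """Fitted y = slope * x + intercept."""

    slope: float
    intercept: float
    r2: float


def _r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_linear_trend(x, y) -> LinearTrend:
    """Ordinary least-squares line through >= 2 points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need at least 2 (x, y) points")
    slope, intercept = np.polyfit(x, y, 1)
    return LinearTrend(float(slope), float(intercept), _r2(y, slope * x + intercept))


def fit_exponential_decay(days, values, method: str = "log-linear") -> DecayFit:
    """Fit y = A * exp(k * t) to a (day, value) series.

    log-linear: OLS of ln(value) on day, A = e^intercept, k = slope; requires
    strictly positive values.  nonlinear: least squares on the original
    scale, initialized from the log-linear fit (or from the data range when
    values are not all positive).
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3 or t.size != y.size:
        raise ValueError("need at least 3 (day, value) points")
    if method == "log-linear":
        if np.any(y <= 0):
            raise ValueError(
                "log-linear fit requires strictly positive values; "
                "use method='nonlinear' for series touching zero"
            )
        ln_y = np.log(y)
        k, ln_a = np.polyfit(t, ln_y, 1)
        return DecayFit(float(np.exp(ln_a)), float(k), _r2(ln_y, k * t + ln_a), t.size, method)
    if method == "nonlinear":
        if np.all(y > 0):
            init = fit_exponential_decay(t, y, "log-linear")
            p0 = (init.amplitude, init.rate)
        else:
            p0 = (float(max(y.max(), 1e-9)), -0.1)
        popt, _ = curve_fit(lambda tt, a, k: a * np.exp(k * tt), t, y, p0=p0, maxfev=10000)
        a, k = popt
        return DecayFit(float(a), float(k), _r2(y, a * np.exp(k * t)), t.size, method)
    raise ValueError(f"unknown method {method!r}")


def percent_initial_difference(fit_treat: DecayFit, fit_ref: DecayFit) -> float:
    """Percent reduction of fitted initial lesion size: 100*(1 - A_treat/A_ref)."""
    if fit_ref.amplitude <= 0:
        raise ValueError("reference amplitude must be positive")
    return 100.0 * (1.0 - fit_treat.amplitude / fit_ref.amplitude)


def rate_slowdown(fit_treat: DecayFit, fit_ref: DecayFit) -> float:
    """Percent slowdown of healing: 100*(1 - |k_treat| / |k_ref|)."""
    if fit_ref.rate == 0:
        raise ValueError("reference rate must be nonzero")
    return 100.0 * (1.0 - abs(fit_treat.rate) / abs(fit_ref.rate))


def interval_decrease(fit: DecayFit, t0: float, t1: float) -> float:
    """Percent decrease over [t0, t1]: 100*(1 - e^(k*(t1-t0))).

    Depends only on the rate and the span, not on the amplitude or on the
    absolute day labels.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    return 100.0 * (1.0 - np.exp(fit.rate * (t1 - t0)))


def fold_change(value: float, baseline: float) -> float:
    """Relative change against a baseline: (value - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return (value - baseline) / baseline


def trend_ratio(trend_a: LinearTrend, trend_b: LinearTrend) -> float:
    """Ratio of two linear-trend slopes, slope_a / slope_b."""
    if trend_b.slope == 0:
        raise ValueError("denominator slope must be nonzero")
    return trend_a.slope / trend_b.slope
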