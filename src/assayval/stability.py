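"""Storage-stability regression and drift-limit duration.

For each donor and storage condition the measurand is regressed on
storage time (ordinary least squares over all replicates).  Stability
duration follows the drift-limit convention for stability studies:

* drift limits are ``baseline_mean * (1 +- drift_limit/100)``, anchored
  to the mean of the baseline (t = 0) replicates;
* if the slope is significantly positive (two-sided p < 0.05), the
  duration is the earliest time at which the pointwise one-sided upper
  95% confidence bound of the regression mean crosses the upper limit;
  a significantly negative slope uses the lower bound against the lower
  limit;
* if the slope is not significant, or the band never crosses a limit
  inside the tested period, the duration is the study horizon (the
  maximum tested time point).

The crossing is solved by bisection to 1e-3 days.  With zero residual
variance the confidence band collapses onto the fitted line, so a
noiseless drifting course yields the exact line/limit intersection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import as_frame
from ._regression import OLSFit, ols

__all__ = ["StabilityFit", "fit_stability_regression", "stability_duration",
           "analyze_stability_course"]

ALPHA = 0.05


@dataclass(frozen=True)
class StabilityFit:
    """Per-donor regression of measurand vs storage time."""

    donor: str
    condition: str
    baseline_mean: float
    slope: float
    intercept: float
    slope_p_value: float
    n_timepoints: int
    duration_days: float | None = None
    duration_branch: str | None = None   # which rule produced the duration
    _ols: OLSFit | None = None


def fit_stability_regression(course, donor: str = "", condition: str = "",
                             max_missing_fraction: float = 0.10) -> StabilityFit:
    """OLS of value on timepoint_days over all replicates of one course.

    Requires the baseline (t = 0) plus at least 2 additional time points,
    and no more than ``max_missing_fraction`` lost results.
    """
    df = as_frame(course)
    n_total = len(df)
    missing = float((df["status"] == "no_result").mean()) if n_total else 1.0
    ok = df[df["status"] == "ok"]
    t = ok["timepoint_days"].to_numpy(dtype=float)
    y = ok["value"].to_numpy(dtype=float)
    timepoints = np.unique(t)
    if 0.0 not in timepoints or len(timepoints) < 3:
        raise ValueError(
            "stability acceptance requires the baseline (t=0) plus at least "
            f"2 additional time points; have {sorted(timepoints)}")
    if missing > max_missing_fraction:
        raise ValueError(f"missing fraction {missing:.2f} exceeds "
                         f"{max_missing_fraction:.2f} allowance")
    X = np.column_stack([np.ones_like(t), t])
    fit = ols(X, y)
    return StabilityFit(
        donor=donor, condition=condition,
        baseline_mean=float(y[t == 0.0].mean()),
        slope=float(fit.beta[1]), intercept=float(fit.beta[0]),
        slope_p_value=float(fit.p_values[1]),
        n_timepoints=len(timepoints), _ols=fit)


def _one_sided_bound(fit: OLSFit, t: np.ndarray, upper: bool) -> np.ndarray:
    X = np.column_stack([np.ones_like(t), t])
    mean = fit.predict(X)
    if fit.sigma == 0.0:
        return mean
    tq = stats.t.ppf(1.0 - ALPHA, fit.df_resid)
    half = tq * fit.se_mean(X)
    return mean + half if upper else mean - half


def stability_duration(fit: StabilityFit, drift_limit: float = 10.0,
                       horizon: float | None = None,
                       tol: float = 1e-3) -> StabilityFit:
    """Attach the drift-limit stability duration to a fitted course.

    ``horizon`` defaults to the maximum tested time point implied by the
    fit's data.  Returns a new :class:`StabilityFit` with
    ``duration_days`` and ``duration_branch`` set; the branch records
    whether the slope was non-significant, the band never crossed, or a
    crossing was found.
    """
    if drift_limit <= 0:
        raise ValueError("drift_limit must be > 0")
    if fit._ols is None:
        raise ValueError("fit lacks regression internals; use fit_stability_regression")
    if horizon is None:
        raise ValueError("horizon (maximum tested time point) is required")

    if fit.slope_p_value >= ALPHA:
        return _with_duration(fit, float(horizon), "slope not significant")

    upper = fit.slope > 0
    limit = fit.baseline_mean * (1.0 + (drift_limit if upper else -drift_limit) / 100.0)

    def excess(t: float) -> float:
        b = float(_one_sided_bound(fit._ols, np.array([t]), upper)[0])
        return (b - limit) if upper else (limit - b)

    # bracket the first crossing on a coarse grid, then bisect
    grid = np.linspace(0.0, float(horizon), 512)
    vals = np.array([excess(t) for t in grid])
    crossing = None
    if vals[0] >= 0:
        crossing = 0.0
    else:
        idx = np.nonzero(vals >= 0)[0]
        if idx.size:
            lo, hi = grid[idx[0] - 1], grid[idx[0]]
            while hi - lo > tol:
                mid = (lo + hi) / 2.0
                if excess(mid) >= 0:
                    hi = mid
                else:
                    lo = mid
            crossing = hi
    if crossing is None:
        return _with_duration(fit, float(horizon), "no crossing within period")
    return _with_duration(fit, float(crossing), "band crossed drift limit")


def _with_duration(fit: StabilityFit, duration: float, branch: str) -> StabilityFit:
    return StabilityFit(
        donor=fit.donor, condition=fit.condition,
        baseline_mean=fit.baseline_mean, slope=fit.slope,
        intercept=fit.intercept, slope_p_value=fit.slope_p_value,
        n_timepoints=fit.n_timepoints, duration_days=duration,
        duration_branch=branch, _ols=fit._ols)


def analyze_stability_course(course, donor: str = "", condition: str = "",
                             drift_limit: float = 10.0,
                             horizon: float | None = None) -> StabilityFit:
    """Fit one course and attach its duration in a single call."""
    df = as_frame(course)
    if horizon is None:
        horizon = float(df["timepoint_days"].max())
    fit = fit_stability_regression(df, donor, condition)
    return stability_duration(fit, drift_limit, horizon)
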