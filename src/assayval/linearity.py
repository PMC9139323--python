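"""Linearity assessment of a dilution/intermixture series.

The series is measured at equidistant assigned concentrations (levels of
a linear intermixture between a low and a high fraction).  Assessment
follows the polynomial-hierarchy convention for analytical linearity
studies: ordinary least-squares fits of order 1, 2 and 3 on all replicate
points, two-sided t-tests on the nonlinear coefficients (b2 of the
quadratic, b3 of the cubic), and — when any nonlinear term is significant
at 0.05 — a *degree of nonlinearity*: the maximum over levels of the
relative departure of the best nonlinear fit from the straight-line fit.

The composite verdict passes when:

* at least 5 consecutive levels have results with no more than 15%
  missing data,
* Pearson r >= 0.95 (computed on all replicate points vs assigned
  concentration),
* every level's repeatability CV < 15%,
* and either no nonlinear term is significant or the degree of
  nonlinearity stays below 10%.

The upper limit of the linear range (LoL) is the highest assigned
concentration inside the longest consecutive stretch of passing levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import as_frame
from ._regression import ols

__all__ = ["LinearityCriteria", "LinearityVerdict", "fit_polynomial_hierarchy",
           "assess_linearity"]


@dataclass(frozen=True)
class LinearityCriteria:
    r_threshold: float = 0.95
    cv_threshold: float = 15.0           # per-level repeatability, %
    max_missing_fraction: float = 0.15   # per level
    min_consecutive_levels: int = 5
    nonlinearity_threshold: float = 10.0  # degree of nonlinearity, %
    alpha: float = 0.05


@dataclass(frozen=True)
class PolynomialHierarchy:
    """OLS fits of order 1-3 with t-test p-values on b2 and b3."""

    coefficients: dict[int, np.ndarray]     # order -> [b0, b1, ...]
    nonlinear_p_values: dict[str, float]    # {"b2": ..., "b3": ...}
    residual_se: dict[int, float]           # order -> standard error of regression
    skipped: tuple[str, ...] = ()


@dataclass(frozen=True)
class LinearityVerdict:
    pearson_r: float
    per_level_cv: dict[int, float]
    hierarchy: PolynomialHierarchy
    degree_of_nonlinearity: float | None
    lol: float | None
    pass_flag: bool
    reasons: tuple[str, ...] = ()


def fit_polynomial_hierarchy(x, y, alpha: float = 0.05) -> PolynomialHierarchy:
    """Fit orders 1..3 on all replicate points; t-test b2 and b3.

    An order with fewer than ``order + 2`` distinct x values is skipped
    with a logged reason rather than fitted rank-deficiently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_distinct = len(np.unique(x))
    coefficients: dict[int, np.ndarray] = {}
    residual_se: dict[int, float] = {}
    p_values: dict[str, float] = {}
    skipped: list[str] = []
    for order in (1, 2, 3):
        if n_distinct < order + 2:
            skipped.append(f"order {order} skipped: needs {order + 2} distinct "
                           f"levels, have {n_distinct}")
            continue
        X = np.vander(x, order + 1, increasing=True)
        fit = ols(X, y)
        coefficients[order] = fit.beta
        residual_se[order] = fit.sigma
        if order == 2:
            p_values["b2"] = float(fit.p_values[2])
        elif order == 3:
            p_values["b3"] = float(fit.p_values[3])
    if 1 not in coefficients:
        raise ValueError("cannot fit even a straight line: " + "; ".join(skipped))
    return PolynomialHierarchy(coefficients=coefficients,
                               nonlinear_p_values=p_values,
                               residual_se=residual_se,
                               skipped=tuple(skipped))


def degree_of_nonlinearity(hierarchy: PolynomialHierarchy,
                           level_concentrations: np.ndarray,
                           alpha: float = 0.05) -> tuple[float | None, int | None]:
    """Max relative departure of the best nonlinear fit from the line.

    Evaluated at the assigned level concentrations.  The best nonlinear
    model is the significant-term model with the smaller standard error
    of regression, ties broken toward lower order.  Returns
    ``(degree_percent, best_order)``; ``(None, None)`` when no nonlinear
    term is significant.
    """
    significant = [o for o, key in ((2, "b2"), (3, "b3"))
                   if hierarchy.nonlinear_p_values.get(key, 1.0) < alpha
                   and o in hierarchy.coefficients]
    if not significant:
        return None, None
    best = min(significant, key=lambda o: (hierarchy.residual_se[o], o))
    xs = np.asarray(level_concentrations, dtype=float)
    lin = np.vander(xs, 2, increasing=True) @ hierarchy.coefficients[1]
    nonlin = np.vander(xs, best + 1, increasing=True) @ hierarchy.coefficients[best]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(nonlin - lin) / np.abs(lin)
    rel = rel[np.isfinite(rel)]
    return float(rel.max() * 100.0), best


def assess_linearity(series, assigned: dict[int, float],
                     criteria: LinearityCriteria | None = None) -> LinearityVerdict:
    """Composite linearity verdict for one analyte's intermixture series.

    ``assigned`` maps level index -> assigned concentration.  ``series``
    is a measurement collection/DataFrame with ``level``, ``value`` and
    ``status`` columns.
    """
    crit = criteria or LinearityCriteria()
    df = as_frame(series)
    if df["level"].isna().all():
        raise ValueError("series carries no level annotations")
    reasons: list[str] = []

    # per-level bookkeeping: missing fraction and repeatability CV
    per_level_cv: dict[int, float] = {}
    level_ok: dict[int, bool] = {}
    for lev in sorted(assigned):
        sub = df[df["level"] == lev]
        n_total = len(sub)
        okv = sub.loc[sub["status"] == "ok", "value"].to_numpy(dtype=float)
        missing = 1.0 - (len(okv) / n_total if n_total else 0.0)
        ok = True
        if n_total == 0 or missing > crit.max_missing_fraction:
            ok = False
            reasons.append(f"level {lev}: missing fraction "
                           f"{missing:.2f} > {crit.max_missing_fraction:.2f}")
        if len(okv) >= 2:
            mean = okv.mean()
            cv = 100.0 * okv.std(ddof=1) / mean if mean > 0 else math.inf
            per_level_cv[lev] = cv
            if cv >= crit.cv_threshold:
                ok = False
                reasons.append(f"level {lev}: repeatability CV "
                               f"{cv:.1f}% >= {crit.cv_threshold:.0f}%")
        elif len(okv) == 1:
            per_level_cv[lev] = 0.0
        level_ok[lev] = ok

    ok_rows = df[(df["status"] == "ok") & df["level"].notna()]
    if ok_rows.empty:
        raise ValueError("all levels missing")
    x = ok_rows["level"].map(assigned).to_numpy(dtype=float)
    y = ok_rows["value"].to_numpy(dtype=float)

    if np.ptp(y) == 0 or np.ptp(x) == 0:
        r = 1.0 if np.ptp(x) > 0 else 0.0  # constant response: degenerate
    else:
        r = float(stats.pearsonr(x, y).statistic)
    if r < crit.r_threshold:
        reasons.append(f"Pearson r {r:.3f} < {crit.r_threshold}")

    hierarchy = fit_polynomial_hierarchy(x, y, crit.alpha)
    degree, _best = degree_of_nonlinearity(
        hierarchy, np.array([assigned[l] for l in sorted(assigned)]), crit.alpha)
    if degree is not None and degree >= crit.nonlinearity_threshold:
        reasons.append(f"degree of non-linearity {degree:.1f}% >= "
                       f"{crit.nonlinearity_threshold:.0f}%")

    # longest consecutive run of passing levels
    best_run: list[int] = []
    run: list[int] = []
    for lev in sorted(assigned):
        if level_ok.get(lev, False):
            run.append(lev)
            # ties go to the later stretch: LoL is an upper limit
            if len(run) >= len(best_run):
                best_run = list(run)
        else:
            run = []
    if len(best_run) < crit.min_consecutive_levels:
        reasons.append(f"only {len(best_run)} consecutive passing level(s); "
                       f"need {crit.min_consecutive_levels}")
        lol = None
    else:
        lol = assigned[best_run[-1]]

    return LinearityVerdict(
        pearson_r=r, per_level_cv=per_level_cv, hierarchy=hierarchy,
        degree_of_nonlinearity=degree, lol=lol,
        pass_flag=not reasons, reasons=tuple(reasons))
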