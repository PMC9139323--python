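"""Trueness evaluation: Passing-Bablok regression and spike recovery.

Passing-Bablok regression is the nonparametric method-comparison fit of
clinical chemistry: the slope is the shifted median of all pairwise
slopes S_ij = (y_j - y_i)/(x_j - x_i), robust to outliers and to
measurement error in both axes, and the intercept is the median of
y_i - slope * x_i.  The classical conventions apply:

* pairs with x_i == x_j and y_i == y_j contribute nothing;
* pairs with x_i == x_j and y_i != y_j contribute an infinite-magnitude
  slope with the sign of y_j - y_i;
* slopes equal to exactly -1 are discarded;
* the median position is shifted by K, the number of slopes below -1,
  which makes the estimator equivariant under exchanging x and y.

Confidence intervals use the rank-based normal approximation
(C = z * sqrt(n(n-1)(2n+5)/18)).

For analytes without a reference method, trueness is assessed by spike
recovery: known amounts are added on top of a mock-spiked aliquot and
the recovered fraction plus a Passing-Bablok fit of observed vs expected
(mock + added) are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionEstimate",
    "TruenessVerdict",
    "TruenessCriteria",
    "DEFAULT_TRUENESS_CRITERIA",
    "passing_bablok",
    "assess_trueness",
    "spike_recovery",
]


@dataclass(frozen=True)
class RegressionEstimate:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    pearson_r: float
    n: int

    def equation(self, decimals: int = 3) -> str:
        """Render like a method-comparison report, e.g. ``y = 1.028x - 5.364``."""
        sign = "+" if self.intercept >= 0 else "-"
        return (f"y = {self.slope:.{decimals}f}x {sign} "
                f"{abs(self.intercept):.{decimals}f}")


@dataclass(frozen=True)
class TruenessCriteria:
    slope_tolerance: float
    r_threshold: float = 0.90


#: per-analyte acceptance: slope within 1 +- tolerance and r >= threshold
DEFAULT_TRUENESS_CRITERIA = {
    "creatinine": TruenessCriteria(slope_tolerance=0.15),
    "myo_inositol": TruenessCriteria(slope_tolerance=0.15),
    "valine": TruenessCriteria(slope_tolerance=0.075),
}


@dataclass(frozen=True)
class TruenessVerdict:
    analyte: str
    slope_tolerance: float
    r_threshold: float
    pass_flag: bool
    reasons: tuple[str, ...] = ()


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """All valid pairwise slopes and the offset K (count of slopes < -1)."""
    n = len(x)
    slopes = []
    for i in range(n - 1):
        dx = x[i + 1:] - x[i]
        dy = y[i + 1:] - y[i]
        for j in range(len(dx)):
            if dx[j] == 0:
                if dy[j] == 0:
                    continue            # identical points: no information
                s = math.inf if dy[j] > 0 else -math.inf
            else:
                s = dy[j] / dx[j]
            if s == -1.0:
                continue                # would flip sign under axis exchange
            slopes.append(s)
    arr = np.sort(np.array(slopes, dtype=float))
    k = int((arr < -1.0).sum())
    return arr, k


def _shifted_median(sorted_slopes: np.ndarray, k: int) -> float:
    n = len(sorted_slopes)
    if n == 0:
        raise ValueError("no valid pairwise slopes")
    if n % 2:
        return float(sorted_slopes[(n + 1) // 2 + k - 1])
    lo = sorted_slopes[n // 2 + k - 1]
    hi = sorted_slopes[n // 2 + k]
    return float((lo + hi) / 2.0)


def passing_bablok(x, y, ci_level: float = 0.95) -> RegressionEstimate:
    """Passing-Bablok regression of y on x.

    Requires at least 3 paired finite values and a non-degenerate
    abscissa.  The Pearson correlation of the same pairs is carried on
    the estimate for the acceptance rule.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all x identical")

    slopes, k = _pairwise_slopes(x, y)
    slope = _shifted_median(slopes, k)
    if not math.isfinite(slope):
        raise ValueError("slope estimate is not finite; data are degenerate")
    intercept = float(np.median(y - slope * x))

    # rank-based normal-approximation CI on the slope
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    big_n = len(slopes)
    c = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((big_n - c) / 2.0))
    m2 = big_n - m1 + 1
    lo_idx = min(max(m1 + k, 1), big_n) - 1
    hi_idx = min(max(m2 + k, 1), big_n) - 1
    slope_lo, slope_hi = float(slopes[lo_idx]), float(slopes[hi_idx])
    int_lo = float(np.median(y - slope_hi * x))
    int_hi = float(np.median(y - slope_lo * x))
    if int_lo > int_hi:
        int_lo, int_hi = int_hi, int_lo

    if np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return RegressionEstimate(slope=slope, intercept=intercept,
                              slope_ci=(slope_lo, slope_hi),
                              intercept_ci=(int_lo, int_hi),
                              pearson_r=r, n=n)


def assess_trueness(fit: RegressionEstimate, analyte: str,
                    criteria: dict[str, TruenessCriteria] | None = None
                    ) -> TruenessVerdict:
    """Accept when |slope - 1| <= tolerance and r >= threshold."""
    table = criteria or DEFAULT_TRUENESS_CRITERIA
    if analyte not in table:
        raise ValueError(f"no trueness tolerance configured for {analyte!r}")
    crit = table[analyte]
    reasons = []
    if abs(fit.slope - 1.0) > crit.slope_tolerance:
        reasons.append(f"slope {fit.slope:.3f} outside 1.0 +- "
                       f"{crit.slope_tolerance}")
    if fit.pearson_r < crit.r_threshold:
        reasons.append(f"r {fit.pearson_r:.3f} < {crit.r_threshold}")
    return TruenessVerdict(analyte=analyte,
                           slope_tolerance=crit.slope_tolerance,
                           r_threshold=crit.r_threshold,
                           pass_flag=not reasons, reasons=tuple(reasons))


def spike_recovery(mock_results, spiked_results, added
                   ) -> tuple[pd.DataFrame, RegressionEstimate | None]:
    """Spike-recovery table and observed-vs-expected regression.

    Per aligned pair: recovery % = (spiked - mock)/added * 100; the
    expected value for the regression is mock + added.  The regression is
    ``None`` when the expected values are all identical (a single spike
    level), where only the recovery column is informative.
    """
    mock = np.asarray(mock_results, dtype=float)
    spiked = np.asarray(spiked_results, dtype=float)
    add = np.asarray(added, dtype=float)
    if not (len(mock) == len(spiked) == len(add)):
        raise ValueError("mock, spiked and added must be aligned equal-length lists")
    if (add <= 0).any():
        raise ValueError("added amounts must be > 0")
    recovery = (spiked - mock) / add * 100.0
    expected = mock + add
    table = pd.DataFrame({"mock": mock, "added": add, "spiked": spiked,
                          "expected": expected, "recovery_percent": recovery})
    fit = None
    if len(expected) >= 3 and np.ptp(expected) > 0:
        fit = passing_bablok(expected, spiked)
    return table, fit
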