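"""Limit of blank, detection and quantification estimation.

The estimators follow the standard clinical-laboratory convention for
detection-capability studies:

* **LoB** — from pooled blank-pool results, either parametric
  (``mean + z_{1-alpha} * sd``) or nonparametric (interpolated order
  statistic at rank position ``0.5 + B*(1-alpha)``).  In ``auto`` mode a
  Shapiro-Wilk test at 0.05 decides which path applies.
* **Cochran's C** — homogeneity of the low-level pools' variances
  (largest variance over the sum); the critical value uses the closed
  form from the F distribution.
* **LoD** — classical path (variances homogeneous):
  ``LoB + c_p * SD_pooled`` with ``c_p = z_{1-beta} / (1 - 1/(4f))``,
  ``f`` the pooled degrees of freedom.  Variant path (Cochran fails):
  the lowest pool mean at which at least 95% of that pool's results
  exceed LoB.
* **LoQ** — per reagent lot, the minimum pool mean whose
  within-laboratory CV (day-nested) is below the threshold (default
  20%); the overall LoQ is the maximum over lots.

The upper limit of the linear range (LoL) comes from the linearity
module and is merged into :class:`DetectionLimits` here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import as_frame
from .precision import within_laboratory_cv

__all__ = [
    "DetectionLimits",
    "CochranResult",
    "estimate_lob",
    "cochran_c_test",
    "estimate_lod",
    "estimate_loq",
    "estimate_detection_limits",
]

MIN_BLANKS = 20


@dataclass(frozen=True)
class CochranResult:
    """Outcome of Cochran's C homogeneity test on group variances."""

    statistic: float
    critical_value: float
    n_groups: int
    df_per_group: int
    pass_flag: bool


@dataclass(frozen=True)
class DetectionLimits:
    """LoB/LoD/LoQ(/LoL) for one analyte, with method provenance."""

    analyte: str
    lob: float
    lod: float
    loq: float
    lol: float | None = None
    lob_method: str = "parametric"
    lod_method: str = "classical"
    per_lot_loq: dict[str, float] = field(default_factory=dict)
    consistent: bool = True
    notes: tuple[str, ...] = ()


def _nonparametric_percentile(sorted_values: np.ndarray, alpha: float) -> float:
    """Interpolated order statistic at rank 0.5 + B*(1-alpha), 1-based."""
    b = len(sorted_values)
    pos = 0.5 + b * (1.0 - alpha)
    lo = int(math.floor(pos))
    frac = pos - lo
    lo_idx = min(max(lo, 1), b) - 1
    hi_idx = min(lo + 1, b) - 1
    return float(sorted_values[lo_idx] * (1 - frac) + sorted_values[hi_idx] * frac)


def estimate_lob(blanks, alpha: float = 0.05, method: str = "auto") -> tuple[float, str]:
    """Limit of blank from pooled blank results.

    ``blanks`` may be a measurement collection/DataFrame or a plain array
    of blank values.  Returns ``(lob, method_used)`` with ``method_used``
    in ``{"parametric", "nonparametric"}``.
    """
    values = _values(blanks)
    if len(values) < MIN_BLANKS:
        raise ValueError(
            f"need at least {MIN_BLANKS} blank results, got {len(values)}")
    if method not in ("auto", "parametric", "nonparametric"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        if np.allclose(values, values[0]):
            method = "nonparametric"  # degenerate; Shapiro undefined
        else:
            method = "nonparametric" if stats.shapiro(values).pvalue < 0.05 \
                else "parametric"
    if method == "parametric":
        z = stats.norm.ppf(1.0 - alpha)
        lob = float(values.mean() + z * values.std(ddof=1))
    else:
        lob = _nonparametric_percentile(np.sort(values), alpha)
    return max(lob, 0.0), method


def cochran_c_test(group_variances, df_per_group: int, alpha: float = 0.05) -> CochranResult:
    """Cochran's C test for homogeneity of variances across groups.

    C = max variance / sum of variances; the upper critical value is
    ``1 / (1 + (k-1)/F)`` with ``F`` the upper ``alpha/k`` quantile of the
    F distribution on ``(df, (k-1)*df)`` degrees of freedom.
    """
    v = np.asarray(list(group_variances), dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 groups")
    if (v < 0).any():
        raise ValueError("variances must be >= 0")
    total = v.sum()
    if total == 0:
        raise ValueError("degenerate variances: all zero")
    k = len(v)
    c = float(v.max() / total)
    f = stats.f.isf(alpha / k, df_per_group, (k - 1) * df_per_group)
    crit = 1.0 / (1.0 + (k - 1) / f)
    return CochranResult(statistic=c, critical_value=float(crit),
                         n_groups=k, df_per_group=df_per_group,
                         pass_flag=c <= crit)


def estimate_lod(low_panels, lob: float, alpha: float = 0.05,
                 beta: float = 0.05) -> tuple[float, str]:
    """Limit of detection from low-level pools, given the LoB.

    Runs Cochran's C on the pools' variances.  If homogeneous, the
    classical path returns ``LoB + c_p * SD_pooled``; otherwise the
    variant path scans pools (lowest mean first) for the first whose
    results exceed LoB at least 95% of the time.  Returns
    ``(lod, method_used)``.
    """
    df = _ok_frame(low_panels)
    pools = {str(p): sub["value"].to_numpy(dtype=float)
             for p, sub in df.groupby("pool_id", sort=True)}
    if len(pools) < 2:
        raise ValueError("need at least 2 low-level pools")
    for p, v in pools.items():
        if len(v) < MIN_BLANKS:
            raise ValueError(f"pool {p}: need at least {MIN_BLANKS} results")
    variances = {p: float(np.var(v, ddof=1)) for p, v in pools.items()}
    df_common = int(round(np.mean([len(v) - 1 for v in pools.values()])))
    if all(v == 0.0 for v in variances.values()):
        # perfectly constant pools: trivially homogeneous, SD_pooled = 0
        return float(lob), "classical"
    cochran = cochran_c_test(list(variances.values()), df_common, alpha)
    if cochran.pass_flag:
        n_total = sum(len(v) for v in pools.values())
        f = n_total - len(pools)
        sd_pooled = math.sqrt(
            sum((len(v) - 1) * variances[p] for p, v in pools.items()) / f)
        c_p = stats.norm.ppf(1.0 - beta) / (1.0 - 1.0 / (4.0 * f))
        return float(lob + c_p * sd_pooled), "classical"
    # variant path: lowest pool mean with >= 95% exceedance over LoB
    threshold = 1.0 - beta
    for p in sorted(pools, key=lambda p: pools[p].mean()):
        v = pools[p]
        if (v > lob).mean() >= threshold:
            return float(v.mean()), "nonparametric_variant"
    raise ValueError("LoD not reached within tested range: no pool has "
                     f">= {threshold:.0%} of results above LoB")


def estimate_loq(low_panels, cv_threshold: float = 20.0) -> tuple[float, dict[str, float]]:
    """Limit of quantification: per-lot minimum qualifying pool mean.

    Within each reagent lot, a pool qualifies when its within-laboratory
    CV (repeatability plus between-day, estimated on the pool's day-nested
    results) is below ``cv_threshold``; the lot's LoQ is the minimum
    qualifying pool mean and the overall LoQ is the maximum over lots.
    Returns ``(overall_loq, per_lot_loq)``.
    """
    df = _ok_frame(low_panels)
    per_lot: dict[str, float] = {}
    for lot, lot_df in df.groupby("lot", sort=True):
        candidates = []
        for pool, sub in lot_df.groupby("pool_id", sort=True):
            if sub["day"].nunique() < 2:
                raise ValueError(
                    f"pool {pool}, lot {lot}: need >= 2 days for within-lab CV")
            cv = within_laboratory_cv(sub)
            if cv < cv_threshold:
                candidates.append(float(sub["value"].mean()))
        if not candidates:
            raise ValueError(
                f"lot {lot}: no pool below {cv_threshold}% within-laboratory CV")
        per_lot[str(lot)] = min(candidates)
    return max(per_lot.values()), per_lot


def estimate_detection_limits(
    blanks, low_panels, analyte: str,
    alpha: float = 0.05, beta: float = 0.05,
    cv_threshold: float = 20.0, lob_method: str = "auto",
    lol: float | None = None,
) -> DetectionLimits:
    """Full LoB -> LoD -> LoQ chain for one analyte.

    The ordering LoB <= LoD <= LoQ is asserted after estimation; a
    violation is flagged in ``notes`` (``consistent=False``), never
    silently reordered.
    """
    lob, lob_used = estimate_lob(blanks, alpha, lob_method)
    lod, lod_used = estimate_lod(low_panels, lob, alpha, beta)
    loq, per_lot = estimate_loq(low_panels, cv_threshold)
    notes = []
    consistent = True
    if not lob <= lod + 1e-12:
        consistent = False
        notes.append(f"inconsistent: LoB {lob:.4g} > LoD {lod:.4g}")
    if not lod <= loq + 1e-12:
        consistent = False
        notes.append(f"inconsistent: LoD {lod:.4g} > LoQ {loq:.4g}")
    return DetectionLimits(
        analyte=analyte, lob=lob, lod=lod, loq=loq, lol=lol,
        lob_method=lob_used, lod_method=lod_used, per_lot_loq=per_lot,
        consistent=consistent, notes=tuple(notes))


def _values(data) -> np.ndarray:
    if isinstance(data, (list, tuple, np.ndarray)) and (
            len(data) == 0 or not hasattr(data[0], "pool_id")):
        return np.asarray(data, dtype=float)
    df = _ok_frame(data)
    return df["value"].to_numpy(dtype=float)


def _ok_frame(data):
    df = as_frame(data)
    return df[df["status"] == "ok"]
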