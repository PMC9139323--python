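"""Nested variance components expressed as CV%.

Precision of a quantitative assay is decomposed with a balanced nested
random-effects ANOVA, estimated by the method of moments (the canonical
mean-squares approach for precision evaluation): repeatability is the
residual variance, and each higher stratum's variance is the scaled
difference of adjacent mean squares.  Negative difference estimates are
truncated to zero at the variance scale — a between-day CV of exactly 0.0
in a report means the day mean square fell below the run mean square, not
that days were identical.

Two designs are supported:

* single-site: day > run(day) > replicate, giving repeatability,
  between-run, between-day and within-laboratory CV%;
* multi-site: site > day(site) > replicate (one run per day), giving
  repeatability, between-day, within-laboratory and reproducibility CV%.

Within-laboratory CV is the root sum of squares of the within-site
components; reproducibility adds the between-site component the same way.
Aggregation always uses unrounded components; rounding happens only when
a report is rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StudyDesign, as_frame

__all__ = [
    "PrecisionEstimate",
    "nested_components",
    "estimate_components",
    "aggregate_cv",
    "within_laboratory_cv",
]


@dataclass(frozen=True)
class PrecisionEstimate:
    """Variance components of one pool, as CV% of the pool grand mean."""

    pool_id: str
    grand_mean: float
    cv_repeatability: float
    cv_between_run: float | None
    cv_between_day: float
    cv_between_site: float | None
    cv_within_laboratory: float
    cv_reproducibility: float | None
    n_used: int


def nested_components(
    df: pd.DataFrame, factors: list[str], value_col: str = "value"
) -> tuple[dict[str, float], float, int]:
    """Method-of-moments variance components for a nested design.

    ``factors`` lists the nesting order from the top down (e.g.
    ``["day", "run"]`` for day > run(day) > replicate).  Returns
    ``(variances, grand_mean, n)`` where ``variances`` maps each factor
    plus ``"error"`` to its (pre-truncation) variance estimate; negative
    estimates are truncated to 0.  Exact for balanced data; near-balanced
    data uses average subgroup counts in the expected-mean-square
    coefficients.
    """
    y = df[value_col].to_numpy(dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("no data")
    grand = float(y.mean())

    for f in factors:
        if df[f].nunique() < 2 and factors.index(f) == 0:
            raise ValueError(f"factor {f!r} has a single level; nested design needs >= 2")

    # mean squares per stratum, top down
    ms: list[float] = []
    m_per_group: list[float] = []
    for depth in range(1, len(factors) + 1):
        keys = factors[:depth]
        groups = df.groupby(keys, sort=False)[value_col]
        means = groups.mean()
        sizes = groups.size()
        if depth == 1:
            parent_mean = pd.Series(grand, index=means.index)
            df_num = len(means) - 1
        else:
            parent = df.groupby(factors[: depth - 1], sort=False)[value_col].mean()
            idx = means.index.to_frame(index=False)
            pk = factors[: depth - 1]
            parent_keys = idx[pk[0]] if len(pk) == 1 else list(map(tuple, idx[pk].to_numpy()))
            parent_mean = pd.Series(parent.loc[parent_keys].to_numpy(), index=means.index)
            df_num = len(means) - len(parent)
        if df_num < 1:
            raise ValueError(f"factor {keys[-1]!r} has a single level per parent group")
        ss = float((sizes * (means - parent_mean) ** 2).sum())
        ms.append(ss / df_num)
        m_per_group.append(n / len(means))

    cell = df.groupby(factors, sort=False)[value_col]
    ss_err = float(((y - cell.transform("mean").to_numpy()) ** 2).sum())
    df_err = n - cell.ngroups
    ms_error = ss_err / df_err if df_err > 0 else 0.0

    variances: dict[str, float] = {"error": max(ms_error, 0.0)}
    ms_below = ms[1:] + [ms_error]
    for f, ms_f, ms_next, m in zip(factors, ms, ms_below, m_per_group):
        variances[f] = max((ms_f - ms_next) / m, 0.0)
    return variances, grand, n


def estimate_components(data, design: StudyDesign) -> list[PrecisionEstimate]:
    """Per-pool CV% components under the declared precision design."""
    df = as_frame(data)
    df = df[df["status"] == "ok"]
    if df.empty:
        raise ValueError("no data")
    single = design.study_kind == "precision_single"
    if not single and design.study_kind != "precision_multi":
        raise ValueError(f"not a precision design: {design.study_kind!r}")
    factors = ["day", "run"] if single else ["site", "day"]
    out: list[PrecisionEstimate] = []
    for pool, sub in df.groupby("pool_id", sort=True):
        var, grand, n = nested_components(sub, factors)
        cv = {k: 100.0 * math.sqrt(v) / grand for k, v in var.items()}
        if single:
            within = aggregate_cv([cv["error"], cv["run"], cv["day"]])
            out.append(PrecisionEstimate(
                pool_id=str(pool), grand_mean=grand,
                cv_repeatability=cv["error"], cv_between_run=cv["run"],
                cv_between_day=cv["day"], cv_between_site=None,
                cv_within_laboratory=within, cv_reproducibility=None,
                n_used=n))
        else:
            within = aggregate_cv([cv["error"], cv["day"]])
            repro = aggregate_cv([within, cv["site"]])
            out.append(PrecisionEstimate(
                pool_id=str(pool), grand_mean=grand,
                cv_repeatability=cv["error"], cv_between_run=None,
                cv_between_day=cv["day"], cv_between_site=cv["site"],
                cv_within_laboratory=within, cv_reproducibility=repro,
                n_used=n))
    return out


def aggregate_cv(components) -> float:
    """Root sum of squares of CV% components over a common mean."""
    comps = [float(c) for c in components]
    if any(c < 0 for c in comps):
        raise ValueError("CV components must be >= 0")
    return math.sqrt(sum(c * c for c in comps))


def within_laboratory_cv(df: pd.DataFrame, value_col: str = "value") -> float:
    """Within-laboratory CV% from a day-nested table (day > replicate).

    Used by the quantification-limit rule, where each pool x lot block is
    measured on several days and the qualifying precision is the
    combination of repeatability and between-day variance.
    """
    var, grand, _ = nested_components(df, ["day"], value_col)
    cv_rep = 100.0 * math.sqrt(var["error"]) / grand
    cv_day = 100.0 * math.sqrt(var["day"]) / grand
    return aggregate_cv([cv_rep, cv_day])
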