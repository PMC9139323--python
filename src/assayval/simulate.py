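"""Synthetic measurement tables with the variance structure each study assumes.

The generators reproduce the validation study designs: a 20-day x 2-run x
3-replicate single-site precision grid (480 results over 4 pools), a
3-site x 5-day x 6-replicate reproducibility grid, 11-level linear
intermixture series, 45-replicate blank/low-level detection panels spread
over 3 reagent lots and 3 days, serum (days 0-8) and on-board NMR
(days 0,1,4,7,9,10) stability courses, and 10+10-aliquot interference
screens with 5-level dose-response follow-up.

Noise is multiplicative Gaussian on the CV scale throughout: a value is
``truth * (1 + sum of relative effects)`` where each hierarchical effect is
a zero-mean Gaussian with standard deviation CV/100.  This maps the CV%
components the precision estimators report directly onto generator
parameters.  Values are truncated at zero after noise (concentrations are
nonnegative); truncation events are counted and warned about.

A single global seed feeds a per-study stream splitter
(:func:`substream`), so each simulated study is independently
reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .core import Measurement, StudyDesign

__all__ = [
    "VarianceSpec",
    "SurrogateScoreParams",
    "substream",
    "simulate_precision_study",
    "simulate_linearity_series",
    "simulate_detection_panels",
    "simulate_stability_course",
    "simulate_interference_pair",
    "surrogate_score",
    "SERUM_STABILITY_TIMEPOINTS",
    "ONBOARD_STABILITY_TIMEPOINTS",
]

#: default stability sampling grids: serum at 2-10 °C, NMR tubes on board at 6 °C
SERUM_STABILITY_TIMEPOINTS = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
ONBOARD_STABILITY_TIMEPOINTS = (0.0, 1.0, 4.0, 7.0, 9.0, 10.0)


@dataclass(frozen=True)
class VarianceSpec:
    """CV% of each hierarchical precision component."""

    cv_repeatability: float = 0.0
    cv_between_run: float = 0.0
    cv_between_day: float = 0.0
    cv_between_site: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.cv_repeatability, self.cv_between_run,
                  self.cv_between_day, self.cv_between_site):
            if not np.isfinite(f) or f < 0:
                raise ValueError("CV components must be finite and >= 0")


def substream(seed: int, label: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream for one study."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


def _truncate(values: np.ndarray, label: str) -> np.ndarray:
    n_neg = int((values < 0).sum())
    if n_neg:
        warnings.warn(f"{label}: truncated {n_neg} negative simulated value(s) at 0",
                      stacklevel=3)
    return np.maximum(values, 0.0)


def simulate_precision_study(
    design: StudyDesign,
    true_mean: float,
    spec: VarianceSpec,
    seed: int,
    *,
    pool_id: str = "P1",
    analyte: str = "gfr_score",
) -> list[Measurement]:
    """Simulate one pool of a nested precision study.

    For the single-site design (``precision_single``) the hierarchy is
    day > run(day) > replicate; for the multi-site design
    (``precision_multi``) it is site > day(site) > replicate with no run
    factor.  Effects are shared within their stratum, so the nested ANOVA
    estimators can recover the generating CVs.
    """
    if true_mean <= 0:
        raise ValueError("true_mean must be > 0")
    rng = substream(seed, f"precision:{pool_id}:{analyte}")
    counts = design.expected_counts
    out: list[Measurement] = []
    if design.study_kind == "precision_single":
        n_day, n_run, n_rep = counts["day"], counts["run"], counts["replicate"]
        d_eff = rng.normal(0.0, spec.cv_between_day / 100.0, n_day)
        r_eff = rng.normal(0.0, spec.cv_between_run / 100.0, (n_day, n_run))
        e_eff = rng.normal(0.0, spec.cv_repeatability / 100.0, (n_day, n_run, n_rep))
        rel = d_eff[:, None, None] + r_eff[:, :, None] + e_eff
        values = _truncate(true_mean * (1.0 + rel), "precision")
        for d in range(n_day):
            for r in range(n_run):
                for k in range(n_rep):
                    out.append(Measurement(pool_id, analyte, float(values[d, r, k]),
                                           day=d + 1, run=r + 1, replicate=k + 1))
    elif design.study_kind == "precision_multi":
        n_site, n_day, n_rep = counts["site"], counts["day"], counts["replicate"]
        s_eff = rng.normal(0.0, spec.cv_between_site / 100.0, n_site)
        d_eff = rng.normal(0.0, spec.cv_between_day / 100.0, (n_site, n_day))
        e_eff = rng.normal(0.0, spec.cv_repeatability / 100.0, (n_site, n_day, n_rep))
        rel = s_eff[:, None, None] + d_eff[:, :, None] + e_eff
        values = _truncate(true_mean * (1.0 + rel), "precision")
        for s in range(n_site):
            for d in range(n_day):
                for k in range(n_rep):
                    out.append(Measurement(pool_id, analyte, float(values[s, d, k]),
                                           site=f"S{s + 1}", day=d + 1, run=1,
                                           replicate=k + 1))
    else:
        raise ValueError(f"not a precision design: {design.study_kind!r}")
    return out


def simulate_linearity_series(
    low: float,
    high: float,
    n_levels: int = 11,
    reps: int = 3,
    curvature: float = 0.0,
    cv: float = 0.0,
    seed: int = 0,
    *,
    pool_id: str = "LIN",
    analyte: str = "creatinine",
) -> list[Measurement]:
    """Equidistant intermixture series between a low and a high fraction.

    Assigned concentration at level ``i`` is ``low + i*(high-low)/(n_levels-1)``;
    the measured value adds a quadratic departure
    ``curvature * (assigned - midpoint)**2`` and multiplicative noise at
    ``cv`` %.  The assigned concentration is recoverable from the level
    index; analyses regress measured value on it.
    """
    if not high > low >= 0:
        raise ValueError("need high > low >= 0")
    if n_levels < 5:
        raise ValueError("linearity needs at least 5 levels")
    rng = substream(seed, f"linearity:{pool_id}:{analyte}")
    mid = (low + high) / 2.0
    out: list[Measurement] = []
    for i in range(n_levels):
        assigned = low + i * (high - low) / (n_levels - 1)
        truth = assigned + curvature * (assigned - mid) ** 2
        noise = rng.normal(0.0, cv / 100.0, reps)
        vals = _truncate(truth * (1.0 + noise), "linearity")
        for k in range(reps):
            out.append(Measurement(pool_id, analyte, float(vals[k]),
                                   level=i, replicate=k + 1))
    return out


def assigned_concentration(low: float, high: float, n_levels: int, level: int) -> float:
    """Assigned concentration of an intermixture level."""
    return low + level * (high - low) / (n_levels - 1)


def simulate_detection_panels(
    n_blank_pools: int = 4,
    n_low_pools: int = 4,
    reps_per_pool: int = 45,
    lots: int = 3,
    blank_mean: float = 10.0,
    blank_sd: float = 3.0,
    low_means: tuple[float, ...] | list[float] = (20.0, 25.0, 30.0, 40.0),
    low_cv: float = 10.0,
    seed: int = 0,
    *,
    days: int = 3,
    analyte: str = "creatinine",
) -> list[Measurement]:
    """Blank and low-level panels for LoB/LoD/LoQ estimation.

    Defaults mirror the detection study design: 4 dialyzed-serum blank
    pools and 4 low-level intermixture pools, 45 replicates each, spread
    over 3 days using 3 reagent lots.  Blanks are Gaussian around
    ``blank_mean`` truncated at 0; low pools carry multiplicative noise at
    ``low_cv`` % around their target means.
    """
    if n_low_pools and not low_means:
        raise ValueError("low_means required when low-level panels are requested")
    if reps_per_pool % (lots * days):
        raise ValueError("reps_per_pool must divide evenly over lots x days "
                         "for balanced panels")
    rng = substream(seed, f"detection:{analyte}")
    per_cell = reps_per_pool // (lots * days)
    out: list[Measurement] = []

    def cells():
        for lot in range(lots):
            for day in range(days):
                for k in range(per_cell):
                    yield lot, day, k

    for p in range(n_blank_pools):
        vals = _truncate(rng.normal(blank_mean, blank_sd, reps_per_pool), "blanks")
        for v, (lot, day, k) in zip(vals, cells()):
            out.append(Measurement(f"BLK{p + 1}", analyte, float(v),
                                   day=day + 1, replicate=k + 1,
                                   lot=f"L{lot + 1}", arm=None))
    for p in range(n_low_pools):
        mean = float(low_means[p % len(low_means)])
        vals = _truncate(mean * (1.0 + rng.normal(0, low_cv / 100.0, reps_per_pool)),
                         "low panels")
        for v, (lot, day, k) in zip(vals, cells()):
            out.append(Measurement(f"LOW{p + 1}", analyte, float(v),
                                   day=day + 1, replicate=k + 1,
                                   lot=f"L{lot + 1}"))
    return out


def simulate_stability_course(
    baseline: float,
    drift_per_day: float,
    timepoints=SERUM_STABILITY_TIMEPOINTS,
    reps: int = 3,
    cv: float = 0.0,
    missing_prob: float = 0.0,
    seed: int = 0,
    *,
    pool_id: str = "D1",
    analyte: str = "gfr_score",
    baseline_reps: int = 5,
) -> list[Measurement]:
    """One donor's storage time course.

    Truth is the line ``baseline + drift_per_day * t`` with multiplicative
    noise at ``cv`` %.  The baseline (t=0) uses ``baseline_reps`` replicate
    samples, later time points ``reps`` each, matching the study layout.
    Each result independently becomes ``no_result`` with ``missing_prob``.
    """
    if 0.0 not in [float(t) for t in timepoints]:
        raise ValueError("timepoints must include 0 (baseline)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0.0 <= missing_prob <= 1.0:
        raise ValueError("missing_prob must lie in [0, 1]")
    rng = substream(seed, f"stability:{pool_id}:{analyte}")
    out: list[Measurement] = []
    for t in sorted(float(x) for x in timepoints):
        n = baseline_reps if t == 0.0 else reps
        truth = baseline + drift_per_day * t
        vals = _truncate(truth * (1.0 + rng.normal(0, cv / 100.0, n)), "stability")
        lost = rng.random(n) < missing_prob
        for k in range(n):
            if lost[k]:
                out.append(Measurement(pool_id, analyte, None, status="no_result",
                                       timepoint_days=t, replicate=k + 1))
            else:
                out.append(Measurement(pool_id, analyte, float(vals[k]),
                                       timepoint_days=t, replicate=k + 1))
    return out


def simulate_interference_pair(
    control_mean: float,
    bias_percent: float,
    n_per_arm: int = 10,
    cv: float = 3.0,
    no_result_prob: float = 0.0,
    seed: int = 0,
    *,
    pool_id: str = "HIGH",
    analyte: str = "gfr_score",
) -> list[Measurement]:
    """Spiked (test) and unspiked (control) aliquots of one serum pool.

    The screen design uses 10 aliquots per arm.  The test arm's mean is
    shifted by ``bias_percent`` of the control mean and its results are
    lost with ``no_result_prob`` (spiking can abolish the readout
    entirely, which the screen must treat as interference).
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    if n_per_arm < 2:
        raise ValueError("need at least 2 aliquots per arm")
    rng = substream(seed, f"interference:{pool_id}:{analyte}")
    out: list[Measurement] = []
    ctl = _truncate(control_mean * (1.0 + rng.normal(0, cv / 100.0, n_per_arm)),
                    "interference control")
    tst_mean = control_mean * (1.0 + bias_percent / 100.0)
    tst = _truncate(tst_mean * (1.0 + rng.normal(0, cv / 100.0, n_per_arm)),
                    "interference test")
    lost = rng.random(n_per_arm) < no_result_prob
    for k in range(n_per_arm):
        out.append(Measurement(pool_id, analyte, float(ctl[k]),
                               arm="control", replicate=k + 1))
    for k in range(n_per_arm):
        if lost[k]:
            out.append(Measurement(pool_id, analyte, None, status="no_result",
                                   arm="test", replicate=k + 1))
        else:
            out.append(Measurement(pool_id, analyte, float(tst[k]),
                                   arm="test", replicate=k + 1))
    return out


@dataclass(frozen=True)
class SurrogateScoreParams:
    """Parameters of the surrogate GFR score.

    The marketed score combines serum myo-inositol, valine and creatinine
    with cystatin C, age and sex through a proprietary equation; this
    package carries a documented power-law stand-in so the pipeline can be
    exercised end to end.  ``coefficients`` maps marker name -> exponent;
    negative exponents make the score strictly decreasing in that marker.
    """

    coefficients: dict[str, float] = field(default_factory=lambda: {
        "creatinine": -0.65,
        "myo_inositol": -0.3,
        "valine": -0.05,
        "cystatin_c": -0.4,
    })
    reference: dict[str, float] = field(default_factory=lambda: {
        "creatinine": 80.0,      # µmol/L
        "myo_inositol": 25.0,    # µmol/L
        "valine": 250.0,         # µmol/L
        "cystatin_c": 0.9,       # mg/L
    })
    scale: float = 90.0          # mL/min/1.73 m² at reference inputs, age 40, female
    age_exponent: float = -0.25
    sex_factor: float = 1.05     # multiplicative factor for male


def surrogate_score(
    markers: dict[str, float],
    age: float,
    sex: str,
    params: SurrogateScoreParams | None = None,
) -> float:
    """Deterministic surrogate GFR score (mL/min/1.73 m²).

    Closed form::

        score = scale * prod_m (markers[m] / reference[m]) ** coefficients[m]
                      * (age / 40) ** age_exponent
                      * (sex_factor if sex == "male" else 1)

    Strictly monotone in every marker whose exponent is nonzero (default:
    decreasing in creatinine, myo-inositol, valine and cystatin C).
    """
    p = params or SurrogateScoreParams()
    missing = sorted(set(p.coefficients) - set(markers))
    if missing:
        raise ValueError(f"missing marker(s): {', '.join(missing)}")
    for name in p.coefficients:
        if markers[name] <= 0:
            raise ValueError(f"marker {name!r} must be > 0")
    if age <= 0:
        raise ValueError("age must be > 0")
    score = p.scale
    for name, expo in p.coefficients.items():
        score *= (markers[name] / p.reference[name]) ** expo
    score *= (age / 40.0) ** p.age_exponent
    if sex == "male":
        score *= p.sex_factor
    elif sex != "female":
        raise ValueError("sex must be 'male' or 'female'")
    return float(score)
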