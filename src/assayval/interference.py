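"""Two-stage interference evaluation: worst-case screen, then dose-response.

Stage 1 (screen): each candidate substance is spiked at its worst-case
concentration into serum pools with higher and lower scores, ten aliquots
per arm.  The mean relative bias is

    (mean_test - mean_control) / mean_control * 100

over the ok results; a substance is *flagged* when |bias| > 10% (the
flag is two-sided — positive biases interfere too) or when the test
arm loses more than the 10% missing-data allowance (spiking can abolish
the readout entirely, reported as bias-absent interference).

Stage 2 (dose-response): flagged substances are re-tested on independent
serum pools at spike fractions 0, 0.25, 0.5, 0.75 and 1.0 of the
worst-case concentration.  Interference is *confirmed* when some
non-zero level trips the same |bias| > 10% or result-loss rule; the
reported threshold is the lowest tripping fraction, also rendered in
prose as "greater than" the last non-tripping level's concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import as_frame

__all__ = ["InterferenceResult", "screen_interference", "dose_response",
           "BIAS_THRESHOLD", "MISSING_ALLOWANCE"]

BIAS_THRESHOLD = 10.0       # percent, two-sided
MISSING_ALLOWANCE = 0.10    # no-result fraction above which result loss interferes
DOSE_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class InterferenceResult:
    substance: str
    pool: str                                  # "high" | "low"
    mean_relative_bias: float | None           # percent; None when no results
    no_result_fraction_test: float
    flagged: bool
    confirmed: bool | None = None
    threshold_fraction: float | None = None
    threshold_concentration: float | None = None
    threshold_unit: str | None = None
    per_level_bias: dict[float, float | None] | None = None
    reasons: tuple[str, ...] = ()


def _arm_stats(data) -> tuple[np.ndarray, float]:
    df = as_frame(data)
    ok = df.loc[df["status"] == "ok", "value"].to_numpy(dtype=float)
    missing = float((df["status"] == "no_result").mean()) if len(df) else 1.0
    return ok, missing


def screen_interference(test, control, substance: str, pool: str
                        ) -> InterferenceResult:
    """Worst-case screen of one substance in one serum pool."""
    test_ok, test_missing = _arm_stats(test)
    ctl_ok, _ = _arm_stats(control)
    if len(ctl_ok) < 2:
        raise ValueError("invalid control: fewer than 2 ok results")
    reasons: list[str] = []
    if len(test_ok) == 0:
        # total result loss: interference by missing results
        return InterferenceResult(
            substance=substance, pool=pool, mean_relative_bias=None,
            no_result_fraction_test=1.0, flagged=True,
            reasons=("test arm produced no results",))
    if len(test_ok) < 2:
        raise ValueError("need >= 2 ok results in the test arm (or none at all)")
    bias = float((test_ok.mean() - ctl_ok.mean()) / ctl_ok.mean() * 100.0)
    if abs(bias) > BIAS_THRESHOLD:
        reasons.append(f"mean relative bias {bias:+.2f}% exceeds "
                       f"+-{BIAS_THRESHOLD:.0f}%")
    if test_missing > MISSING_ALLOWANCE:
        reasons.append(f"test arm lost {test_missing:.0%} of results "
                       f"(> {MISSING_ALLOWANCE:.0%} allowance)")
    return InterferenceResult(
        substance=substance, pool=pool, mean_relative_bias=bias,
        no_result_fraction_test=test_missing, flagged=bool(reasons),
        reasons=tuple(reasons))


def dose_response(levels: dict[float, object], substance: str, pool: str,
                  spike_concentration: float | None = None,
                  unit: str | None = None) -> InterferenceResult:
    """Five-level dose-response follow-up on an independent serum pool.

    ``levels`` maps spike fraction (0, 0.25, 0.5, 0.75, 1.0) to that
    fraction's measurements; level 0 is the unspiked control.
    ``spike_concentration`` is the substance's 100% (worst-case) spike
    concentration, used to convert the tripping fraction into a
    concentration.
    """
    if 0.0 not in levels:
        raise ValueError("dose-response requires the unspiked level 0")
    if len(levels) < 3:
        raise ValueError("dose-response needs at least 3 levels")
    ctl_ok, _ = _arm_stats(levels[0.0])
    if len(ctl_ok) < 2:
        raise ValueError("level 0 (control) needs >= 2 ok results")
    ctl_mean = ctl_ok.mean()

    per_level: dict[float, float | None] = {0.0: 0.0}
    tripping: list[tuple[float, str]] = []
    for frac in sorted(f for f in levels if f > 0):
        ok, missing = _arm_stats(levels[frac])
        if len(ok) == 0:
            per_level[frac] = None
            tripping.append((frac, "all results missing"))
            continue
        bias = float((ok.mean() - ctl_mean) / ctl_mean * 100.0)
        per_level[frac] = bias
        if abs(bias) > BIAS_THRESHOLD:
            tripping.append((frac, f"bias {bias:+.2f}%"))
        elif missing > MISSING_ALLOWANCE:
            tripping.append((frac, f"missing fraction {missing:.0%}"))

    confirmed = bool(tripping)
    threshold_fraction = tripping[0][0] if confirmed else None
    threshold_conc = (threshold_fraction * spike_concentration
                      if confirmed and spike_concentration is not None else None)
    reasons = tuple(f"level {f:g}: {why}" for f, why in tripping)
    no_result_levels = [f for f, b in per_level.items() if b is None]
    return InterferenceResult(
        substance=substance, pool=pool,
        mean_relative_bias=per_level.get(1.0),
        no_result_fraction_test=1.0 if no_result_levels else 0.0,
        flagged=confirmed, confirmed=confirmed,
        threshold_fraction=threshold_fraction,
        threshold_concentration=threshold_conc,
        threshold_unit=unit, per_level_bias=per_level, reasons=reasons)


def threshold_prose(result: InterferenceResult,
                    spike_concentration: float, unit: str,
                    fractions=DOSE_FRACTIONS) -> str | None:
    """Prose threshold: "> <last non-tripping concentration> <unit>".

    A screen threshold at fraction f is reported as greater than the
    previous tested level's concentration, matching how dose-response
    outcomes are usually phrased.
    """
    if not result.confirmed or result.threshold_fraction is None:
        return None
    fracs = sorted(fractions)
    idx = fracs.index(result.threshold_fraction)
    below = fracs[idx - 1] if idx > 0 else 0.0
    return f"> {below * spike_concentration:g} {unit}"
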