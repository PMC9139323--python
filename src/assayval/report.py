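"""Study orchestration from declarative configs, and report rendering.

A study config (YAML) names a ``study_kind``, either an ``input`` CSV of
measurements or a ``simulate`` block, the design factors, and optional
acceptance thresholds.  :func:`run_study` executes the design check and
the stage's statistics and returns a :class:`ValidationReport`;
:func:`render_tables` lays the report out like the four standard report
tables (detection/trueness summary, precision CV table, stability table,
interference screen table).

All randomness enters through the config seed; rounding happens only at
render time (CV% to 1 decimal, slopes and biases to 2), stored values
stay full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, detection, interference, linearity, simulate, stability
from .core import StudyDesign, as_frame, check_design, read_measurements, to_frame
from .precision import estimate_components

__all__ = ["ValidationReport", "Verdict", "run_study", "render_tables"]


@dataclass(frozen=True)
class Verdict:
    code: str            # machine-readable reason code
    pass_flag: bool
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    study_kind: str
    rows: pd.DataFrame
    verdicts: tuple[Verdict, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def pass_flag(self) -> bool:
        return all(v.pass_flag for v in self.verdicts)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _provenance(cfg: dict) -> dict:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {"config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": cfg.get("seed")}


def run_study(config) -> ValidationReport:
    """Execute one validation study from a config file path or dict."""
    cfg = _load_config(config)
    kind = cfg.get("study_kind")
    runners = {
        "precision_single": _run_precision,
        "precision_multi": _run_precision,
        "detection": _run_detection,
        "linearity": _run_linearity,
        "trueness": _run_trueness,
        "stability": _run_stability,
        "interference_screen": _run_interference_screen,
        "interference_dose_response": _run_dose_response,
    }
    if kind not in runners:
        raise ValueError(f"unknown study_kind {kind!r}")
    return runners[kind](cfg)


# ---------------------------------------------------------------- precision

def _simulate_precision(cfg: dict, design: StudyDesign) -> pd.DataFrame:
    sim = cfg["simulate"]
    seed = int(cfg.get("seed", 0))
    rows = []
    for pool in sim["pools"]:
        spec = simulate.VarianceSpec(
            cv_repeatability=pool.get("cv_repeatability", 0.0),
            cv_between_run=pool.get("cv_between_run", 0.0),
            cv_between_day=pool.get("cv_between_day", 0.0),
            cv_between_site=pool.get("cv_between_site", 0.0))
        rows += simulate.simulate_precision_study(
            design, pool["true_mean"], spec, seed, pool_id=pool["pool_id"],
            analyte=pool.get("analyte", "gfr_score"))
    return to_frame(rows)


def _run_precision(cfg: dict) -> ValidationReport:
    kind = cfg["study_kind"]
    default_design = ({"day": 20, "run": 2, "replicate": 3}
                      if kind == "precision_single"
                      else {"site": 3, "day": 5, "replicate": 6})
    design = StudyDesign(kind, cfg.get("design", default_design),
                         cfg.get("max_missing_fraction", 0.10))
    if "simulate" in cfg:
        df = _simulate_precision(cfg, design)
    else:
        df = as_frame(read_measurements(cfg["input"], design))
    verdicts = [_design_verdict(df, design)]
    estimates = estimate_components(df, design)
    rows = pd.DataFrame([{
        "pool": e.pool_id, "n": e.n_used, "mean": e.grand_mean,
        "repeatability_cv": e.cv_repeatability,
        "between_run_cv": e.cv_between_run,
        "between_day_cv": e.cv_between_day,
        "within_laboratory_cv": e.cv_within_laboratory,
        "reproducibility_cv": e.cv_reproducibility,
    } for e in estimates])
    acc = cfg.get("acceptance", {})
    if "max_repeatability_cv" in acc:
        worst = rows["repeatability_cv"].max()
        verdicts.append(Verdict(
            "repeatability_cv", worst <= acc["max_repeatability_cv"],
            f"max repeatability CV {worst:.2f}% vs allowance "
            f"{acc['max_repeatability_cv']}%"))
    if "max_reproducibility_cv" in acc and rows["reproducibility_cv"].notna().any():
        worst = rows["reproducibility_cv"].max()
        verdicts.append(Verdict(
            "reproducibility_cv", worst <= acc["max_reproducibility_cv"],
            f"max reproducibility CV {worst:.2f}% vs allowance "
            f"{acc['max_reproducibility_cv']}%"))
    return ValidationReport(kind, rows, tuple(verdicts), _provenance(cfg))


def _design_verdict(df: pd.DataFrame, design: StudyDesign) -> Verdict:
    chk = check_design(df, design)
    return Verdict("design_completeness", chk.pass_flag,
                   "; ".join(chk.reasons) or "design complete")


# ---------------------------------------------------------------- detection

def _run_detection(cfg: dict) -> ValidationReport:
    analyte = cfg.get("analyte", "creatinine")
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        panels = to_frame(simulate.simulate_detection_panels(
            seed=int(cfg.get("seed", 0)), analyte=analyte, **sim))
        blanks = panels[panels["pool_id"].str.startswith("BLK")]
        low = panels[panels["pool_id"].str.startswith("LOW")]
    else:
        blanks = as_frame(read_measurements(cfg["blanks"]))
        low = as_frame(read_measurements(cfg["low"]))
    limits = detection.estimate_detection_limits(
        blanks, low, analyte,
        alpha=cfg.get("alpha", 0.05), beta=cfg.get("beta", 0.05),
        cv_threshold=cfg.get("loq_cv_threshold", 20.0),
        lob_method=cfg.get("lob_method", "auto"),
        lol=cfg.get("lol"))
    rows = pd.DataFrame([{
        "analyte": limits.analyte, "lob": limits.lob, "lod": limits.lod,
        "loq": limits.loq, "lol": limits.lol,
        "lob_method": limits.lob_method, "lod_method": limits.lod_method,
        **{f"loq_{lot}": v for lot, v in sorted(limits.per_lot_loq.items())},
    }])
    verdicts = (Verdict("detection_limits_ordered", limits.consistent,
                        "; ".join(limits.notes) or "LoB <= LoD <= LoQ"),)
    return ValidationReport("detection", rows, verdicts, _provenance(cfg))


# ---------------------------------------------------------------- linearity

def _run_linearity(cfg: dict) -> ValidationReport:
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        low, high = sim["low"], sim["high"]
        n_levels = sim.get("n_levels", 11)
        series = to_frame(simulate.simulate_linearity_series(
            seed=int(cfg.get("seed", 0)), **sim))
        assigned = {i: simulate.assigned_concentration(low, high, n_levels, i)
                    for i in range(n_levels)}
    else:
        series = as_frame(read_measurements(cfg["input"]))
        assigned = {int(k): float(v) for k, v in cfg["assigned"].items()}
    crit = linearity.LinearityCriteria(**cfg.get("criteria", {}))
    verdict = linearity.assess_linearity(series, assigned, crit)
    rows = pd.DataFrame([{
        "pearson_r": verdict.pearson_r,
        "degree_of_nonlinearity": verdict.degree_of_nonlinearity,
        "lol": verdict.lol,
        **{f"cv_level_{k}": v for k, v in sorted(verdict.per_level_cv.items())},
    }])
    verdicts = (Verdict("linearity", verdict.pass_flag,
                        "; ".join(verdict.reasons) or "linear"),)
    return ValidationReport("linearity", rows, verdicts, _provenance(cfg))


# ---------------------------------------------------------------- trueness

def _run_trueness(cfg: dict) -> ValidationReport:
    analyte = cfg.get("analyte", "creatinine")
    if "simulate" in cfg:
        sim = cfg["simulate"]
        rng = simulate.substream(int(cfg.get("seed", 0)), f"trueness:{analyte}")
        x = rng.uniform(sim.get("x_low", 40.0), sim.get("x_high", 180.0),
                        int(sim.get("n", 50)))
        truth = sim.get("slope", 1.0) * x + sim.get("intercept", 0.0)
        y = truth * (1.0 + rng.normal(0, sim.get("cv", 3.0) / 100.0, len(x)))
    else:
        ref = as_frame(read_measurements(cfg["reference"]))
        tst = as_frame(read_measurements(cfg["test"]))
        x = ref.loc[ref["status"] == "ok", "value"].to_numpy(dtype=float)
        y = tst.loc[tst["status"] == "ok", "value"].to_numpy(dtype=float)
    fit = comparison.passing_bablok(x, y)
    verdict = comparison.assess_trueness(fit, analyte)
    rows = pd.DataFrame([{
        "analyte": analyte, "equation": fit.equation(), "slope": fit.slope,
        "intercept": fit.intercept, "pearson_r": fit.pearson_r, "n": fit.n,
        "slope_ci_low": fit.slope_ci[0], "slope_ci_high": fit.slope_ci[1],
    }])
    verdicts = (Verdict("trueness", verdict.pass_flag,
                        "; ".join(verdict.reasons) or
                        f"slope within 1.0 +- {verdict.slope_tolerance}"),)
    return ValidationReport("trueness", rows, verdicts, _provenance(cfg))


# ---------------------------------------------------------------- stability

def _run_stability(cfg: dict) -> ValidationReport:
    condition = cfg.get("condition", "serum")
    timepoints = (simulate.SERUM_STABILITY_TIMEPOINTS if condition == "serum"
                  else simulate.ONBOARD_STABILITY_TIMEPOINTS)
    horizon = float(cfg.get("horizon", max(timepoints)))
    drift_limit = float(cfg.get("drift_limit", 10.0))
    courses: list[tuple[str, pd.DataFrame]] = []
    if "simulate" in cfg:
        sim = cfg["simulate"]
        for donor in sim["donors"]:
            rows = simulate.simulate_stability_course(
                baseline=donor["baseline"],
                drift_per_day=donor.get("drift_per_day", 0.0),
                timepoints=sim.get("timepoints", timepoints),
                reps=sim.get("reps", 3), cv=sim.get("cv", 0.0),
                missing_prob=sim.get("missing_prob", 0.0),
                seed=int(cfg.get("seed", 0)), pool_id=str(donor["donor"]))
            courses.append((str(donor["donor"]), to_frame(rows)))
    else:
        df = as_frame(read_measurements(cfg["input"]))
        courses = [(str(d), sub) for d, sub in df.groupby("pool_id", sort=True)]
    out = []
    for donor, course in courses:
        fit = stability.analyze_stability_course(
            course, donor=donor, condition=condition,
            drift_limit=drift_limit, horizon=horizon)
        out.append({"donor": donor, "baseline_mean": fit.baseline_mean,
                    "slope": fit.slope, "intercept": fit.intercept,
                    "slope_p_value": fit.slope_p_value,
                    "duration_days": fit.duration_days,
                    "branch": fit.duration_branch})
    rows = pd.DataFrame(out)
    overall = float(rows["duration_days"].min())
    ok = overall >= horizon
    verdicts = (Verdict("stability_duration", ok,
                        f"overall duration {overall:g} d vs horizon {horizon:g} d"),)
    return ValidationReport("stability", rows, verdicts, _provenance(cfg))


# ------------------------------------------------------------- interference

def _run_interference_screen(cfg: dict) -> ValidationReport:
    results: list[interference.InterferenceResult] = []
    if "simulate" in cfg:
        sim = cfg["simulate"]
        seed = int(cfg.get("seed", 0))
        for i, item in enumerate(sim["substances"]):
            rows = simulate.simulate_interference_pair(
                control_mean=item["control_mean"],
                bias_percent=item.get("bias_percent", 0.0),
                n_per_arm=sim.get("n_per_arm", 10), cv=sim.get("cv", 3.0),
                no_result_prob=item.get("no_result_prob", 0.0),
                seed=seed + i, pool_id=item.get("pool", "high").upper())
            df = to_frame(rows)
            results.append(interference.screen_interference(
                df[df["arm"] == "test"], df[df["arm"] == "control"],
                item["substance"], item.get("pool", "high")))
    else:
        df = as_frame(read_measurements(cfg["input"]))
        for (substance, pool), sub in df.groupby(["analyte", "pool_id"], sort=True):
            results.append(interference.screen_interference(
                sub[sub["arm"] == "test"], sub[sub["arm"] == "control"],
                str(substance), str(pool).lower()))
    rows = pd.DataFrame([{
        "substance": r.substance, "pool": r.pool,
        "mean_relative_bias": r.mean_relative_bias,
        "no_result_fraction": r.no_result_fraction_test,
        "flagged": r.flagged, "reasons": "; ".join(r.reasons),
    } for r in results])
    flagged = sorted({r.substance for r in results if r.flagged})
    verdicts = (Verdict("interference_screen", not flagged,
                        ("dose-response follow-up required for: "
                         + ", ".join(flagged)) if flagged
                        else "no substance flagged"),)
    return ValidationReport("interference_screen", rows, tuple(verdicts),
                            {**_provenance(cfg), "dose_response_tasks": flagged})


def _run_dose_response(cfg: dict) -> ValidationReport:
    substance = cfg["substance"]
    pool = cfg.get("pool", "high")
    spike_conc = cfg.get("spike_concentration")
    unit = cfg.get("unit")
    if "simulate" in cfg:
        sim = cfg["simulate"]
        seed = int(cfg.get("seed", 0))
        levels = {}
        for j, frac in enumerate(interference.DOSE_FRACTIONS):
            rows = simulate.simulate_interference_pair(
                control_mean=sim["control_mean"],
                bias_percent=sim.get("bias_at_full", 0.0) * frac,
                n_per_arm=max(2, sim.get("n_per_level", 5)),
                cv=sim.get("cv", 3.0),
                no_result_prob=(sim.get("no_result_prob_at_full", 0.0)
                                if frac == 1.0 else 0.0),
                seed=seed + j, pool_id=pool.upper())
            df = to_frame(rows)
            levels[frac] = df[df["arm"] == "test"]
            if frac == 0.0:
                levels[frac] = df[df["arm"] == "control"]
    else:
        df = as_frame(read_measurements(cfg["input"]))
        levels = {float(interference.DOSE_FRACTIONS[int(l)]): sub
                  for l, sub in df.groupby("level", sort=True)}
    result = interference.dose_response(levels, substance, pool,
                                        spike_concentration=spike_conc, unit=unit)
    rows = pd.DataFrame([{
        "substance": result.substance, "pool": result.pool,
        "confirmed": result.confirmed,
        "threshold_fraction": result.threshold_fraction,
        "threshold_concentration": result.threshold_concentration,
        "unit": result.threshold_unit,
        **{f"bias_at_{f:g}": b for f, b in (result.per_level_bias or {}).items()},
    }])
    verdicts = (Verdict("interference_dose_response", not result.confirmed,
                        "; ".join(result.reasons) or "interference not confirmed"),)
    return ValidationReport("interference_dose_response", rows, verdicts,
                            _provenance(cfg))


# ---------------------------------------------------------------- rendering

def _fmt(v, decimals) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)) or pd.isna(v):
        return "n.a."
    # half away from zero, matching conventional report rounding
    q = 10 ** decimals
    return f"{np.sign(v) * np.floor(abs(v) * q + 0.5) / q:.{decimals}f}"


def render_tables(report: ValidationReport, layout: str) -> str:
    """Render a report in one of the four standard table layouts."""
    expected = {
        "table1": {"detection", "trueness", "linearity"},
        "table2": {"precision_single", "precision_multi"},
        "table3": {"stability"},
        "table4": {"interference_screen", "interference_dose_response"},
    }
    if layout not in expected:
        raise ValueError(f"unknown layout {layout!r}")
    if report.study_kind not in expected[layout]:
        raise ValueError(f"layout {layout} cannot render a "
                         f"{report.study_kind} report")
    if report.rows.empty:
        raise ValueError("empty report")
    rows = report.rows
    lines: list[str] = []
    if layout == "table2":
        lines.append("Pool\tMean\tRepeatability [CV%]\tBetween-Run [CV%]\t"
                     "Between-Day [CV%]\tWithin-Laboratory [CV%]\t"
                     "Reproducibility [CV%]")
        for _, r in rows.iterrows():
            lines.append("\t".join([
                str(r["pool"]), _fmt(r["mean"], 1),
                _fmt(r["repeatability_cv"], 1), _fmt(r["between_run_cv"], 1),
                _fmt(r["between_day_cv"], 1), _fmt(r["within_laboratory_cv"], 1),
                _fmt(r["reproducibility_cv"], 1)]))
    elif layout == "table3":
        lines.append("Donor\tMean at t0\tSlope\tIntercept\tSlope p-Value\t"
                     "Duration [days]")
        for _, r in rows.iterrows():
            lines.append("\t".join([
                str(r["donor"]), _fmt(r["baseline_mean"], 1),
                _fmt(r["slope"], 2), _fmt(r["intercept"], 2),
                _fmt(r["slope_p_value"], 3), _fmt(r["duration_days"], 0)]))
    elif layout == "table4":
        lines.append("Substance\tPool\tMean Relative Bias [%]")
        bias_col = ("mean_relative_bias" if "mean_relative_bias" in rows
                    else "bias_at_1")
        for _, r in rows.iterrows():
            bias = r.get(bias_col)
            txt = "No result" if bias is None or pd.isna(bias) else _fmt(bias, 2)
            lines.append(f"{r['substance']}\t{str(r['pool']).capitalize()}\t{txt}")
    else:  # table1: one summary block per analyte
        if report.study_kind == "detection":
            lines.append("Analyte\tLoB\tLoD\tLoQ\tLoL")
            for _, r in rows.iterrows():
                lines.append("\t".join([
                    str(r["analyte"]), _fmt(r["lob"], 1), _fmt(r["lod"], 1),
                    _fmt(r["loq"], 1), _fmt(r.get("lol"), 1)]))
        elif report.study_kind == "trueness":
            lines.append("Analyte\tTrueness PB; r")
            for _, r in rows.iterrows():
                lines.append(f"{r['analyte']}\t{r['equation']}; "
                             f"{_fmt(r['pearson_r'], 3)}")
        else:
            lines.append("Pearson r\tDegree of non-linearity [%]\tLoL")
            for _, r in rows.iterrows():
                lines.append("\t".join([
                    _fmt(r["pearson_r"], 3),
                    _fmt(r.get("degree_of_nonlinearity"), 1),
                    _fmt(r.get("lol"), 1)]))
    return "\n".join(lines) + "\n"
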