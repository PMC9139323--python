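"""Long-format measurement data model, CSV I/O and design-completeness checks.

Every validation stage consumes the same long-format table: one row per
individual measurement, tagged with all the design factors that stage needs
(pool, site, day, run, replicate, storage time point, dilution level,
interference arm, reagent lot).  A measurement either carries a numeric
result (``status == "ok"``) or records that the assay returned nothing
(``status == "no_result"``); lost results stay in the table because the
missing-data accounting treats them exactly like rows absent from the
design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Measurement",
    "StudyDesign",
    "DesignCheck",
    "MEASUREMENT_COLUMNS",
    "STUDY_KINDS",
    "read_measurements",
    "write_measurements",
    "to_frame",
    "from_frame",
    "check_design",
]

MEASUREMENT_COLUMNS = [
    "pool_id",
    "analyte",
    "value",
    "status",
    "site",
    "day",
    "run",
    "replicate",
    "timepoint_days",
    "level",
    "arm",
    "lot",
]

STUDY_KINDS = frozenset(
    {
        "detection",
        "linearity",
        "precision_single",
        "precision_multi",
        "trueness",
        "stability",
        "interference_screen",
        "interference_dose_response",
    }
)

_ARMS = frozenset({"test", "control", "mock", "spiked"})

#: columns each study kind cannot do without (beyond pool_id/analyte/value/status)
REQUIRED_FACTORS = {
    "detection": ("replicate", "lot"),
    "linearity": ("level", "replicate"),
    "precision_single": ("day", "run", "replicate"),
    "precision_multi": ("site", "day", "replicate"),
    "trueness": ("replicate",),
    "stability": ("timepoint_days", "replicate"),
    "interference_screen": ("arm", "replicate"),
    "interference_dose_response": ("level", "replicate"),
}


@dataclass(frozen=True)
class Measurement:
    """One observation tagged with every design factor.

    ``value`` is in µmol/L for metabolites and mL/min/1.73 m² for GFR
    scores; ``None`` encodes an absent result and is only legal together
    with ``status == "no_result"``.
    """

    pool_id: str
    analyte: str
    value: float | None
    status: str = "ok"
    site: str | None = None
    day: int | None = None
    run: int | None = None
    replicate: int = 1
    timepoint_days: float | None = None
    level: int | None = None
    arm: str | None = None
    lot: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("ok", "no_result"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "no_result":
            if self.value is not None:
                raise ValueError("status no_result requires an absent value")
        else:
            if self.value is None or not math.isfinite(self.value):
                raise ValueError("status ok requires a finite value")
            if self.value < 0:
                raise ValueError("measurement values are nonnegative")
        if self.arm is not None and self.arm not in _ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.level is not None and not 0 <= self.level <= 10:
            raise ValueError("level index must lie in 0..10")


@dataclass(frozen=True)
class StudyDesign:
    """Declares the factor structure a study expects.

    ``expected_counts`` maps factor name -> cardinality (e.g. for the
    single-site precision design ``{"day": 20, "run": 2, "replicate": 3}``).
    ``max_missing_fraction`` is the per-pool missing-data allowance
    (default 10%).
    """

    study_kind: str
    expected_counts: dict[str, int] = field(default_factory=dict)
    max_missing_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.study_kind not in STUDY_KINDS:
            raise ValueError(f"unknown study_kind {self.study_kind!r}")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")
        for name, count in self.expected_counts.items():
            if count < 1:
                raise ValueError(f"expected count for {name!r} must be >= 1")

    @property
    def expected_per_pool(self) -> int:
        """Total number of results the design expects in each pool."""
        n = 1
        for count in self.expected_counts.values():
            n *= count
        return n


@dataclass(frozen=True)
class DesignCheck:
    """Outcome of the missing-data / completeness check."""

    missing_fraction: dict[str, float]
    pass_flag: bool
    reasons: tuple[str, ...] = ()


class SchemaError(ValueError):
    """A required column is absent from an input table."""


def to_frame(data: Iterable[Measurement]) -> pd.DataFrame:
    """Convert measurements into the canonical long-format DataFrame."""
    rows = [[getattr(m, c) for c in MEASUREMENT_COLUMNS] for m in data]
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    return df


def from_frame(df: pd.DataFrame) -> list[Measurement]:
    """Build validated measurements from a canonical DataFrame."""
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in fields(Measurement):
            v = row.get(f.name)
            if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
                v = None
            elif f.name in ("day", "run", "replicate", "level"):
                v = int(v)
            elif f.name in ("value", "timepoint_days"):
                v = float(v)
            else:
                v = str(v)
            if v is None and f.name == "replicate":
                v = 1
            kwargs[f.name] = v
        out.append(Measurement(**kwargs))
    return out


def as_frame(data) -> pd.DataFrame:
    """Accept either a measurement iterable or a canonical DataFrame."""
    if isinstance(data, pd.DataFrame):
        return data
    return to_frame(data)


def read_measurements(path: str | Path, schema: StudyDesign | None = None) -> list[Measurement]:
    """Read a long-format measurement CSV.

    Empty strings encode absent fields; rows with ``status == "no_result"``
    are retained with an absent value.  When a :class:`StudyDesign` is
    given, the columns that design cannot do without must be present.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"pool_id": str, "analyte": str, "status": str,
                                  "site": str, "arm": str, "lot": str},
                     float_precision="round_trip")
    required = ["pool_id", "analyte", "value", "status"]
    if schema is not None:
        required += list(REQUIRED_FACTORS[schema.study_kind])
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path.name}")
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = None
    # non-numeric value with status ok -> parse error naming the row
    for idx, row in df.iterrows():
        if str(row["status"]) == "ok":
            try:
                float(row["value"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {idx + 2}: non-numeric value {row['value']!r} with status ok"
                ) from None
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return from_frame(df[MEASUREMENT_COLUMNS])


def write_measurements(data: Iterable[Measurement] | pd.DataFrame, path: str | Path) -> None:
    """Write measurements as UTF-8 comma-separated text, header mandatory."""
    df = as_frame(data)
    df.to_csv(path, index=False, encoding="utf-8")


def check_design(data, design: StudyDesign) -> DesignCheck:
    """Per-pool missing-data accounting against the declared design.

    "Missing" counts both rows absent relative to the expected factor
    grid and rows present with ``status == "no_result"``; the check
    passes only when every pool's missing fraction stays within the
    allowance and every declared factor reaches its expected cardinality.
    """
    df = as_frame(data)
    if df.empty:
        raise ValueError("no data")
    expected = design.expected_per_pool
    fractions: dict[str, float] = {}
    reasons: list[str] = []
    for pool, sub in df.groupby("pool_id", sort=True):
        n_ok = int((sub["status"] == "ok").sum())
        frac = max(0.0, (expected - n_ok) / expected)
        fractions[str(pool)] = frac
        if frac > design.max_missing_fraction:
            reasons.append(
                f"pool {pool}: missing fraction {frac:.3f} exceeds "
                f"allowance {design.max_missing_fraction:.2f}"
            )
        for factor, count in design.expected_counts.items():
            observed = sub[factor].dropna().nunique()
            if observed < count:
                reasons.append(
                    f"pool {pool}: factor {factor!r} has {observed} level(s), "
                    f"expected {count}"
                )
    return DesignCheck(
        missing_fraction=fractions,
        pass_flag=not reasons,
        reasons=tuple(reasons),
    )
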