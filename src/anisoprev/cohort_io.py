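"""Cohort CSV reading/writing, exclusion filters and sample characterization.

The cohort file is a plain comma-separated table, one row per participant:
``id, age, gender, residence, cycle, wears_correction`` followed by the
replicate reading columns ``re_s1, re_c1, re_a1, ..., le_s3, le_c3, le_a3``
(sphere/cylinder in diopters to two decimals, axis in integer degrees).
Malformed rows are collected in a parse report, never silently dropped.

Exclusion mirrors field practice with a tabletop autorefractometer: a
participant is removed (whole-person, not per-eye) when any replicate lies
outside the instrument's measurement range (sphere or cylinder outside
[-7.00, +5.00] D, closed interval), when an eye has no readings, or when an
eye has fewer replicates than the protocol requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .vectors import (InsufficientReplicatesError, PowerVector, SpheroCylinder,
                      mean_refraction)
from .simulate import DEMOGRAPHIC_COLUMNS, REPLICATE_COLUMNS

__all__ = [
    "ParticipantRecord",
    "ParseReport",
    "ExclusionReport",
    "MeasurementLimits",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "apply_exclusions",
    "average_frame",
    "characterize_sample",
]

log = logging.getLogger("anisoprev")

GENDERS = ("male", "female", "missing")
RESIDENCES = ("rural", "urban", "missing")
WEAR = ("yes", "no", "missing")
CYCLE_AGE_RANGES = {"preschool": (3, 6), "cycle1": (6, 10), "cycle2": (10, 12),
                    "cycle3": (12, 15)}
AGE_MIN, AGE_MAX = 3, 16


class SchemaError(ValueError):
    """The cohort CSV is missing mandatory columns."""


@dataclass
class ParticipantRecord:
    """Demographics plus replicate readings for both eyes; the unit of
    analysis."""

    id: str
    age: float
    gender: str = "missing"
    residence: str = "missing"
    cycle: str = ""
    wears_correction: str = "missing"
    re_readings: List[SpheroCylinder] = field(default_factory=list)
    le_readings: List[SpheroCylinder] = field(default_factory=list)

    def mean_eyes(self, min_count: int = 3) -> Tuple[PowerVector, PowerVector]:
        return (mean_refraction(self.re_readings, min_count),
                mean_refraction(self.le_readings, min_count))


@dataclass
class ParseReport:
    """What the reader saw: per-row errors and normalization warnings."""

    n_rows: int = 0
    errors: List[Tuple[str, str]] = field(default_factory=list)
    warnings: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def n_parsed(self) -> int:
        return self.n_rows - len(self.errors)


@dataclass
class ExclusionReport:
    """Excluded participant ids with reason codes; reconciles with the
    analyzed set (input = analyzed + excluded)."""

    out_of_range: List[str] = field(default_factory=list)
    insufficient_replicates: List[str] = field(default_factory=list)
    missing_eye: List[str] = field(default_factory=list)

    @property
    def excluded_ids(self) -> List[str]:
        return self.missing_eye + self.insufficient_replicates + self.out_of_range

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": i, "reason": reason}
                for reason, ids in (("missing_eye", self.missing_eye),
                                    ("insufficient_replicates",
                                     self.insufficient_replicates),
                                    ("out_of_range", self.out_of_range))
                for i in ids]
        return pd.DataFrame(rows, columns=["id", "reason"])


@dataclass(frozen=True)
class MeasurementLimits:
    """Closed instrument measurement range in diopters; values strictly
    outside exclude the participant."""

    sphere_min: float = -7.00
    sphere_max: float = 5.00
    cylinder_min: float = -7.00
    cylinder_max: float = 5.00


def _parse_categorical(value, allowed: Sequence[str]) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "missing"
    v = str(value).strip().lower()
    return v if v in allowed else "missing"


def _parse_eye(row: pd.Series, eye: str, pid: str, report: ParseReport
               ) -> List[SpheroCylinder]:
    readings = []
    for k in (1, 2, 3):
        s, c, a = (row.get(f"{eye}_s{k}"), row.get(f"{eye}_c{k}"),
                   row.get(f"{eye}_a{k}"))
        if pd.isna(s) and pd.isna(c) and pd.isna(a):
            continue
        s, c = float(s), float(c)
        a = 0.0 if pd.isna(a) else float(a)
        if not 0 <= a < 180:
            report.warnings.append(
                (pid, f"{eye} replicate {k}: axis {a:g} normalized to "
                      f"{a % 180:g}"))
        readings.append(SpheroCylinder(sphere=s, cylinder=c, axis=a))
    return readings


def read_cohort(path: Union[str, Path]
                ) -> Tuple[List[ParticipantRecord], ParseReport]:
    """Read a cohort CSV into typed records plus a parse report.

    Rows with non-numeric readings or an out-of-band age land in the
    report's ``errors``; axis values outside [0, 180) are normalized
    modulo 180 with a warning.  Missing demographic values become the
    explicit level ``"missing"``.
    """
    df = pd.read_csv(path, dtype={"id": str})
    mandatory = {"id", "age"} | set(REPLICATE_COLUMNS)
    missing_cols = sorted(mandatory - set(df.columns))
    if missing_cols:
        raise SchemaError(f"cohort CSV is missing columns: {missing_cols}")
    report = ParseReport(n_rows=len(df))
    records: List[ParticipantRecord] = []
    for _, row in df.iterrows():
        pid = str(row["id"])
        try:
            age = float(row["age"])
            if not AGE_MIN <= age <= AGE_MAX:
                raise ValueError(f"age {age:g} outside [{AGE_MIN}, {AGE_MAX}]")
            rec = ParticipantRecord(
                id=pid,
                age=age,
                gender=_parse_categorical(row.get("gender"), GENDERS),
                residence=_parse_categorical(row.get("residence"), RESIDENCES),
                cycle=_parse_categorical(row.get("cycle"), CYCLE_AGE_RANGES),
                wears_correction=_parse_categorical(row.get("wears_correction"),
                                                    WEAR),
                re_readings=_parse_eye(row, "re", pid, report),
                le_readings=_parse_eye(row, "le", pid, report),
            )
        except (TypeError, ValueError) as exc:
            report.errors.append((pid, str(exc)))
            continue
        lo_hi = CYCLE_AGE_RANGES.get(rec.cycle)
        if lo_hi and not (lo_hi[0] - 1 <= age <= lo_hi[1] + 1):
            report.warnings.append(
                (pid, f"age {age:g} inconsistent with cycle {rec.cycle}"))
        records.append(rec)
    log.info("read %d rows: %d parsed, %d errors, %d warnings",
             report.n_rows, report.n_parsed, len(report.errors),
             len(report.warnings))
    return records, report


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Serialize records back to the CSV-shaped wide table."""
    rows = []
    for r in records:
        row = {"id": r.id, "age": r.age, "gender": r.gender,
               "residence": r.residence, "cycle": r.cycle,
               "wears_correction": r.wears_correction}
        for eye, readings in (("re", r.re_readings), ("le", r.le_readings)):
            for k in (1, 2, 3):
                if k <= len(readings):
                    rd = readings[k - 1]
                    row[f"{eye}_s{k}"] = rd.sphere
                    row[f"{eye}_c{k}"] = rd.cylinder
                    row[f"{eye}_a{k}"] = rd.axis
                else:
                    row[f"{eye}_s{k}"] = np.nan
                    row[f"{eye}_c{k}"] = np.nan
                    row[f"{eye}_a{k}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=DEMOGRAPHIC_COLUMNS + REPLICATE_COLUMNS)


def write_cohort(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort table with the package's CSV dialect: UTF-8, header
    row, diopters to two decimals, axes as integer degrees.  Byte-stable
    for identical inputs."""
    def fmt(spec):
        def inner(v):
            if pd.isna(v):
                return ""
            try:
                return spec(v)
            except (TypeError, ValueError):
                return str(v)  # pass through; the reader will report it
        return inner

    out = frame.copy()
    for col in out.columns:
        if col.endswith(("1", "2", "3")) and ("_a" in col):
            out[col] = out[col].map(fmt(lambda v: str(int(round(float(v))))))
        elif col.endswith(("1", "2", "3")):
            out[col] = out[col].map(fmt(lambda v: f"{float(v):.2f}"))
    out.to_csv(path, index=False, lineterminator="\n")


def apply_exclusions(
    records: Sequence[ParticipantRecord],
    limits: Optional[MeasurementLimits] = None,
    min_replicates: int = 3,
) -> Tuple[List[ParticipantRecord], ExclusionReport]:
    """Participant-level exclusion filter.

    Reasons, checked in order: ``missing_eye`` (an eye with no readings),
    ``insufficient_replicates`` (an eye with fewer than ``min_replicates``),
    ``out_of_range`` (any replicate sphere or cylinder strictly outside the
    closed instrument range).
    """
    limits = limits or MeasurementLimits()
    analyzed: List[ParticipantRecord] = []
    report = ExclusionReport()
    for rec in records:
        if not rec.re_readings or not rec.le_readings:
            report.missing_eye.append(rec.id)
            continue
        if (len(rec.re_readings) < min_replicates
                or len(rec.le_readings) < min_replicates):
            report.insufficient_replicates.append(rec.id)
            continue
        out = any(
            not (limits.sphere_min <= rd.sphere <= limits.sphere_max
                 and limits.cylinder_min <= rd.cylinder <= limits.cylinder_max)
            for rd in rec.re_readings + rec.le_readings
        )
        if out:
            report.out_of_range.append(rec.id)
            continue
        analyzed.append(rec)
    log.info("exclusions: %d analyzed, %d missing_eye, %d insufficient, "
             "%d out_of_range", len(analyzed), len(report.missing_eye),
             len(report.insufficient_replicates), len(report.out_of_range))
    return analyzed, report


def average_frame(data: pd.DataFrame, min_count: int = 3) -> pd.DataFrame:
    """Vectorized replicate averaging over a CSV-shaped cohort table.

    Converts each replicate to (SE, J0, J45), means them per eye and
    returns demographics plus ``se_re, c_re, se_le, c_le`` (the cylinder
    implied by the mean vector).  Rows with missing replicates yield NaN;
    raises if fewer than ``min_count`` replicate column triplets exist.
    """
    if min_count > 3:
        raise InsufficientReplicatesError(
            f"cohort table carries 3 replicates, protocol requires {min_count}")
    keep = [c for c in DEMOGRAPHIC_COLUMNS if c in data.columns]
    out = data[keep].copy()
    for eye in ("re", "le"):
        se = np.zeros(len(data))
        j0 = np.zeros(len(data))
        j45 = np.zeros(len(data))
        for k in (1, 2, 3):
            s = data[f"{eye}_s{k}"].to_numpy(dtype=float)
            c = data[f"{eye}_c{k}"].to_numpy(dtype=float)
            a = data[f"{eye}_a{k}"].to_numpy(dtype=float)
            two_alpha = np.radians(2.0 * a)
            se += s + c / 2.0
            j0 += -(c / 2.0) * np.cos(two_alpha)
            j45 += -(c / 2.0) * np.sin(two_alpha)
        out[f"se_{eye}"] = se / 3.0
        out[f"c_{eye}"] = -2.0 * np.hypot(j0 / 3.0, j45 / 3.0)
    return out


def characterize_sample(frame: pd.DataFrame,
                        factors: Sequence[str] = ("gender", "residence",
                                                  "cycle", "wears_correction")
                        ) -> pd.DataFrame:
    """Counts and percentages by demographic factor, with explicit
    ``missing`` rows; percentages half-up to one decimal."""
    from .stats import round_half_up

    rows = []
    n = len(frame)
    for factor in factors:
        if factor not in frame.columns or n == 0:
            continue
        counts = frame[factor].fillna("missing").astype(str).value_counts()
        for level, k in counts.items():
            rows.append({"factor": factor, "level": level, "n": int(k),
                         "pct": round_half_up(100.0 * k / n, 1)})
    return pd.DataFrame(rows, columns=["factor", "level", "n", "pct"])
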