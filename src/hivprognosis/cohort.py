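"""Cohort data model, CSV I/O, eligibility screening and baseline-value assembly.

Participants enter the study at their first visit aged >=70 inside the
recruitment window; follow-up runs to death, 5 years, or the administrative
study end, whichever comes first.  Baseline covariates are resolved from
dated measurements using a +/-12-month window around entry, taking the value
closest to entry and preferring the after-entry value on exact ties.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Fixed calendar conventions used by every window and duration rule.
DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

#: Analytes carried in the long-format measurement table, with the unit each
#: must be reported in.  Albumin arrives in g/L and is converted to g/dL only
#: inside the VACS 2.0 engine.
EXPECTED_UNITS: dict[str, str] = {
    "cd4": "cells/mm3",
    "cd4_nadir": "cells/mm3",
    "hiv_rna": "copies/mL",
    "hemoglobin": "g/dL",
    "creatinine": "umol/L",
    "ast": "U/L",
    "alt": "U/L",
    "platelets": "10^3/uL",
    "wbc": "10^3/uL",
    "albumin": "g/L",
    "weight": "kg",
    "height": "m",
}

PARTICIPANT_COLUMNS = [
    "participant_id", "sex", "birth_date", "entry_date", "exit_date", "event",
    "hiv2_flag", "non_hiv_cancer", "cvd", "cirrhosis", "aids",
    "hbsag_pos", "hcv_ab_pos",
]
MEASUREMENT_COLUMNS = ["participant_id", "analyte", "date", "value", "unit"]


class CohortParseError(ValueError):
    """Raised when a cohort CSV contains malformed rows; message lists each offending line."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject's static record: identity, dates, vital status and comorbidity flags."""

    participant_id: str
    sex_at_birth: Literal["male", "female"]
    birth_date: date
    entry_date: date
    exit_date: date
    event: Literal["death", "censored"]
    hiv2: bool = False
    non_hiv_cancer: bool = False
    cvd: bool = False
    cirrhosis: bool = False
    aids: bool = False
    hbsag_pos: bool | None = None
    hcv_ab_pos: bool | None = None

    def __post_init__(self) -> None:
        if self.exit_date < self.entry_date:
            raise ValueError(
                f"participant {self.participant_id}: exit_date {self.exit_date} "
                f"precedes entry_date {self.entry_date}"
            )
        if self.event not in ("death", "censored"):
            raise ValueError(f"event must be 'death' or 'censored', got {self.event!r}")

    @property
    def age_at_entry(self) -> float:
        """Exact fractional age in years at the entry date."""
        return (self.entry_date - self.birth_date).days / DAYS_PER_YEAR


@dataclass
class MeasurementSeries:
    """All dated values of one analyte for one participant."""

    participant_id: str
    analyte: str
    entries: list[tuple[date, float, str]] = field(default_factory=list)

    def sorted_entries(self) -> list[tuple[date, float, str]]:
        return sorted(self.entries, key=lambda e: e[0])


@dataclass(frozen=True)
class ResolvedValue:
    """A baseline value resolved from a measurement series, with provenance."""

    value: float
    source_date: date
    side: Literal["before", "after", "none"]
    imputed: bool = False


@dataclass
class BaselineCovariates:
    """Per-participant values resolved at entry, plus the participant's static flags."""

    participant_id: str
    sex: Literal["male", "female"]
    age: float
    values: dict[str, ResolvedValue] = field(default_factory=dict)
    non_hiv_cancer: bool = False
    cvd: bool = False
    cirrhosis: bool = False
    aids: bool = False
    hbv: bool | None = None
    hcv: bool | None = None
    bmi: float | None = None

    def get(self, analyte: str) -> float | None:
        rv = self.values.get(analyte)
        return None if rv is None else rv.value


@dataclass(frozen=True)
class EligibilityResult:
    included: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_date(text: str, line: int, col: str, errors: list[str]) -> date | None:
    try:
        return date.fromisoformat(text.strip())
    except ValueError:
        errors.append(f"line {line}: column {col!r}: malformed date {text!r} (expected ISO-8601)")
        return None


def _parse_bool(text: str, line: int, col: str, errors: list[str]) -> bool | None:
    t = text.strip()
    if t == "":
        return None
    if t in ("0", "1"):
        return t == "1"
    errors.append(f"line {line}: column {col!r}: expected 0/1, got {text!r}")
    return None


def load_participants(path: str | Path) -> list[ParticipantRecord]:
    """Parse the participant table; raises :class:`CohortParseError` listing bad rows."""
    records: list[ParticipantRecord] = []
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(PARTICIPANT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CohortParseError(f"{path}: missing columns {sorted(missing)}")
        for line, row in enumerate(reader, start=2):
            nerr = len(errors)
            birth = _parse_date(row["birth_date"], line, "birth_date", errors)
            entry = _parse_date(row["entry_date"], line, "entry_date", errors)
            exit_ = _parse_date(row["exit_date"], line, "exit_date", errors)
            sex = row["sex"].strip().lower()
            if sex not in ("male", "female"):
                errors.append(f"line {line}: column 'sex': expected male/female, got {row['sex']!r}")
            event = row["event"].strip().lower()
            if event not in ("death", "censored"):
                errors.append(f"line {line}: column 'event': expected death/censored, got {row['event']!r}")
            flags = {
                col: _parse_bool(row[col], line, col, errors)
                for col in ("hiv2_flag", "non_hiv_cancer", "cvd", "cirrhosis", "aids")
            }
            opt = {col: _parse_bool(row[col], line, col, errors) for col in ("hbsag_pos", "hcv_ab_pos")}
            if len(errors) > nerr:
                continue
            try:
                records.append(ParticipantRecord(
                    participant_id=row["participant_id"].strip(),
                    sex_at_birth=sex,  # type: ignore[arg-type]
                    birth_date=birth,  # type: ignore[arg-type]
                    entry_date=entry,  # type: ignore[arg-type]
                    exit_date=exit_,  # type: ignore[arg-type]
                    event=event,  # type: ignore[arg-type]
                    hiv2=bool(flags["hiv2_flag"]),
                    non_hiv_cancer=bool(flags["non_hiv_cancer"]),
                    cvd=bool(flags["cvd"]),
                    cirrhosis=bool(flags["cirrhosis"]),
                    aids=bool(flags["aids"]),
                    hbsag_pos=opt["hbsag_pos"],
                    hcv_ab_pos=opt["hcv_ab_pos"],
                ))
            except ValueError as exc:
                errors.append(f"line {line}: {exc}")
    if errors:
        raise CohortParseError(f"{path}: {len(errors)} bad row(s):\n" + "\n".join(errors))
    return records


def load_measurements(path: str | Path) -> list[MeasurementSeries]:
    """Parse the long-format measurement table into per-(participant, analyte) series."""
    series: dict[tuple[str, str], MeasurementSeries] = {}
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = set(MEASUREMENT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CohortParseError(f"{path}: missing columns {sorted(missing)}")
        for line, row in enumerate(reader, start=2):
            analyte = row["analyte"].strip()
            if analyte not in EXPECTED_UNITS:
                errors.append(f"line {line}: unknown analyte {analyte!r}")
                continue
            unit = row["unit"].strip()
            if unit != EXPECTED_UNITS[analyte]:
                errors.append(
                    f"line {line}: analyte {analyte!r}: unit {unit!r}, "
                    f"expected {EXPECTED_UNITS[analyte]!r}"
                )
                continue
            d = _parse_date(row["date"], line, "date", errors)
            if d is None:
                continue
            try:
                value = float(row["value"])
            except ValueError:
                errors.append(f"line {line}: malformed value {row['value']!r}")
                continue
            if value <= 0:
                errors.append(f"line {line}: analyte {analyte!r}: nonpositive value {value}")
                continue
            key = (row["participant_id"].strip(), analyte)
            series.setdefault(key, MeasurementSeries(key[0], key[1])).entries.append((d, value, unit))
    if errors:
        raise CohortParseError(f"{path}: {len(errors)} bad row(s):\n" + "\n".join(errors))
    return list(series.values())


def load_cohort(
    participant_csv: str | Path, measurements_csv: str | Path
) -> tuple[list[ParticipantRecord], list[MeasurementSeries]]:
    """Load both cohort tables. See module docstring for the schemas."""
    return load_participants(participant_csv), load_measurements(measurements_csv)


def write_cohort(
    participants: Iterable[ParticipantRecord],
    measurements: Iterable[MeasurementSeries],
    participant_csv: str | Path,
    measurements_csv: str | Path,
) -> None:
    """Write both tables in the documented schema (inverse of :func:`load_cohort`)."""

    def b(v: bool | None) -> str:
        return "" if v is None else str(int(v))

    with open(participant_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PARTICIPANT_COLUMNS)
        for p in participants:
            w.writerow([
                p.participant_id, p.sex_at_birth, p.birth_date.isoformat(),
                p.entry_date.isoformat(), p.exit_date.isoformat(), p.event,
                b(p.hiv2), b(p.non_hiv_cancer), b(p.cvd), b(p.cirrhosis),
                b(p.aids), b(p.hbsag_pos), b(p.hcv_ab_pos),
            ])
    with open(measurements_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MEASUREMENT_COLUMNS)
        for s in measurements:
            for d, v, u in s.sorted_entries():
                w.writerow([s.participant_id, s.analyte, d.isoformat(), repr(v), u])


# ---------------------------------------------------------------------------
# Eligibility and follow-up


def screen_eligibility(
    p: ParticipantRecord,
    measurements: Sequence[MeasurementSeries],
    window_months: float = 12.0,
) -> EligibilityResult:
    """Inclusion screen: age >=70 at entry, HIV-1 only, and at least one CD4
    count within ``window_months`` before or after entry."""
    if p.age_at_entry < 70.0:
        return EligibilityResult(False, "age")
    if p.hiv2:
        return EligibilityResult(False, "hiv2")
    window = timedelta(days=window_months * DAYS_PER_MONTH)
    for s in measurements:
        if s.participant_id == p.participant_id and s.analyte == "cd4":
            if any(abs(d - p.entry_date) <= window for d, _, _ in s.entries):
                return EligibilityResult(True)
    return EligibilityResult(False, "no_cd4_in_window")


def compute_followup(
    p: ParticipantRecord, study_end: date, horizon_years: float = 5.0
) -> tuple[float, int]:
    """Follow-up time (years) and event flag, truncated at the horizon and study end.

    Deaths after the truncation point are recoded as censored at truncation.
    Same-day exits are shifted to half a day to keep downstream log terms finite.
    """
    if p.exit_date < p.entry_date:
        raise ValueError("negative follow-up duration")
    raw = (p.exit_date - p.entry_date).days / DAYS_PER_YEAR
    cap = min(horizon_years, (study_end - p.entry_date).days / DAYS_PER_YEAR)
    time = min(raw, cap)
    event = 1 if (p.event == "death" and raw <= cap) else 0
    if time <= 0:
        logger.info("participant %s: zero follow-up shifted to 0.5 day", p.participant_id)
        time = 0.5 / DAYS_PER_YEAR
    return time, event


# ---------------------------------------------------------------------------
# Windowed baseline-value selection


def select_baseline_value(
    series: MeasurementSeries | None,
    entry: date,
    window_months: float = 12.0,
    prefer_after: bool = True,
) -> ResolvedValue | None:
    """The in-window value closest to entry; exact-distance ties go to the
    after-entry value when ``prefer_after``; None when nothing is in window."""
    if series is None or not series.entries:
        return None
    window_days = window_months * DAYS_PER_MONTH
    best: tuple[float, int, date, float] | None = None
    seen_dates: set[date] = set()
    for d, v, _ in series.sorted_entries():
        dist = abs((d - entry).days)
        if dist > window_days:
            continue
        if d in seen_dates:
            warnings.warn(
                f"{series.participant_id}/{series.analyte}: duplicate measurement on {d}; "
                "keeping the last listed",
                stacklevel=2,
            )
        seen_dates.add(d)
        after = 1 if (d >= entry) == prefer_after else 0
        # sort key: nearest wins; on exact tie the preferred side wins; later
        # same-day entries overwrite earlier ones (>= in the comparison).
        if best is None or (dist, -after) <= (best[0], -best[1]):
            best = (dist, after, d, v)
    if best is None:
        return None
    _, _, d, v = best
    side: Literal["before", "after", "none"] = "after" if d >= entry else "before"
    return ResolvedValue(v, d, side)


def select_bmi_inputs(
    weight_series: MeasurementSeries | None,
    height_series: MeasurementSeries | None,
    entry: date,
    mode: Literal["windowed", "unrestricted"] = "windowed",
    window_months: float = 12.0,
) -> tuple[ResolvedValue, ResolvedValue] | None:
    """Weight and height for BMI.

    ``windowed`` applies the usual +/-12-month rule to weight; ``unrestricted``
    takes the globally closest dated weight, so stable patients weighed rarely
    are not dropped.  Height is taken as the closest available regardless of
    mode (adult height is treated as static).
    """
    if mode not in ("windowed", "unrestricted"):
        raise ValueError(f"unknown BMI mode {mode!r}")
    height = select_baseline_value(height_series, entry, window_months=1e9)
    if height is None:
        return None
    wm = window_months if mode == "windowed" else 1e9
    weight = select_baseline_value(weight_series, entry, window_months=wm)
    if weight is None:
        return None
    return weight, height


def assemble_baseline(
    p: ParticipantRecord,
    measurements: Sequence[MeasurementSeries],
    window_months: float = 12.0,
    bmi_mode: Literal["windowed", "unrestricted"] = "windowed",
    hcv_window_months_after: float = 3.0,
) -> BaselineCovariates:
    """Resolve all baseline covariates for one participant.

    Lab analytes use the +/-12-month window; weight follows ``bmi_mode``;
    the HCV-antibody flag from the participant record is kept as recorded
    (serology resolution up to 3 months after baseline is a data-collection
    rule, applied upstream when building the participant table).
    """
    by_analyte: Mapping[str, MeasurementSeries] = {
        s.analyte: s for s in measurements if s.participant_id == p.participant_id
    }
    cov = BaselineCovariates(
        participant_id=p.participant_id,
        sex=p.sex_at_birth,
        age=p.age_at_entry,
        non_hiv_cancer=p.non_hiv_cancer,
        cvd=p.cvd,
        cirrhosis=p.cirrhosis,
        aids=p.aids,
        hbv=p.hbsag_pos,
        hcv=p.hcv_ab_pos,
    )
    for analyte in ("cd4", "cd4_nadir", "hiv_rna", "hemoglobin", "creatinine",
                    "ast", "alt", "platelets", "wbc", "albumin"):
        rv = select_baseline_value(by_analyte.get(analyte), p.entry_date, window_months)
        if rv is not None:
            cov.values[analyte] = rv
    wh = select_bmi_inputs(by_analyte.get("weight"), by_analyte.get("height"),
                           p.entry_date, bmi_mode, window_months)
    if wh is not None:
        cov.values["weight"], cov.values["height"] = wh
    return cov
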