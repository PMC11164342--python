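"""Longitudinal CA-125 cohort data model, file I/O, and eligibility filtering.

A patient's record couples a serum CA-125 time series with a treatment
schedule (chemotherapy cycles grouped into lines) and clinical covariates.
Time is measured in days from each patient's first CA-125 measurement, so
day 0 always carries an observed CA-125 value — the models use it as the
initial condition C(0).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Measurement",
    "TreatmentLine",
    "TreatmentSchedule",
    "PatientRecord",
    "Cohort",
    "CohortFormatError",
    "CohortValidationError",
    "alpha",
    "read_cohort",
    "write_cohort",
    "filter_eligible",
    "PLATINUM_AGENTS",
]

#: Drug-label substrings (case-insensitive) that mark a platinum-based regimen.
PLATINUM_AGENTS = ("carboplatin", "cisplatin")


class CohortFormatError(ValueError):
    """A tabular input file does not conform to the expected dialect."""


class CohortValidationError(ValueError):
    """Input rows violate a data invariant (e.g. non-positive CA-125)."""


@dataclass(frozen=True)
class Measurement:
    """One CA-125 observation: ``day`` (days from patient origin) and ``value`` (U/mL)."""

    day: float
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.day):
            raise CohortValidationError(f"measurement day must be finite, got {self.day}")
        if not (math.isfinite(self.value) and self.value > 0):
            raise CohortValidationError(
                f"CA-125 value must be positive and finite, got {self.value}"
            )


@dataclass(frozen=True)
class TreatmentLine:
    """One line of treatment: a group of dosing cycles including intra-line gaps."""

    line_number: int
    cycle_days: tuple[float, ...]
    drug_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.line_number < 1:
            raise CohortValidationError("line_number must be a positive integer")
        if not self.cycle_days:
            raise CohortValidationError("a treatment line needs at least one cycle day")
        if any(b < a for a, b in zip(self.cycle_days, self.cycle_days[1:])):
            raise CohortValidationError("cycle_days must be non-decreasing")
        if self.drug_labels and len(self.drug_labels) != len(self.cycle_days):
            raise CohortValidationError("one drug label per cycle required")

    @property
    def start_day(self) -> float:
        return self.cycle_days[0]

    @property
    def end_day(self) -> float:
        return self.cycle_days[-1]

    @property
    def is_zero_length(self) -> bool:
        """True for single-cycle lines whose on-treatment interval has measure zero."""
        return self.end_day == self.start_day


@dataclass(frozen=True)
class TreatmentSchedule:
    """Ordered treatment lines defining the on-treatment indicator alpha(t).

    alpha(t) = 1 while the patient is inside the closed interval
    [first cycle day, last cycle day] of any line, 0 otherwise.
    """

    lines: tuple[TreatmentLine, ...] = ()

    def __post_init__(self) -> None:
        nums = [ln.line_number for ln in self.lines]
        if len(set(nums)) != len(nums):
            raise CohortValidationError("line numbers must be unique within a patient")
        ordered = sorted(self.lines, key=lambda ln: ln.start_day)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_day < a.end_day:
                raise CohortValidationError(
                    f"treatment lines {a.line_number} and {b.line_number} overlap"
                )
        object.__setattr__(self, "lines", tuple(ordered))

    @property
    def intervals(self) -> tuple[tuple[float, float], ...]:
        """On-treatment intervals, one per line, ordered by start day."""
        return tuple((ln.start_day, ln.end_day) for ln in self.lines)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def line(self, line_number: int) -> TreatmentLine:
        for ln in self.lines:
            if ln.line_number == line_number:
                return ln
        raise KeyError(f"no line {line_number}")

    def alpha(self, t: float) -> int:
        return alpha(self, t)


def alpha(schedule: TreatmentSchedule, t: float) -> int:
    """Treatment indicator: 1 iff ``t`` lies in a closed on-treatment interval."""
    for start, end in schedule.intervals:
        if start <= t <= end:
            return 1
        if t < start:
            break
    return 0


@dataclass(frozen=True)
class PatientRecord:
    """One patient's CA-125 series, treatment schedule, covariates, and outcomes.

    Day fields may be ``None`` when the event is unobserved; a patient without
    a death day must carry a last-follow-up day.
    """

    patient_id: str
    measurements: tuple[Measurement, ...]
    schedule: TreatmentSchedule
    age_at_diagnosis: float | None = None
    first_line_type: str | None = None  # "PDS" or "NACT"
    residual_disease: str | None = None  # "<=1cm", ">1cm" or None (unknown)
    platinum_first_line: bool = False
    pretreatment_ca125: float | None = None
    uln: float | None = None
    diagnosis_day: float | None = None
    progression_day: float | None = None
    death_day: float | None = None
    last_followup_day: float | None = None

    def __post_init__(self) -> None:
        days = [m.day for m in self.measurements]
        if any(b < a for a, b in zip(days, days[1:])):
            raise CohortValidationError(
                f"patient {self.patient_id}: measurements must be sorted by day"
            )
        if len(set(days)) != len(days):
            raise CohortValidationError(
                f"patient {self.patient_id}: duplicate measurement days"
            )
        if self.death_day is None and self.last_followup_day is None:
            raise CohortValidationError(
                f"patient {self.patient_id}: need death day or last follow-up day"
            )
        if (
            self.progression_day is not None
            and self.diagnosis_day is not None
            and self.progression_day < self.diagnosis_day
        ):
            raise CohortValidationError(
                f"patient {self.patient_id}: progression precedes diagnosis"
            )
        if self.first_line_type not in (None, "PDS", "NACT"):
            raise CohortValidationError(
                f"patient {self.patient_id}: first_line_type must be PDS or NACT"
            )

    @property
    def days(self) -> np.ndarray:
        return np.array([m.day for m in self.measurements], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([m.value for m in self.measurements], dtype=float)

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    @property
    def last_record_day(self) -> float:
        """Latest day with any information: measurement, cycle, or outcome."""
        candidates = [m.day for m in self.measurements]
        candidates += [ln.end_day for ln in self.schedule.lines]
        for d in (self.death_day, self.last_followup_day, self.progression_day):
            if d is not None:
                candidates.append(d)
        return max(candidates) if candidates else float("nan")


@dataclass(frozen=True)
class Cohort:
    """A mapping of patient id to :class:`PatientRecord` with unique ids."""

    patients: Mapping[str, PatientRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, rec in self.patients.items():
            if pid != rec.patient_id:
                raise CohortValidationError(f"key {pid!r} != record id {rec.patient_id!r}")
        object.__setattr__(self, "patients", dict(self.patients))

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients.values())

    def __getitem__(self, patient_id: str) -> PatientRecord:
        return self.patients[patient_id]

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self.patients

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients.keys())


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_MEAS_COLS = ["patient_id", "day", "ca125"]
_TREAT_COLS = ["patient_id", "line_number", "cycle_day", "drug"]
_OUTCOME_COLS = [
    "patient_id",
    "age_at_diagnosis",
    "first_line_type",
    "residual_disease",
    "pretreatment_ca125",
    "uln",
    "diagnosis_day",
    "progression_day",
    "death_day",
    "last_followup_day",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], label: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{label} file is missing column(s): {', '.join(missing)}")


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return float(x)


def _opt_str(x) -> str | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return str(x)


def is_platinum(drug_labels: Iterable[str], agents: Sequence[str] = PLATINUM_AGENTS) -> bool:
    """Case-insensitive substring match of drug labels against platinum agents."""
    for label in drug_labels:
        low = label.lower()
        if any(agent in low for agent in agents):
            return True
    return False


def read_cohort(
    measurements_path,
    treatments_path,
    outcomes_path,
    platinum_agents: Sequence[str] = PLATINUM_AGENTS,
) -> Cohort:
    """Assemble a :class:`Cohort` from the three CSV inputs.

    Files follow the dialects: measurements ``patient_id,day,ca125``;
    treatments ``patient_id,line_number,cycle_day,drug``; outcomes with the
    clinical covariate and outcome-day columns (empty cell = absent).
    """
    meas = pd.read_csv(measurements_path)
    treat = pd.read_csv(treatments_path)
    outc = pd.read_csv(outcomes_path, dtype={"first_line_type": str, "residual_disease": str})
    _require_columns(meas, _MEAS_COLS, "measurements")
    _require_columns(treat, _TREAT_COLS, "treatments")
    _require_columns(outc, _OUTCOME_COLS, "outcomes")

    meas["patient_id"] = meas["patient_id"].astype(str)
    treat["patient_id"] = treat["patient_id"].astype(str)
    outc["patient_id"] = outc["patient_id"].astype(str)

    dup = meas.duplicated(subset=["patient_id", "day"])
    if dup.any():
        bad = meas.loc[dup, ["patient_id", "day"]].iloc[0]
        raise CohortValidationError(
            f"duplicate measurement for patient {bad['patient_id']} at day {bad['day']}"
        )
    if (meas["ca125"] <= 0).any() or not np.isfinite(meas["ca125"]).all():
        bad = meas.loc[~(meas["ca125"] > 0) | ~np.isfinite(meas["ca125"])].iloc[0]
        raise CohortValidationError(
            f"non-positive CA-125 value {bad['ca125']} for patient {bad['patient_id']}"
        )

    outc_by_id = {str(r["patient_id"]): r for _, r in outc.iterrows()}

    patients: dict[str, PatientRecord] = {}
    for pid, group in meas.groupby("patient_id", sort=True):
        group = group.sort_values("day")
        measurements = tuple(
            Measurement(day=float(r.day), value=float(r.ca125)) for r in group.itertuples()
        )
        tgroup = treat[treat["patient_id"] == pid]
        lines = []
        for lnum, lg in tgroup.groupby("line_number", sort=True):
            lg = lg.sort_values("cycle_day")
            lines.append(
                TreatmentLine(
                    line_number=int(lnum),
                    cycle_days=tuple(float(d) for d in lg["cycle_day"]),
                    drug_labels=tuple(str(d) for d in lg["drug"]),
                )
            )
        schedule = TreatmentSchedule(lines=tuple(lines))
        first = next((ln for ln in schedule.lines if ln.line_number == 1), None)
        plat = is_platinum(first.drug_labels, platinum_agents) if first else False

        row = outc_by_id.get(pid)
        kwargs = {}
        if row is not None:
            kwargs = dict(
                age_at_diagnosis=_opt_float(row["age_at_diagnosis"]),
                first_line_type=_opt_str(row["first_line_type"]),
                residual_disease=_opt_str(row["residual_disease"]),
                pretreatment_ca125=_opt_float(row["pretreatment_ca125"]),
                uln=_opt_float(row["uln"]),
                diagnosis_day=_opt_float(row["diagnosis_day"]),
                progression_day=_opt_float(row["progression_day"]),
                death_day=_opt_float(row["death_day"]),
                last_followup_day=_opt_float(row["last_followup_day"]),
            )
        if kwargs.get("death_day") is None and kwargs.get("last_followup_day") is None:
            # outcomes row missing or empty: fall back to the last measurement day
            kwargs["last_followup_day"] = measurements[-1].day if measurements else 0.0
        patients[str(pid)] = PatientRecord(
            patient_id=str(pid),
            measurements=measurements,
            schedule=schedule,
            platinum_first_line=plat,
            **kwargs,
        )
    return Cohort(patients=patients)


def write_cohort(cohort: Cohort, measurements_path, treatments_path, outcomes_path) -> None:
    """Write a cohort back to the three-CSV layout read by :func:`read_cohort`."""
    mrows, trows, orows = [], [], []
    for rec in cohort:
        for m in rec.measurements:
            mrows.append({"patient_id": rec.patient_id, "day": m.day, "ca125": m.value})
        for ln in rec.schedule.lines:
            labels = ln.drug_labels or ("",) * len(ln.cycle_days)
            for cday, drug in zip(ln.cycle_days, labels):
                trows.append(
                    {
                        "patient_id": rec.patient_id,
                        "line_number": ln.line_number,
                        "cycle_day": cday,
                        "drug": drug,
                    }
                )
        orows.append(
            {
                "patient_id": rec.patient_id,
                "age_at_diagnosis": rec.age_at_diagnosis,
                "first_line_type": rec.first_line_type,
                "residual_disease": rec.residual_disease,
                "pretreatment_ca125": rec.pretreatment_ca125,
                "uln": rec.uln,
                "diagnosis_day": rec.diagnosis_day,
                "progression_day": rec.progression_day,
                "death_day": rec.death_day,
                "last_followup_day": rec.last_followup_day,
            }
        )
    pd.DataFrame(mrows, columns=_MEAS_COLS[:2] + ["ca125"]).to_csv(measurements_path, index=False)
    pd.DataFrame(trows, columns=_TREAT_COLS).to_csv(treatments_path, index=False)
    pd.DataFrame(orows, columns=_OUTCOME_COLS).to_csv(outcomes_path, index=False)


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def eligibility_report(cohort: Cohort, min_measurements: int = 7) -> pd.DataFrame:
    """Per-patient eligibility breakdown mirroring the study inclusion criteria."""
    rows = []
    for rec in cohort:
        has_two_lines = rec.schedule.n_lines >= 2
        completed_second = False
        if has_two_lines:
            line2 = rec.schedule.lines[1]
            completed_second = rec.last_record_day >= line2.end_day
        rows.append(
            {
                "patient_id": rec.patient_id,
                "n_measurements": rec.n_measurements,
                "enough_measurements": rec.n_measurements >= min_measurements,
                "completed_second_line": has_two_lines and completed_second,
                "platinum_first_line": rec.platinum_first_line,
                "progression_recorded": rec.progression_day is not None,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "n_measurements",
            "enough_measurements",
            "completed_second_line",
            "platinum_first_line",
            "progression_recorded",
        ],
    )
    if len(df):
        df["eligible"] = (
            df["enough_measurements"]
            & df["completed_second_line"]
            & df["platinum_first_line"]
            & df["progression_recorded"]
        )
    else:
        df["eligible"] = pd.Series(dtype=bool)
    return df


def filter_eligible(cohort: Cohort, min_measurements: int = 7) -> Cohort:
    """Retain patients meeting the study inclusion criteria.

    Criteria: completion of second-line treatment (>= 2 lines and the last
    record day reaches the end of line 2), more than six CA-125 measurements
    (read strictly: >= ``min_measurements`` = 7), a platinum-based first-line
    regimen, and a recorded disease progression. Returns a new cohort; the
    input is unmodified. Idempotent.
    """
    report = eligibility_report(cohort, min_measurements=min_measurements)
    keep = set(report.loc[report["eligible"], "patient_id"]) if len(report) else set()
    return Cohort(patients={pid: cohort[pid] for pid in cohort.patient_ids if pid in keep})
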