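"""Data-based resistance and aggressiveness from per-patient log-linear slopes.

Data-based *resistance* for line k is the OLS slope of ln CA-125 against time
over the measurements falling inside line k's on-treatment interval (decline
during therapy gives a negative slope; values drifting up toward zero across
lines indicate emerging chemoresistance). Data-based *aggressiveness* after
line k is the slope over the gap between the end of line k and the start of
line k+1 (regrowth while off therapy). Natural logarithms throughout; slopes
in any other base are a constant multiple.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord

__all__ = [
    "TraitEstimates",
    "DegenerateWindowError",
    "line_slope",
    "estimate_traits",
    "cohort_trait_table",
]


class DegenerateWindowError(ValueError):
    """All measurement days in a window coincide; a slope is undefined."""


@dataclass(frozen=True)
class TraitEstimates:
    """Per-line slope estimates for one patient (log U/mL per day).

    A slope is present only when at least two measurements with distinct days
    fell in the corresponding window; ``n_resistance``/``n_aggressiveness``
    record the point counts used.
    """

    patient_id: str
    resistance: Mapping[int, float] = field(default_factory=dict)
    aggressiveness: Mapping[int, float] = field(default_factory=dict)
    n_resistance: Mapping[int, int] = field(default_factory=dict)
    n_aggressiveness: Mapping[int, int] = field(default_factory=dict)


def line_slope(points: Sequence[tuple[float, float]]) -> float | None:
    """OLS slope of ln CA-125 against day; ``None`` when fewer than 2 points.

    Raises :class:`DegenerateWindowError` when all days coincide. Invariant to
    rescaling all CA-125 values by a positive constant and equivariant under
    time translation.
    """
    if len(points) < 2:
        return None
    days = np.array([p[0] for p in points], dtype=float)
    values = np.array([p[1] for p in points], dtype=float)
    if np.any(values <= 0):
        raise ValueError("CA-125 values must be positive for log-slope estimation")
    if np.ptp(days) == 0:
        raise DegenerateWindowError("all measurement days identical in window")
    slope, _ = np.polyfit(days, np.log(values), 1)
    return float(slope)


def _window_points(
    patient: PatientRecord, lo: float, hi: float, closed_left: bool, closed_right: bool
) -> list[tuple[float, float]]:
    pts = []
    for m in patient.measurements:
        left_ok = m.day >= lo if closed_left else m.day > lo
        right_ok = m.day <= hi if closed_right else m.day < hi
        if left_ok and right_ok:
            pts.append((m.day, m.value))
    return pts


def estimate_traits(patient: PatientRecord) -> TraitEstimates:
    """Per-line data-based resistance and aggressiveness for one patient.

    Resistance for line k uses the closed on-treatment interval
    [start, end] of line k (boundary measurements belong to the line, matching
    the closed-interval treatment indicator). Single-cycle lines have a
    zero-length interval and yield no resistance slope. Aggressiveness after
    line k uses the open gap (end of line k, start of line k+1); after the
    final line the gap extends through the last measurement.
    """
    resistance: dict[int, float] = {}
    aggressiveness: dict[int, float] = {}
    n_res: dict[int, int] = {}
    n_agg: dict[int, int] = {}
    lines = patient.schedule.lines
    last_day = patient.measurements[-1].day if patient.measurements else float("-inf")
    for idx, ln in enumerate(lines):
        if not ln.is_zero_length:
            pts = _window_points(patient, ln.start_day, ln.end_day, True, True)
            n_res[ln.line_number] = len(pts)
            slope = line_slope(pts)
            if slope is not None:
                resistance[ln.line_number] = slope
        if idx + 1 < len(lines):
            gap_hi, closed_right = lines[idx + 1].start_day, False
        else:
            gap_hi, closed_right = last_day, True
        pts = _window_points(patient, ln.end_day, gap_hi, False, closed_right)
        n_agg[ln.line_number] = len(pts)
        slope = line_slope(pts)
        if slope is not None:
            aggressiveness[ln.line_number] = slope
    return TraitEstimates(
        patient_id=patient.patient_id,
        resistance=resistance,
        aggressiveness=aggressiveness,
        n_resistance=n_res,
        n_aggressiveness=n_agg,
    )


def cohort_trait_table(
    cohort: Cohort, max_line: int = 6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format trait table for lines 1..``max_line`` plus a per-line summary.

    Returns ``(table, summary)``: ``table`` has one row per
    (patient, line, trait) with the slope and point count; ``summary`` gives
    mean, sd, and n of each trait per line.
    """
    rows = []
    for rec in cohort:
        est = estimate_traits(rec)
        for trait, slopes, counts in (
            ("resistance", est.resistance, est.n_resistance),
            ("aggressiveness", est.aggressiveness, est.n_aggressiveness),
        ):
            for line, slope in slopes.items():
                if line <= max_line:
                    rows.append(
                        {
                            "patient_id": rec.patient_id,
                            "line_number": line,
                            "trait": trait,
                            "slope": slope,
                            "n_points": counts[line],
                        }
                    )
    table = pd.DataFrame(
        rows, columns=["patient_id", "line_number", "trait", "slope", "n_points"]
    )
    if len(table):
        summary = (
            table.groupby(["trait", "line_number"])["slope"]
            .agg(mean="mean", sd="std", n="count")
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["trait", "line_number", "mean", "sd", "n"])
    return table, summary
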