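"""Survival stratification of traits and model-estimated parameters.

Overall survival is measured from the end of second-line treatment to death
or last follow-up (starting the clock at the end of line 2 avoids the
survivorship bias of conditioning on having reached later lines). The module
builds complete-case survival inputs from a cohort plus any per-patient
covariate table (trait slopes, fitted model parameters), runs median-split
Kaplan-Meier comparisons with log-rank or Wilcoxon tests, and fits
multivariate Cox proportional-hazards models. The product-limit and partial-
likelihood machinery is lifelines (Efron tie handling); this module owns the
input construction and split protocol.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .cohort import Cohort, PatientRecord

__all__ = [
    "SurvivalSpecificationError",
    "DegenerateSplitError",
    "HazardEstimate",
    "KMSplitResult",
    "build_survival_inputs",
    "median_split_km",
    "cox_multivariate",
]

#: Covariates resolvable directly from the patient record.
CLINICAL_COVARIATES = (
    "age_at_diagnosis",
    "first_line_type",
    "residual_disease",
    "log_pretreatment_ca125",
    "pfi",
)


class SurvivalSpecificationError(ValueError):
    """A requested covariate cannot be resolved from cohort or table."""


class DegenerateSplitError(ValueError):
    """All covariate values identical; a median split is impossible."""


@dataclass(frozen=True)
class HazardEstimate:
    """One covariate's adjusted hazard ratio with 95% CI and p-value."""

    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int


@dataclass(frozen=True)
class KMSplitResult:
    """Median-split Kaplan-Meier comparison of one continuous covariate."""

    covariate: str
    median_value: float
    n_low: int
    n_high: int
    median_survival_low: float
    median_survival_high: float
    statistic: float
    p_value: float
    km_low: KaplanMeierFitter
    km_high: KaplanMeierFitter


def _clinical_value(rec: PatientRecord, name: str):
    if name == "age_at_diagnosis":
        return rec.age_at_diagnosis
    if name == "first_line_type":
        return rec.first_line_type
    if name == "residual_disease":
        return rec.residual_disease
    if name == "log_pretreatment_ca125":
        if rec.pretreatment_ca125 is None or rec.pretreatment_ca125 <= 0:
            return None
        return math.log(rec.pretreatment_ca125)
    if name == "pfi":
        # platinum/progression-free interval: end of line 1 to progression
        if rec.progression_day is None or rec.schedule.n_lines < 1:
            return None
        return rec.progression_day - rec.schedule.lines[0].end_day
    raise SurvivalSpecificationError(f"unknown clinical covariate {name!r}")


def build_survival_inputs(
    cohort: Cohort,
    covariate_names: Sequence[str],
    covariate_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Complete-case survival rows: time, event, and the requested covariates.

    ``time`` runs from the end of second-line treatment to death (event = 1)
    or last follow-up (event = 0). Clinical covariates come from the patient
    records; any other name must be a column of ``covariate_table`` (indexed
    by patient id — e.g. trait slopes or fitted parameters). Patients missing
    any requested covariate, lacking a second line, or with negative follow-up
    are excluded.
    """
    for name in covariate_names:
        if name in CLINICAL_COVARIATES:
            continue
        if covariate_table is None or name not in covariate_table.columns:
            raise SurvivalSpecificationError(
                f"covariate {name!r} is neither clinical nor a column of the covariate table"
            )
    rows = []
    for rec in cohort:
        if rec.schedule.n_lines < 2:
            continue
        t0 = rec.schedule.lines[1].end_day
        end = rec.death_day if rec.death_day is not None else rec.last_followup_day
        if end is None:
            continue
        time = end - t0
        if time < 0:
            continue
        row = {"patient_id": rec.patient_id, "time": time,
               "event": int(rec.death_day is not None)}
        ok = True
        for name in covariate_names:
            if name in CLINICAL_COVARIATES:
                value = _clinical_value(rec, name)
            else:
                if rec.patient_id in covariate_table.index:
                    value = covariate_table.loc[rec.patient_id, name]
                else:
                    value = None
            if value is None or (isinstance(value, float) and not math.isfinite(value)):
                ok = False
                break
            row[name] = value
        if ok:
            rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "time", "event", *covariate_names])


def median_split_km(
    inputs: pd.DataFrame, covariate: str, test: str = "logrank"
) -> KMSplitResult:
    """Kaplan-Meier comparison of the below/above-median groups of a covariate.

    Ties at the median go to the lower group. ``test`` selects the rank test:
    ``"logrank"`` (default) or ``"wilcoxon"`` (Gehan-Breslow weighting).
    """
    if covariate not in inputs.columns:
        raise SurvivalSpecificationError(f"covariate {covariate!r} not in inputs")
    values = inputs[covariate].astype(float)
    med = float(values.median())
    low = inputs[values <= med]
    high = inputs[values > med]
    if len(low) < 2 or len(high) < 2:
        raise DegenerateSplitError(
            f"median split of {covariate!r} leaves groups of {len(low)}/{len(high)}"
        )
    km_low = KaplanMeierFitter(label=f"{covariate} <= median")
    km_low.fit(low["time"], low["event"])
    km_high = KaplanMeierFitter(label=f"{covariate} > median")
    km_high.fit(high["time"], high["event"])
    weightings = None if test == "logrank" else "wilcoxon"
    res = logrank_test(
        low["time"], high["time"], low["event"], high["event"], weightings=weightings
    )
    return KMSplitResult(
        covariate=covariate,
        median_value=med,
        n_low=len(low),
        n_high=len(high),
        median_survival_low=float(km_low.median_survival_time_),
        median_survival_high=float(km_high.median_survival_time_),
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        km_low=km_low,
        km_high=km_high,
    )


def cox_multivariate(
    inputs: pd.DataFrame,
    covariate_names: Sequence[str],
    min_cases_per_covariate: int = 10,
) -> list[HazardEstimate]:
    """Multivariate Cox proportional hazards over the named covariates.

    Categorical covariates are expanded to indicator columns against the
    first (alphabetical) reference level. Requires at least
    ``min_cases_per_covariate`` complete cases per covariate (guardrail).
    Returns one :class:`HazardEstimate` per model column.
    """
    df = inputs[["time", "event", *covariate_names]].copy()
    df = df.dropna()
    n = len(df)
    if n < min_cases_per_covariate * max(1, len(covariate_names)):
        raise ValueError(
            f"{n} complete cases for {len(covariate_names)} covariates is below "
            f"the guardrail of {min_cases_per_covariate} per covariate"
        )
    cat_cols = [c for c in covariate_names if df[c].dtype == object or str(df[c].dtype) == "category"]
    design = pd.get_dummies(df, columns=cat_cols, drop_first=True, dtype=float)
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(
            f"Cox model failed to converge for covariates {list(covariate_names)}: {err}"
        ) from err
    summary = cph.summary
    out = []
    for cov, row in summary.iterrows():
        out.append(
            HazardEstimate(
                covariate=str(cov),
                hazard_ratio=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p_value=float(row["p"]),
                n_used=n,
            )
        )
    return out
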