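"""Synthetic HGSOC cohort generator.

Generates patients with the statistical structure the analysis assumes:
chemotherapy cycles spaced about 21 days apart grouped into lines (median
line duration 106 days, median between-line interval 165 days, both
log-normal), model-driven CA-125 trajectories with multiplicative log-normal
measurement noise, the three qualitative response patterns seen in CA-125
series (fluctuating response, primary resistance, durable response), and
survival times whose hazard depends on the generating parameters.

Parameter priors default to published per-patient estimate summaries for the
sensitive/resistant model (means: delta_R = -0.00018, delta_S = 0.04421,
gamma_S = 0.0142, gamma_R = 0.01024 per day; ln R0 mean 0.1208). The printed
spread of ln R0 is inconsistent with its printed range, so the ln R0 prior sd
is widened to 1.0 here.

Everything is driven by one integer seed; a fixed seed reproduces the cohort
byte for byte.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ad import ADParams, simulate_ad
from .cohort import (
    Cohort,
    Measurement,
    PatientRecord,
    TreatmentLine,
    TreatmentSchedule,
    write_cohort,
)
from .sr import SRParams, simulate_single, simulate_sr

__all__ = ["GeneratorConfig", "generate_schedule", "generate_patient", "generate_cohort"]

#: (mean, sd, (low, high)) truncated-normal priors for the generating rates.
DEFAULT_PRIORS: dict[str, tuple[float, float, tuple[float, float]]] = {
    "delta_R": (-0.00018, 0.0127, (-0.0491, 0.0431)),
    "delta_S": (0.04421, 0.0241, (1e-4, 0.0899)),
    "gamma_S": (0.0142, 0.0167, (1e-4, 0.2441)),
    "gamma_R": (0.01024, 0.0127, (1e-4, 0.0878)),
    "ln_R0": (0.1208, 1.0, (-5.5149, 3.7757)),
    "ln_mu": (-7.0, 1.0, (-12.0, -3.0)),
    "A_gamma": (0.0, 1.0, (-3.0, 3.0)),
    "A_delta": (0.0, 1.0, (-3.0, 3.0)),
    "B_gamma": (1.0, 0.5, (0.1, 3.0)),
    "B_delta": (1.0, 0.5, (0.1, 3.0)),
}

_SECOND_LINE_DRUGS = (
    "carboplatin",
    "carboplatin+gemcitabine",
    "paclitaxel",
    "liposomal doxorubicin",
    "topotecan",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``pattern_weights`` are the probabilities of the three qualitative CA-125
    response patterns: (1) fluctuating response — CA-125 falls during each
    line and regrows between lines; (2) primary resistance — a large resistant
    fraction with net growth under therapy; (3) durable response — strong kill
    of sensitive cells and slow regrowth. ``survival_link`` maps generating
    parameters to the log hazard of death after second-line treatment.
    """

    n_patients: int = 100
    seed: int = 0
    model: str = "sr_r0"  # sr_r0 | sr_mu | single | ad
    parameter_priors: dict[str, tuple[float, float, tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_PRIORS)
    )
    noise_sd: float = 0.2
    cycle_interval: float = 21.0
    line_duration_median: float = 106.0
    line_duration_sigma: float = 0.5
    gap_median: float = 165.0
    gap_sigma: float = 0.5
    n_lines_range: tuple[int, int] = (2, 6)
    gap_points: int = 2
    pattern_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)
    survival_link: dict[str, float] = field(
        default_factory=lambda: {"gamma_S": 20.0, "gamma_R": 20.0, "delta_R": -20.0}
    )
    base_log_hazard: float = -6.9
    censor_horizon: float = 2500.0
    baseline_ca125_median: float = 300.0
    baseline_ca125_sigma: float = 1.0
    uln: float = 35.0
    first_treatment_delay: float = 7.0
    #: Optional post-window drift: after the start of line ``drift_after_line + 1``
    #: the generating rates are multiplied by ``drift_factors`` (SR family only).
    #: Emulates resistance emerging after the fitted lines, which no
    #: constant-parameter fit can anticipate.
    drift_after_line: int | None = None
    drift_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.model not in ("sr_r0", "sr_mu", "single", "ad"):
            raise ValueError(f"unknown generating model {self.model!r}")
        if abs(sum(self.pattern_weights) - 1.0) > 1e-9:
            raise ValueError("pattern_weights must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_lines_range[0] < 2 or self.n_lines_range[1] < self.n_lines_range[0]:
            raise ValueError("n_lines_range must be (lo, hi) with 2 <= lo <= hi")
        if self.drift_after_line is not None and self.model not in ("sr_r0", "sr_mu"):
            raise ValueError("parameter drift is supported for the SR-family models only")


class GenerationError(RuntimeError):
    """No feasible parameter draw found within the rejection budget."""


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, max_tries: int = 1000) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise GenerationError(f"truncated normal ({mean}, {sd}) on [{lo}, {hi}] did not accept")


def generate_schedule(config: GeneratorConfig, rng: np.random.Generator) -> TreatmentSchedule:
    """Draw a treatment schedule: lines of 21-day-spaced cycles with log-normal
    durations and between-line gaps whose medians match the configuration."""
    n_lines = int(rng.integers(config.n_lines_range[0], config.n_lines_range[1] + 1))
    t = config.first_treatment_delay
    lines = []
    for k in range(1, n_lines + 1):
        duration = float(
            rng.lognormal(math.log(config.line_duration_median), config.line_duration_sigma)
        )
        n_cycles = max(2, int(round(duration / config.cycle_interval)) + 1)
        cycle_days = tuple(t + i * config.cycle_interval for i in range(n_cycles))
        if k == 1:
            drugs = ("carboplatin+paclitaxel",) * n_cycles
        else:
            drugs = (str(rng.choice(_SECOND_LINE_DRUGS)),) * n_cycles
        lines.append(TreatmentLine(line_number=k, cycle_days=cycle_days, drug_labels=drugs))
        gap = max(
            float(rng.lognormal(math.log(config.gap_median), config.gap_sigma)),
            config.cycle_interval,
        )
        t = cycle_days[-1] + gap
    return TreatmentSchedule(lines=tuple(lines))


def _draw_theta(config: GeneratorConfig, rng: np.random.Generator, pattern: int, C0: float) -> dict:
    pri = config.parameter_priors
    theta = {
        name: _trunc_normal(rng, *pri[name][:2], *pri[name][2])
        for name in ("gamma_R", "gamma_S", "delta_R", "delta_S")
    }
    if pattern == 1:
        theta["delta_S"] = max(theta["delta_S"], 0.02)
        theta["gamma_S"] = max(theta["gamma_S"], 0.005)
        R0 = min(math.exp(_trunc_normal(rng, *pri["ln_R0"][:2], *pri["ln_R0"][2])), 0.3 * C0)
    elif pattern == 2:
        theta["delta_R"] = -abs(theta["delta_R"]) - 0.002
        theta["delta_S"] = max(theta["delta_S"], 0.02)
        R0 = float(rng.uniform(0.5, 0.9)) * C0
    else:  # durable response
        theta["delta_S"] = max(theta["delta_S"], 0.06)
        theta["gamma_S"] *= 0.15
        theta["gamma_R"] *= 0.15
        R0 = min(math.exp(_trunc_normal(rng, *pri["ln_R0"][:2], *pri["ln_R0"][2])), 0.02 * C0)

    if config.model == "sr_r0":
        theta["mu"], theta["R0"] = 0.0, R0
    elif config.model == "sr_mu":
        theta["mu"] = math.exp(_trunc_normal(rng, *pri["ln_mu"][:2], *pri["ln_mu"][2]))
        theta["R0"] = 0.0
    elif config.model == "single":
        theta["mu"], theta["R0"] = 0.0, 0.0
        theta["gamma_R"], theta["delta_R"] = 0.0, 0.0
    else:  # ad
        for name in ("A_gamma", "A_delta", "B_gamma", "B_delta"):
            theta[name] = _trunc_normal(rng, *pri[name][:2], *pri[name][2])
        theta["mu"], theta["R0"] = 0.0, 0.0
    return theta


def _measurement_days(config: GeneratorConfig, schedule: TreatmentSchedule,
                      rng: np.random.Generator) -> list[float]:
    days = [0.0]
    lines = schedule.lines
    for idx, ln in enumerate(lines):
        days.extend(ln.cycle_days)
        if idx + 1 < len(lines):
            gap = lines[idx + 1].start_day - ln.end_day
            start = ln.end_day
        else:
            gap = max(
                float(rng.lognormal(math.log(config.gap_median), config.gap_sigma)),
                config.cycle_interval,
            )
            start = ln.end_day
        for j in range(1, config.gap_points + 1):
            days.append(start + gap * j / (config.gap_points + 1))
    return sorted(set(days))


def _simulate_truth(config: GeneratorConfig, theta: dict, schedule: TreatmentSchedule,
                    C0: float, days: np.ndarray) -> np.ndarray:
    if config.model == "single":
        traj = simulate_single(theta["gamma_S"], theta["delta_S"], schedule, C0, days)
    elif config.model == "ad":
        params = ADParams(
            gamma_R=theta["gamma_R"], gamma_S=theta["gamma_S"],
            delta_R=theta["delta_R"], delta_S=theta["delta_S"],
            A_gamma=theta["A_gamma"], A_delta=theta["A_delta"],
            B_gamma=theta["B_gamma"], B_delta=theta["B_delta"],
        )
        traj = simulate_ad(params, schedule, C0, days)
    else:
        params = SRParams(
            gamma_R=theta["gamma_R"], gamma_S=theta["gamma_S"],
            delta_R=theta["delta_R"], delta_S=theta["delta_S"],
            mu=theta["mu"], R0=theta["R0"],
        )
        k = config.drift_after_line
        t_switch = (
            schedule.lines[k].start_day
            if k is not None and schedule.n_lines > k
            else None
        )
        if t_switch is None or t_switch >= days[-1]:
            traj = simulate_sr(params, schedule, C0, days)
        else:
            before = days[days <= t_switch]
            pre_days = np.append(before, t_switch) if before.size == 0 or before[-1] != t_switch else before
            traj1 = simulate_sr(params, schedule, C0, pre_days)
            R_sw, S_sw = float(traj1.R[-1]), float(traj1.S[-1])
            drifted = {
                name: getattr(params, name) * config.drift_factors.get(name, 1.0)
                for name in ("gamma_R", "gamma_S", "delta_R", "delta_S", "mu")
            }
            params2 = SRParams(**drifted, R0=R_sw)
            after = days[days > t_switch]
            traj2 = simulate_sr(params2, schedule, R_sw + S_sw, after, start_day=t_switch)
            C = np.concatenate([traj1.C[: before.size], traj2.C])
            return C
    return traj.C


def generate_patient(
    config: GeneratorConfig, rng: np.random.Generator, patient_id: str = "P0"
) -> tuple[PatientRecord, dict]:
    """Draw one patient record plus its ground truth.

    Returns ``(record, truth)`` where ``truth`` holds the generating
    parameters, the response pattern, the true (uncensored) survival time from
    the end of second-line treatment, and the event indicator.
    """
    pattern = int(rng.choice((1, 2, 3), p=config.pattern_weights))
    C0 = float(rng.lognormal(math.log(config.baseline_ca125_median), config.baseline_ca125_sigma))
    schedule = generate_schedule(config, rng)
    theta = _draw_theta(config, rng, pattern, C0)

    end_line2 = schedule.lines[1].end_day
    log_hazard = config.base_log_hazard + sum(
        coef * theta[name] for name, coef in config.survival_link.items()
    )
    survival_time = float(rng.exponential(math.exp(-log_hazard)))
    event = survival_time <= config.censor_horizon
    death_day = end_line2 + survival_time if event else None
    last_day = end_line2 + min(survival_time, config.censor_horizon)

    # truncate schedule and sampling at death/censoring (keep lines 1-2 intact)
    kept = [ln for i, ln in enumerate(schedule.lines) if i < 2 or ln.start_day <= last_day]
    schedule = TreatmentSchedule(lines=tuple(kept))
    days = [d for d in _measurement_days(config, schedule, rng) if d <= last_day or d == 0.0]
    days = np.asarray(sorted(set(days)), dtype=float)

    true_C = _simulate_truth(config, theta, schedule, C0, days)
    noise = rng.normal(0.0, config.noise_sd, size=days.size) if config.noise_sd > 0 else np.zeros(days.size)
    observed = true_C * np.exp(noise)
    measurements = tuple(Measurement(day=float(d), value=float(v)) for d, v in zip(days, observed))

    start_line2 = schedule.lines[1].start_day
    end_line1 = schedule.lines[0].end_day
    progression_day = max(end_line1 + 1.0, start_line2 - 30.0)
    record = PatientRecord(
        patient_id=patient_id,
        measurements=measurements,
        schedule=schedule,
        age_at_diagnosis=float(np.round(rng.normal(62.0, 10.0), 1)),
        first_line_type="PDS" if rng.random() < 0.8 else "NACT",
        residual_disease=str(rng.choice(("<=1cm", ">1cm"), p=(0.28 / 0.95, 0.67 / 0.95)))
        if rng.random() < 0.95
        else None,
        platinum_first_line=True,
        pretreatment_ca125=C0,
        uln=config.uln,
        diagnosis_day=-30.0,
        progression_day=progression_day,
        death_day=death_day,
        last_followup_day=None if event else last_day,
    )
    truth = {
        "patient_id": patient_id,
        "model": config.model,
        "pattern": pattern,
        "C0": C0,
        "survival_time": survival_time,
        "event": int(event),
        "n_lines": schedule.n_lines,
        **{k: theta.get(k, float("nan")) for k in (
            "gamma_R", "gamma_S", "delta_R", "delta_S", "mu", "R0",
            "A_gamma", "A_delta", "B_gamma", "B_delta")},
    }
    return record, truth


def generate_cohort(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> tuple[Cohort, pd.DataFrame]:
    """Generate ``n_patients`` independent patients; optionally write CSVs.

    With ``out_dir`` set, writes ``measurements.csv``, ``treatments.csv``,
    ``outcomes.csv``, and ``ground_truth.csv``. Deterministic for a fixed
    seed (byte-identical files on re-run).
    """
    rng = np.random.default_rng(config.seed)
    patients: dict[str, PatientRecord] = {}
    truths = []
    width = max(3, len(str(max(config.n_patients, 1))))
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        record, truth = generate_patient(config, rng, patient_id=pid)
        patients[pid] = record
        truths.append(truth)
    cohort = Cohort(patients=patients)
    truth_df = pd.DataFrame(
        truths,
        columns=[
            "patient_id", "model", "pattern", "C0", "survival_time", "event", "n_lines",
            "gamma_R", "gamma_S", "delta_R", "delta_S", "mu", "R0",
            "A_gamma", "A_delta", "B_gamma", "B_delta",
        ],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(
            cohort,
            out / "measurements.csv",
            out / "treatments.csv",
            out / "outcomes.csv",
        )
        truth_df.to_csv(out / "ground_truth.csv", index=False)
    return cohort, truth_df
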