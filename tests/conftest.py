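"""Shared fixtures and independent numeric oracles.

The oracles here deliberately avoid the package's closed-form propagation:
they integrate the raw right-hand sides with adaptive or fixed-step schemes
so that agreement between the two routes is a real check.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy.integrate import solve_ivp

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ca125kin.ad import ADParams, delta_of_x, gamma_of_x
from ca125kin.cohort import (
    Cohort,
    Measurement,
    PatientRecord,
    TreatmentLine,
    TreatmentSchedule,
)
from ca125kin.sr import SRParams, regime_segments


def make_schedule(*cycle_day_groups: tuple[float, ...], drugs: str = "carboplatin") -> TreatmentSchedule:
    """Schedule from tuples of cycle days, numbered 1..n."""
    lines = tuple(
        TreatmentLine(
            line_number=i + 1,
            cycle_days=tuple(float(d) for d in days),
            drug_labels=(drugs,) * len(days),
        )
        for i, days in enumerate(cycle_day_groups)
    )
    return TreatmentSchedule(lines=lines)


def make_patient(
    schedule: TreatmentSchedule,
    days,
    values,
    patient_id: str = "P1",
    **kwargs,
) -> PatientRecord:
    measurements = tuple(
        Measurement(day=float(d), value=float(v)) for d, v in zip(days, values)
    )
    kwargs.setdefault("last_followup_day", max(days) if len(days) else 0.0)
    kwargs.setdefault("platinum_first_line", True)
    kwargs.setdefault("progression_day", None)
    return PatientRecord(
        patient_id=patient_id, measurements=measurements, schedule=schedule, **kwargs
    )


def sr_rhs_oracle(
    params: SRParams,
    schedule: TreatmentSchedule,
    C0: float,
    eval_days,
    start_day: float = 0.0,
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> np.ndarray:
    """Adaptive-step integration of the raw sensitive/resistant ODEs."""
    days = np.asarray(eval_days, dtype=float)
    y = np.array([params.R0, C0 - params.R0])
    out = np.empty(days.size)
    i = 0
    t = start_day
    while i < days.size and days[i] == t:
        out[i] = y.sum()
        i += 1
    if i < days.size:
        for t0, t1, a in regime_segments(schedule, t, float(days[-1])):
            def rhs(_t, z):
                R, S = z
                dR = (1 - a) * params.gamma_R * R - a * params.delta_R * R + params.mu * S
                dS = (1 - a) * params.gamma_S * S - a * params.delta_S * S - params.mu * S
                return [dR, dS]

            inside = days[(days > t0) & (days <= t1)]
            t_eval = np.unique(np.append(inside, t1))
            sol = solve_ivp(rhs, (t0, t1), y, t_eval=t_eval, rtol=rtol, atol=atol)
            assert sol.success, sol.message
            for k, td in enumerate(sol.t):
                if i < days.size and td == days[i]:
                    out[i] = sol.y[:, k].sum()
                    i += 1
            y = sol.y[:, -1]
    return out


def ad_rk4_oracle(
    params: ADParams,
    schedule: TreatmentSchedule,
    C0: float,
    eval_days,
    start_day: float = 0.0,
    step: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step classical Runge-Kutta integration of the adaptive-dynamics ODEs."""
    from ca125kin.ad import fitness, fitness_gradient

    days = np.asarray(eval_days, dtype=float)

    def deriv(y, a):
        x = y[1]
        return np.array([fitness(x, a, params), params.K * fitness_gradient(x, a, params)])

    y = np.array([np.log(C0), params.x0])
    N_out = np.empty(days.size)
    x_out = np.empty(days.size)
    i = 0
    t = start_day
    while i < days.size and days[i] == t:
        N_out[i], x_out[i] = np.exp(y[0]), y[1]
        i += 1
    if i < days.size:
        for t0, t1, a in regime_segments(schedule, t, float(days[-1])):
            targets = list(days[(days > t0) & (days <= t1)])
            if not targets or targets[-1] != t1:
                targets.append(t1)
            cur = t0
            for target in targets:
                span = target - cur
                n_steps = max(1, int(np.ceil(span / step)))
                h = span / n_steps
                for _ in range(n_steps):
                    k1 = deriv(y, a)
                    k2 = deriv(y + 0.5 * h * k1, a)
                    k3 = deriv(y + 0.5 * h * k2, a)
                    k4 = deriv(y + h * k3, a)
                    y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                cur = target
                if i < days.size and target == days[i]:
                    N_out[i], x_out[i] = np.exp(y[0]), y[1]
                    i += 1
    return N_out, x_out


def eligible_patient(pid: str, n_meas: int = 10, n_lines: int = 3, platinum=True,
                     progression=True) -> PatientRecord:
    """A patient satisfying (or, via the flags, violating) the study criteria."""
    groups = [tuple(200 * k + 10 + 21 * i for i in range(3)) for k in range(n_lines)]
    sched = make_schedule(*groups, drugs="carboplatin" if platinum else "taxol")
    days = np.linspace(0, 200 * n_lines, n_meas)
    values = 100 * np.exp(-0.001 * days)
    return make_patient(
        sched, days, values, patient_id=pid,
        platinum_first_line=platinum,
        progression_day=300.0 if progression else None,
        last_followup_day=float(days[-1]),
    )


@pytest.fixture
def two_line_schedule() -> TreatmentSchedule:
    return make_schedule((10, 31, 52, 73), (250, 271, 292))


@pytest.fixture
def mean_sr_params() -> SRParams:
    """Cohort-mean rates of the pre-existing-resistance scenario."""
    return SRParams(
        gamma_R=0.01024, gamma_S=0.0142, delta_R=-0.00018, delta_S=0.04421,
        mu=0.0, R0=20.0,
    )


def random_sr_draw(rng: np.random.Generator) -> tuple[SRParams, TreatmentSchedule, float]:
    """Random parameters and schedule for oracle-equivalence checks."""
    n_lines = int(rng.integers(1, 4))
    t = float(rng.uniform(0, 30))
    groups = []
    for _ in range(n_lines):
        n_cycles = int(rng.integers(2, 6))
        groups.append(tuple(t + 21.0 * i for i in range(n_cycles)))
        t = groups[-1][-1] + float(rng.uniform(40, 250))
    schedule = make_schedule(*groups)
    C0 = float(rng.uniform(50, 800))
    params = SRParams(
        gamma_R=float(rng.uniform(0, 0.05)),
        gamma_S=float(rng.uniform(0, 0.08)),
        delta_R=float(rng.uniform(-0.03, 0.04)),
        delta_S=float(rng.uniform(0, 0.09)),
        mu=float(rng.choice([0.0, rng.uniform(0, 0.01)])),
        R0=float(rng.uniform(0, 0.8)) * C0,
    )
    return params, schedule, C0
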