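"""Two-cell-type (treatment-sensitive / treatment-resistant) CA-125 dynamics.

The model tracks sensitive cells S and resistant cells R. Off treatment
(alpha = 0) they grow exponentially at rates gamma_S and gamma_R; on
treatment (alpha = 1) they die at rates delta_S and delta_R, where delta_R
may be negative (resistant cells can keep growing under therapy). Sensitive
cells convert to resistant cells at rate mu, on and off treatment. The
observable is CA-125, C = R + S; an extended variant lets C relax toward
R + S with turnover rate delta_C instead of tracking it instantaneously.

Within any interval of constant alpha the system is linear with constant
coefficients and lower-triangular structure, so propagation uses the exact
closed form; the only numerics are scalar exponentials. Regime boundaries
(line starts/ends) are never integrated across.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .cohort import TreatmentSchedule, alpha as treatment_alpha

__all__ = [
    "SRParams",
    "SRState",
    "Trajectory",
    "propagate_interval",
    "simulate_sr",
    "simulate_single",
    "simulate_sr_extended",
    "regime_segments",
]

#: Below this |b - a| the equal-eigenvalue analytic limit is used.
EIGENVALUE_TOL = 1e-12


@dataclass(frozen=True)
class SRParams:
    """Rates of the sensitive/resistant model, all per day.

    ``delta_R`` is unconstrained in sign; all other rates are non-negative.
    ``R0`` is the initial resistant population (same U/mL-equivalent scale as
    CA-125). ``delta_C`` activates the extended CA-125 turnover variant.
    """

    gamma_R: float
    gamma_S: float
    delta_R: float
    delta_S: float
    mu: float = 0.0
    R0: float = 0.0
    delta_C: float | None = None

    def __post_init__(self) -> None:
        if self.gamma_R < 0 or self.gamma_S < 0:
            raise ValueError("growth rates gamma_R, gamma_S must be non-negative")
        if self.delta_S < 0:
            raise ValueError("delta_S must be non-negative")
        if self.mu < 0:
            raise ValueError("transition rate mu must be non-negative")
        if self.R0 < 0:
            raise ValueError("initial resistant population R0 must be non-negative")
        if self.delta_C is not None and self.delta_C <= 0:
            raise ValueError("CA-125 turnover rate delta_C must be positive")


@dataclass(frozen=True)
class SRState:
    """Populations of resistant (R) and sensitive (S) cells; CA-125 C = R + S."""

    R: float
    S: float

    @property
    def C(self) -> float:
        return self.R + self.S


@dataclass(frozen=True)
class Trajectory:
    """Model output sampled at ``days``: CA-125 ``C`` plus optional state detail."""

    days: np.ndarray
    C: np.ndarray
    R: np.ndarray | None = None
    S: np.ndarray | None = None
    x: np.ndarray | None = None
    regime_boundaries: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        if np.any(np.diff(days) <= 0):
            raise ValueError("trajectory days must be strictly increasing")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "C", np.asarray(self.C, dtype=float))


def propagate_interval(state: SRState, params: SRParams, alpha: int, dt: float) -> SRState:
    """Exact propagation over a constant-``alpha`` interval of length ``dt`` days.

    With a = (1-alpha)*gamma_R - alpha*delta_R and
    b = (1-alpha)*gamma_S - alpha*delta_S - mu:

        S(dt) = S e^{b dt}
        R(dt) = R e^{a dt} + mu S (e^{b dt} - e^{a dt}) / (b - a)

    falling back to the analytic limit R e^{a dt} + mu S dt e^{a dt} when the
    eigenvalues coincide.
    """
    if dt < 0:
        raise ValueError(f"propagation time must be non-negative, got {dt}")
    if dt == 0:
        return state
    a = (1 - alpha) * params.gamma_R - alpha * params.delta_R
    b = (1 - alpha) * params.gamma_S - alpha * params.delta_S - params.mu
    ebt = math.exp(b * dt)
    eat = math.exp(a * dt)
    S_new = state.S * ebt
    if abs(b - a) < EIGENVALUE_TOL:
        R_new = state.R * eat + params.mu * state.S * dt * eat
    else:
        R_new = state.R * eat + params.mu * state.S * (ebt - eat) / (b - a)
    return SRState(R=R_new, S=S_new)


def regime_segments(
    schedule: TreatmentSchedule, start_day: float, end_day: float
) -> list[tuple[float, float, int]]:
    """Split [start_day, end_day] at every alpha switch into (t0, t1, alpha) pieces.

    Zero-length (single-cycle) lines contribute no segment: they have measure
    zero and do not affect the integrated dynamics.
    """
    cuts = {start_day, end_day}
    for s, e in schedule.intervals:
        for t in (s, e):
            if start_day < t < end_day:
                cuts.add(t)
    ts = sorted(cuts)
    segments = []
    for t0, t1 in zip(ts, ts[1:]):
        mid = 0.5 * (t0 + t1)
        segments.append((t0, t1, treatment_alpha(schedule, mid)))
    return segments


def _boundaries(schedule: TreatmentSchedule) -> tuple[float, ...]:
    out: list[float] = []
    for s, e in schedule.intervals:
        out.extend((s, e))
    return tuple(out)


def simulate_sr(
    params: SRParams,
    schedule: TreatmentSchedule,
    C0: float,
    eval_days: Sequence[float],
    start_day: float = 0.0,
) -> Trajectory:
    """Simulate the SR model and return CA-125 (and R, S) at ``eval_days``.

    The initial state at ``start_day`` is (R, S) = (R0, C0 - R0): the observed
    initial CA-125 splits into the pre-existing resistant population and the
    sensitive remainder. Propagation is the exact piecewise closed form,
    chained across every regime boundary and evaluation day.
    """
    if C0 <= 0:
        raise ValueError("C0 must be positive")
    if params.R0 > C0:
        raise ValueError(f"infeasible initial condition: R0 = {params.R0} exceeds C0 = {C0}")
    days = np.asarray(eval_days, dtype=float)
    if days.size == 0:
        return Trajectory(days=days, C=days.copy(), regime_boundaries=_boundaries(schedule))
    if np.any(days < start_day):
        raise ValueError("eval_days must not precede start_day")

    state = SRState(R=params.R0, S=C0 - params.R0)
    t = start_day
    R_out = np.empty(days.size)
    S_out = np.empty(days.size)
    for i, target in enumerate(days):
        if target > t:
            for t0, t1, a in regime_segments(schedule, t, float(target)):
                state = propagate_interval(state, params, a, t1 - t0)
            t = float(target)
        R_out[i] = state.R
        S_out[i] = state.S
    return Trajectory(
        days=days,
        C=R_out + S_out,
        R=R_out,
        S=S_out,
        regime_boundaries=_boundaries(schedule),
    )


def simulate_single(
    gamma_S: float,
    delta_S: float,
    schedule: TreatmentSchedule,
    C0: float,
    eval_days: Sequence[float],
    start_day: float = 0.0,
) -> Trajectory:
    """Single-cell-type special case: no resistant cells (mu = 0, R0 = 0).

    log C(t) is piecewise linear with slope -delta_S on treatment and
    gamma_S off treatment.
    """
    params = SRParams(gamma_R=0.0, gamma_S=gamma_S, delta_R=0.0, delta_S=delta_S)
    return simulate_sr(params, schedule, C0, eval_days, start_day=start_day)


def simulate_sr_extended(
    params: SRParams,
    schedule: TreatmentSchedule,
    C0: float,
    eval_days: Sequence[float],
    start_day: float = 0.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """SR variant where CA-125 relaxes toward R + S at turnover rate delta_C.

    dC/dt = delta_C (R + S - C), coupled to the R/S dynamics; C tracks R + S
    with characteristic lag 1/delta_C. Integrated numerically piecewise
    between regime boundaries (R and S still use the exact rates).
    """
    if params.delta_C is None or params.delta_C <= 0:
        raise ValueError("extended model requires delta_C > 0")
    if C0 <= 0:
        raise ValueError("C0 must be positive")
    if params.R0 > C0:
        raise ValueError("infeasible initial condition: R0 exceeds C0")
    days = np.asarray(eval_days, dtype=float)
    if days.size == 0:
        return Trajectory(days=days, C=days.copy(), regime_boundaries=_boundaries(schedule))
    if np.any(days < start_day):
        raise ValueError("eval_days must not precede start_day")

    dC = params.delta_C
    mu = params.mu

    def rhs(_t, y, a, b):
        R, S, C = y
        return [a * R + mu * S, b * S, dC * (R + S - C)]

    y = np.array([params.R0, C0 - params.R0, C0])
    t = start_day
    out = np.empty(days.size)
    i = 0
    end = float(days[-1])
    # eval days exactly at start
    while i < days.size and days[i] == t:
        out[i] = y[2]
        i += 1
    if i < days.size:
        for t0, t1, a in regime_segments(schedule, t, end):
            coef_a = (1 - a) * params.gamma_R - a * params.delta_R
            coef_b = (1 - a) * params.gamma_S - a * params.delta_S - mu
            inside = days[(days > t0) & (days <= t1)]
            sol = solve_ivp(
                rhs,
                (t0, t1),
                y,
                t_eval=np.unique(np.append(inside, t1)),
                args=(coef_a, coef_b),
                rtol=rtol,
                atol=atol,
                method="RK45",
            )
            if not sol.success:  # pragma: no cover - defensive
                raise RuntimeError(f"integration failed on [{t0}, {t1}]: {sol.message}")
            for k, td in enumerate(sol.t):
                if i < days.size and td == days[i]:
                    out[i] = sol.y[2, k]
                    i += 1
            y = sol.y[:, -1]
    return Trajectory(days=days, C=out, regime_boundaries=_boundaries(schedule))
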