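"""Adaptive-dynamics model: one cancer population climbing a fitness gradient.

All cells share a continuous chemoresistance level x. The population N grows
at gamma(x) off treatment and dies at delta(x) on treatment, where gamma and
delta are logistic interpolations between the sensitive-cell rates (x -> -inf)
and the resistant-cell rates (x -> +inf). The resistance level evolves up the
gradient of the net growth W(x) = (1 - alpha) gamma(x) - alpha delta(x) at
selection-response rate K (fixed at 0.01 per day): treatment pushes x up
toward lower death rates, treatment-free intervals pull it back down toward
higher growth rates.

N is integrated in log space (it is strictly positive), with adaptive error
control, restarting at every treatment-regime switch.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .cohort import TreatmentSchedule
from .sr import Trajectory, regime_segments

__all__ = [
    "ADParams",
    "ADState",
    "gamma_of_x",
    "delta_of_x",
    "fitness",
    "fitness_gradient",
    "simulate_ad",
]

#: Selection-response rate K of the resistance-level equation (per day).
DEFAULT_K = 0.01


@dataclass(frozen=True)
class ADParams:
    """Parameters of the adaptive-dynamics model.

    ``gamma_R/gamma_S/delta_R/delta_S`` carry the same meaning and sign
    constraints as in the SR model. ``A_gamma``/``A_delta`` place the
    half-maximum of the logistic rate curves; ``B_gamma``/``B_delta`` (>= 0)
    set their steepness so the stated x -> +/-inf limits hold. ``K`` scales
    the response to the selection gradient; ``x0`` is the initial resistance
    level (not an estimated parameter — the A offsets absorb the origin).
    """

    gamma_R: float
    gamma_S: float
    delta_R: float
    delta_S: float
    A_gamma: float = 0.0
    A_delta: float = 0.0
    B_gamma: float = 1.0
    B_delta: float = 1.0
    K: float = DEFAULT_K
    x0: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_R < 0 or self.gamma_S < 0:
            raise ValueError("growth rates must be non-negative")
        if self.delta_S < 0:
            raise ValueError("delta_S must be non-negative")
        if self.B_gamma < 0 or self.B_delta < 0:
            raise ValueError("shape parameters B_gamma, B_delta must be non-negative")
        if self.K <= 0:
            raise ValueError("selection-response rate K must be positive")


@dataclass(frozen=True)
class ADState:
    """Total population N (U/mL-equivalent) and resistance level x."""

    N: float
    x: float

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("population N must be non-negative")


def gamma_of_x(x, params: ADParams):
    """Growth rate gamma(x) = gamma_R + (gamma_S - gamma_R) / (1 + e^{B_gamma x + A_gamma}).

    Evaluated overflow-safely; tends to gamma_S as x -> -inf and gamma_R as
    x -> +inf (for B_gamma > 0).
    """
    u = params.B_gamma * np.asarray(x, dtype=float) + params.A_gamma
    out = params.gamma_R + (params.gamma_S - params.gamma_R) * expit(-u)
    return float(out) if np.isscalar(x) else out


def delta_of_x(x, params: ADParams):
    """Death rate delta(x), same logistic form with A_delta/B_delta."""
    u = params.B_delta * np.asarray(x, dtype=float) + params.A_delta
    out = params.delta_R + (params.delta_S - params.delta_R) * expit(-u)
    return float(out) if np.isscalar(x) else out


def fitness(x, alpha: int, params: ADParams):
    """Net per-capita growth W(x) = (1 - alpha) gamma(x) - alpha delta(x)."""
    return (1 - alpha) * gamma_of_x(x, params) - alpha * delta_of_x(x, params)


def _logistic_part_derivative(x, A: float, B: float, lo_minus_hi: float):
    # d/dx [ lo_minus_hi * expit(-(B x + A)) ] = -lo_minus_hi * B * s(1-s)
    u = B * np.asarray(x, dtype=float) + A
    s = expit(-u)
    return -lo_minus_hi * B * s * (1.0 - s)


def fitness_gradient(x, alpha: int, params: ADParams):
    """Analytic dW/dx at resistance level x under treatment status alpha.

    On treatment (delta_S > delta_R, B_delta > 0) the gradient is positive for
    all finite x — selection pushes resistance up; off treatment
    (gamma_S > gamma_R, B_gamma > 0) it is negative — resistance decays.
    """
    dgamma = _logistic_part_derivative(
        x, params.A_gamma, params.B_gamma, params.gamma_S - params.gamma_R
    )
    ddelta = _logistic_part_derivative(
        x, params.A_delta, params.B_delta, params.delta_S - params.delta_R
    )
    out = (1 - alpha) * dgamma - alpha * ddelta
    return float(out) if np.isscalar(x) else out


def simulate_ad(
    params: ADParams,
    schedule: TreatmentSchedule,
    C0: float,
    eval_days: Sequence[float],
    start_day: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Simulate (N, x) on the treatment schedule; CA-125 output is N itself.

    Integrates d(ln N)/dt = W(x), dx/dt = K dW/dx with N(start) = C0 and
    x(start) = x0, restarting the adaptive integrator at every regime switch.
    """
    if C0 <= 0:
        raise ValueError("C0 must be positive")
    days = np.asarray(eval_days, dtype=float)
    boundaries = tuple(b for s, e in schedule.intervals for b in (s, e))
    if days.size == 0:
        return Trajectory(days=days, C=days.copy(), regime_boundaries=boundaries)
    if np.any(days < start_day):
        raise ValueError("eval_days must not precede start_day")

    def rhs(_t, y, a):
        x = y[1]
        return [fitness(x, a, params), params.K * fitness_gradient(x, a, params)]

    y = np.array([math.log(C0), params.x0])
    logN_out = np.empty(days.size)
    x_out = np.empty(days.size)
    i = 0
    while i < days.size and days[i] == start_day:
        logN_out[i], x_out[i] = y
        i += 1
    if i < days.size:
        end = float(days[-1])
        for t0, t1, a in regime_segments(schedule, start_day, end):
            inside = days[(days > t0) & (days <= t1)]
            t_eval = np.unique(np.append(inside, t1))
            sol = solve_ivp(
                rhs, (t0, t1), y, t_eval=t_eval, args=(a,), rtol=rtol, atol=atol
            )
            if not sol.success:
                raise RuntimeError(
                    f"adaptive-dynamics integration failed on [{t0}, {t1}]: {sol.message}"
                )
            for k, td in enumerate(sol.t):
                if i < days.size and td == days[i]:
                    logN_out[i] = sol.y[0, k]
                    x_out[i] = sol.y[1, k]
                    i += 1
            y = sol.y[:, -1]
    with np.errstate(over="ignore"):
        N = np.exp(logN_out)
    return Trajectory(days=days, C=N, x=x_out, regime_boundaries=boundaries)
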