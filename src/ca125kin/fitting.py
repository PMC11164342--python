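"""Per-patient constrained least squares on log CA-125.

Each model variant is fitted to one patient at a time by minimizing the sum
of squared deviations between log-transformed observed CA-125 and the model
prediction, over a fitting window (first two/three/four lines, or all data).
Sign constraints (delta_S, gamma_S, gamma_R, mu, R(0) >= 0; delta_R free) are
enforced by smooth reparameterization: non-negative rates live on a log
scale, R(0) is a logit-transformed fraction of the observed C(0), and
delta_R and the adaptive-dynamics offsets are unconstrained. The local
optimizer is Nelder-Mead simplex with multistart initialization from the
data-based trait slopes, followed by a Gauss-Newton polish of the same
objective; everything is deterministic given the configuration seed.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .ad import ADParams, simulate_ad
from .cohort import Cohort, PatientRecord, TreatmentSchedule
from .sr import SRParams, Trajectory, regime_segments, simulate_sr
from .traits import estimate_traits

__all__ = [
    "ModelVariant",
    "VARIANTS",
    "FittingWindow",
    "FitConfig",
    "FitResult",
    "InsufficientDataError",
    "objective",
    "fit_patient",
    "fit_cohort",
    "fits_to_frame",
    "predict_future",
]

PENALTY = 1e12

_WINDOW_LINES = {"two": 2, "three": 3, "four": 4, "all": None}


class InsufficientDataError(ValueError):
    """Fewer measurements in the window than free parameters + 1."""


@dataclass(frozen=True)
class ModelVariant:
    """A fitting variant: which simulator runs and which parameters are free.

    ``sr_r0``: pre-existing resistant cells (mu = 0, R(0) > 0 free);
    ``sr_mu``: resistance arises by transition (R(0) = 0, mu > 0 free);
    ``single``: one cell type (mu = 0, R(0) = 0);
    ``ad``: adaptive dynamics (8 free parameters, K fixed at 0.01).
    """

    name: str
    free_parameters: tuple[str, ...]
    # transform kind per free parameter: log / identity / logit01
    transforms: tuple[str, ...]

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)


VARIANTS: dict[str, ModelVariant] = {
    "single": ModelVariant("single", ("gamma_S", "delta_S"), ("log", "log")),
    "sr_r0": ModelVariant(
        "sr_r0",
        ("gamma_R", "gamma_S", "delta_R", "delta_S", "r0_frac"),
        ("log", "log", "identity", "log", "logit01"),
    ),
    "sr_mu": ModelVariant(
        "sr_mu",
        ("gamma_R", "gamma_S", "delta_R", "delta_S", "mu"),
        ("log", "log", "identity", "log", "log"),
    ),
    "ad": ModelVariant(
        "ad",
        ("gamma_R", "gamma_S", "delta_R", "delta_S",
         "A_gamma", "A_delta", "B_gamma", "B_delta"),
        ("log", "log", "identity", "log", "identity", "identity", "log", "log"),
    ),
}


@dataclass(frozen=True)
class FittingWindow:
    """Which measurements enter the objective.

    ``two``/``three``/``four`` use all measurements through the gap that
    follows line k, i.e. up to (and including, for boundary measurements) the
    start of line k+1; ``all`` uses every measurement.
    """

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _WINDOW_LINES:
            raise ValueError(f"unknown window kind {self.kind!r}")

    @property
    def n_lines(self) -> int | None:
        return _WINDOW_LINES[self.kind]

    def cutoff_day(self, schedule: TreatmentSchedule) -> float:
        """Last day included in the objective (start of line k+1, else +inf)."""
        k = self.n_lines
        if k is None or schedule.n_lines <= k:
            return math.inf
        return schedule.lines[k].start_day


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings; fits are bit-for-bit reproducible given the seed."""

    n_restarts: int = 20
    seed: int = 0
    max_iter: int = 4000
    xatol: float = 1e-8
    fatol: float = 1e-12
    polish: bool = True
    early_stop_rss: float = 1e-12
    penalty: float = PENALTY


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters and diagnostics for one patient x variant x window."""

    patient_id: str
    variant: str
    window: str
    theta: Mapping[str, float]
    rss: float
    n_obs: int
    converged: bool
    n_restarts_used: int = 0
    C0: float = float("nan")
    message: str = ""


# ---------------------------------------------------------------------------
# Reparameterization
# ---------------------------------------------------------------------------

_LOG_FLOOR = 1e-10


def _to_unconstrained(values: Sequence[float], transforms: Sequence[str]) -> np.ndarray:
    out = np.empty(len(values))
    for i, (v, kind) in enumerate(zip(values, transforms)):
        if kind == "log":
            out[i] = math.log(max(v, _LOG_FLOOR))
        elif kind == "logit01":
            v = min(max(v, 1e-9), 1 - 1e-9)
            out[i] = math.log(v / (1 - v))
        else:
            out[i] = v
    return out


def _to_natural(u: Sequence[float], transforms: Sequence[str]) -> list[float]:
    out = []
    for v, kind in zip(u, transforms):
        if kind == "log":
            out.append(math.exp(min(v, 700.0)))  # overflow-safe; huge rates hit the penalty
        elif kind == "logit01":
            out.append(1.0 / (1.0 + math.exp(-max(min(v, 700.0), -700.0))))
        else:
            out.append(float(v))
    return out


def variant_params(variant: str, theta: Mapping[str, float], C0: float):
    """Materialize a parameter object for ``variant`` from a natural-scale theta."""
    if variant == "single":
        return SRParams(gamma_R=0.0, gamma_S=theta["gamma_S"], delta_R=0.0,
                        delta_S=theta["delta_S"])
    if variant == "sr_r0":
        return SRParams(
            gamma_R=theta["gamma_R"], gamma_S=theta["gamma_S"],
            delta_R=theta["delta_R"], delta_S=theta["delta_S"],
            mu=0.0, R0=theta["r0_frac"] * C0,
        )
    if variant == "sr_mu":
        return SRParams(
            gamma_R=theta["gamma_R"], gamma_S=theta["gamma_S"],
            delta_R=theta["delta_R"], delta_S=theta["delta_S"],
            mu=theta["mu"], R0=0.0,
        )
    if variant == "ad":
        return ADParams(
            gamma_R=theta["gamma_R"], gamma_S=theta["gamma_S"],
            delta_R=theta["delta_R"], delta_S=theta["delta_S"],
            A_gamma=theta["A_gamma"], A_delta=theta["A_delta"],
            B_gamma=theta["B_gamma"], B_delta=theta["B_delta"],
        )
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def window_measurements(patient: PatientRecord, window: FittingWindow) -> tuple[np.ndarray, np.ndarray]:
    """(days, values) of the measurements entering the window's objective."""
    cutoff = window.cutoff_day(patient.schedule)
    days, values = patient.days, patient.values
    mask = days <= cutoff
    return days[mask], values[mask]


class _SRObjective:
    """Fast squared-log-error evaluator for the closed-form SR family.

    Precomputes the regime/evaluation step plan once per (patient, window) so
    each evaluation is a short scalar-exponential recursion.
    """

    def __init__(self, patient: PatientRecord, variant: ModelVariant, window: FittingWindow):
        days, values = window_measurements(patient, window)
        if days.size == 0:
            raise InsufficientDataError("no measurements in fitting window")
        self.variant = variant
        self.log_y = np.log(values)
        self.C0 = float(values[0])
        self.n_obs = int(days.size)
        t0 = float(days[0])
        # step plan: (dt, alpha, emit) walked from the first measurement
        steps: list[tuple[float, int, bool]] = []
        emit0 = 0
        t = t0
        eval_days = [float(d) for d in days]
        while eval_days and eval_days[0] == t:
            emit0 += 1
            eval_days.pop(0)
        self.emit0 = emit0
        for target in eval_days:
            for a0, a1, a in regime_segments(patient.schedule, t, target):
                steps.append((a1 - a0, a, a1 == target))
            t = target
        self.steps = steps

    def rss_natural(self, theta: Mapping[str, float], penalty: float = PENALTY) -> float:
        resid = self.residuals_natural(theta)
        if resid is None:
            return penalty
        return float(np.dot(resid, resid))

    def residuals_natural(self, theta: Mapping[str, float]) -> np.ndarray | None:
        """Log residual vector, or None when the simulation is infeasible."""
        name = self.variant.name
        gamma_R = theta.get("gamma_R", 0.0)
        gamma_S = theta["gamma_S"]
        delta_R = theta.get("delta_R", 0.0)
        delta_S = theta["delta_S"]
        mu = theta.get("mu", 0.0)
        R = theta["r0_frac"] * self.C0 if name == "sr_r0" else 0.0
        S = self.C0 - R
        preds = np.empty(self.n_obs)
        k = 0
        for _ in range(self.emit0):
            preds[k] = self.C0
            k += 1
        try:
            for dt, a, emit in self.steps:
                ca = (1 - a) * gamma_R - a * delta_R
                cb = (1 - a) * gamma_S - a * delta_S - mu
                ebt = math.exp(cb * dt)
                eat = math.exp(ca * dt)
                if mu == 0.0:
                    R = R * eat
                elif abs(cb - ca) < 1e-12:
                    R = R * eat + mu * S * dt * eat
                else:
                    R = R * eat + mu * S * (ebt - eat) / (cb - ca)
                S = S * ebt
                if emit:
                    C = R + S
                    if not (C > 0 and math.isfinite(C)):
                        return None
                    preds[k] = C
                    k += 1
        except OverflowError:
            return None
        resid = self.log_y - np.log(preds)
        return resid if np.all(np.isfinite(resid)) else None


class _ADObjective:
    """Squared-log-error evaluator for the adaptive-dynamics variant.

    Uses a relaxed integrator tolerance (1e-6) inside the optimization loop;
    final reporting paths re-simulate at the tight default tolerance.
    """

    rtol = 1e-6

    def __init__(self, patient: PatientRecord, variant: ModelVariant, window: FittingWindow):
        days, values = window_measurements(patient, window)
        if days.size == 0:
            raise InsufficientDataError("no measurements in fitting window")
        self.variant = variant
        self.days = days
        self.log_y = np.log(values)
        self.C0 = float(values[0])
        self.n_obs = int(days.size)
        self.schedule = patient.schedule

    def rss_natural(self, theta: Mapping[str, float], penalty: float = PENALTY) -> float:
        resid = self.residuals_natural(theta)
        if resid is None:
            return penalty
        return float(np.dot(resid, resid))

    def residuals_natural(self, theta: Mapping[str, float]) -> np.ndarray | None:
        try:
            params = variant_params("ad", theta, self.C0)
            traj = simulate_ad(
                params, self.schedule, self.C0, self.days,
                start_day=float(self.days[0]), rtol=self.rtol,
            )
        except (ValueError, RuntimeError, OverflowError):
            return None
        with np.errstate(all="ignore"):
            resid = self.log_y - np.log(traj.C)
        return resid if np.all(np.isfinite(resid)) else None


def _make_objective(patient: PatientRecord, variant: ModelVariant, window: FittingWindow):
    if variant.name == "ad":
        return _ADObjective(patient, variant, window)
    return _SRObjective(patient, variant, window)


def objective(
    theta: Mapping[str, float],
    patient: PatientRecord,
    variant: str | ModelVariant,
    window: str | FittingWindow,
) -> float:
    """Sum of squared deviations of log CA-125 from the model prediction.

    ``theta`` is on the natural scale and must contain the variant's free
    parameters (``r0_frac`` is the resistant fraction of the observed C(0)).
    Infeasible simulations return a large finite penalty instead of raising,
    so optimizers can recover.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if isinstance(window, str):
        window = FittingWindow(window)
    return _make_objective(patient, variant, window).rss_natural(theta)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _initial_theta(patient: PatientRecord, variant: ModelVariant) -> dict[str, float]:
    """Starting values from the data-based trait slopes.

    delta_S and gamma_S come from first-line resistance/aggressiveness;
    delta_R and gamma_R from the latest line with an estimate (the resistant
    population dominates late), falling back to scaled copies of the
    sensitive-cell values.
    """
    est = estimate_traits(patient)
    first = patient.schedule.lines[0].line_number if patient.schedule.lines else 1

    res1 = est.resistance.get(first)
    delta_S0 = max(-res1, 1e-3) if res1 is not None else 0.03
    agg1 = est.aggressiveness.get(first)
    gamma_S0 = max(agg1, 1e-3) if agg1 is not None else 0.01

    later_res = [v for k, v in sorted(est.resistance.items()) if k != first]
    delta_R0 = -later_res[-1] if later_res else 0.25 * delta_S0
    later_agg = [v for k, v in sorted(est.aggressiveness.items()) if k != first]
    gamma_R0 = max(later_agg[-1], 1e-3) if later_agg else 0.5 * gamma_S0

    theta = {
        "gamma_S": gamma_S0,
        "delta_S": delta_S0,
        "gamma_R": gamma_R0,
        "delta_R": delta_R0,
        "r0_frac": 0.1,
        "mu": 1e-4,
        "A_gamma": 0.0,
        "A_delta": 0.0,
        "B_gamma": 1.0,
        "B_delta": 1.0,
    }
    return {name: theta[name] for name in variant.free_parameters}


def _jitter(u0: np.ndarray, transforms: Sequence[str], rng: np.random.Generator,
            restart: int) -> np.ndarray:
    scale = 0.4 + 0.15 * restart
    u = u0.copy()
    for i, kind in enumerate(transforms):
        if kind == "identity":
            u[i] += rng.normal(0.0, 0.01 * (1.0 + 0.5 * restart))
        else:
            u[i] += rng.normal(0.0, scale)
    return u


def _patient_rng(config: FitConfig, patient_id: str, variant: str, window: str) -> np.random.Generator:
    tag = zlib.crc32(f"{patient_id}|{variant}|{window}".encode())
    return np.random.default_rng([config.seed, tag])


def fit_patient(
    patient: PatientRecord,
    variant: str | ModelVariant,
    window: str | FittingWindow = "all",
    config: FitConfig | None = None,
) -> FitResult:
    """Best constrained least-squares fit over multistart local optimizations.

    Runs ``config.n_restarts`` Nelder-Mead searches on the unconstrained
    reparameterized scale (first start from the trait-based initial guess,
    later starts jittered with growing spread), keeps the best, and polishes
    it with a Gauss-Newton pass on the residual vector. Stops early once the
    objective falls below ``config.early_stop_rss``. Deterministic given the
    configuration seed.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if isinstance(window, str):
        window = FittingWindow(window)
    config = config or FitConfig()

    obj = _make_objective(patient, variant, window)
    if obj.n_obs < variant.n_free + 1:
        raise InsufficientDataError(
            f"{obj.n_obs} measurements in window {window.kind!r} but variant "
            f"{variant.name!r} frees {variant.n_free} parameters"
        )

    transforms = variant.transforms
    names = variant.free_parameters

    def fun(u: np.ndarray) -> float:
        theta = dict(zip(names, _to_natural(u, transforms)))
        return obj.rss_natural(theta, penalty=config.penalty)

    theta0 = _initial_theta(patient, variant)
    u0 = _to_unconstrained([theta0[n] for n in names], transforms)
    rng = _patient_rng(config, patient.patient_id, variant.name, window.kind)

    best_u, best_rss = None, math.inf
    used = 0
    for r in range(max(1, config.n_restarts)):
        u_start = u0 if r == 0 else _jitter(u0, transforms, rng, r)
        res = minimize(
            fun,
            u_start,
            method="Nelder-Mead",
            options={
                "maxiter": config.max_iter,
                "xatol": config.xatol,
                "fatol": config.fatol,
                "adaptive": True,
            },
        )
        used = r + 1
        if res.fun < best_rss:
            best_rss, best_u = float(res.fun), res.x
        if best_rss < config.early_stop_rss:
            break

    if best_u is None or not math.isfinite(best_rss) or best_rss >= config.penalty:
        return FitResult(
            patient_id=patient.patient_id, variant=variant.name, window=window.kind,
            theta={}, rss=math.inf, n_obs=obj.n_obs, converged=False,
            n_restarts_used=used, C0=obj.C0, message="all restarts infeasible",
        )

    if config.polish:
        def resid_fun(u: np.ndarray) -> np.ndarray:
            theta = dict(zip(names, _to_natural(u, transforms)))
            resid = obj.residuals_natural(theta)
            if resid is None:
                return np.full(obj.n_obs, 1e6)
            return resid

        try:
            ls = least_squares(
                resid_fun, best_u, method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=300 * len(names),
            )
            if math.isfinite(ls.cost) and 2 * ls.cost <= best_rss:
                best_u, best_rss = ls.x, float(2 * ls.cost)
        except Exception:
            pass  # keep the simplex optimum

    theta = dict(zip(names, _to_natural(best_u, transforms)))
    return FitResult(
        patient_id=patient.patient_id, variant=variant.name, window=window.kind,
        theta=theta, rss=best_rss, n_obs=obj.n_obs, converged=True,
        n_restarts_used=used, C0=obj.C0,
    )


def fit_cohort(
    cohort: Cohort,
    variants: Iterable[str] = ("sr_r0",),
    windows: Iterable[str] = ("all",),
    config: FitConfig | None = None,
) -> list[FitResult]:
    """Fit every patient x variant x window; failures become non-converged rows.

    Ordering is deterministic: patients in id order, then variants and windows
    in the order given.
    """
    config = config or FitConfig()
    out: list[FitResult] = []
    for pid in sorted(cohort.patient_ids):
        patient = cohort[pid]
        for v in variants:
            for w in windows:
                try:
                    out.append(fit_patient(patient, v, w, config))
                except InsufficientDataError as err:
                    days, _ = window_measurements(patient, FittingWindow(w))
                    out.append(
                        FitResult(
                            patient_id=pid, variant=v, window=w, theta={},
                            rss=math.inf, n_obs=int(days.size), converged=False,
                            message=str(err),
                        )
                    )
    return out


def fits_to_frame(fits: Sequence[FitResult]):
    """Tabular view of fit results (one row per patient x variant x window)."""
    import pandas as pd

    param_names = sorted({k for f in fits for k in f.theta})
    rows = []
    for f in fits:
        row = {
            "patient_id": f.patient_id, "variant": f.variant, "window": f.window,
            "rss": f.rss, "n_obs": f.n_obs, "converged": f.converged,
            "n_restarts_used": f.n_restarts_used, "C0": f.C0, "message": f.message,
        }
        for p in param_names:
            row[p] = f.theta.get(p, float("nan"))
        rows.append(row)
    cols = ["patient_id", "variant", "window"] + param_names + [
        "rss", "n_obs", "converged", "n_restarts_used", "C0", "message"]
    return pd.DataFrame(rows, columns=cols)


def predict_future(fit: FitResult, patient: PatientRecord) -> Trajectory:
    """Simulate the fitted variant over the patient's full schedule.

    Evaluation is at every measurement day (including those beyond the
    fitting window), with C(0) anchored at the first observed CA-125.
    """
    if not fit.converged:
        raise ValueError(f"fit for patient {fit.patient_id} did not converge")
    days = patient.days
    C0 = fit.C0 if math.isfinite(fit.C0) else float(patient.values[0])
    params = variant_params(fit.variant, fit.theta, C0)
    start = float(days[0])
    if fit.variant == "ad":
        return simulate_ad(params, patient.schedule, C0, days, start_day=start)
    return simulate_sr(params, patient.schedule, C0, days, start_day=start)
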