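"""Model-comparison metrics for fitted CA-125 trajectories.

Three complementary views of fit quality:

* ``ratio`` — residual sum of squares of a variable-span local-linear
  smoother (the reference smoother, after Friedman's SuperSmoother) divided
  by the model RSS on the same log CA-125 points; values near 1 mean the
  mechanistic model tracks the data about as well as a flexible smoother.
* ``aic`` — Akaike information criterion with a Gaussian likelihood whose
  variance is profiled out: ln L = -(n/2)(ln(2 pi rss / n) + 1), and
  k counts the free model parameters plus one for the variance.
* three R-squared values on log CA-125 — over the fitted window, over the
  next treatment line (through its following gap), and over all later
  measurements. Total sums of squares are centered on the evaluation
  subset's own mean, which is the convention under which out-of-sample R2
  can go negative when prediction is worse than a constant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord
from .fitting import FitResult, FittingWindow, VARIANTS, predict_future, window_measurements

__all__ = [
    "EvaluationResult",
    "supersmoother",
    "rss_ratio",
    "aic",
    "r_squared_triplet",
    "evaluate_fit",
    "evaluate_cohort",
]

SPANS = (0.05, 0.2, 0.5)
MID_SPAN = 0.2


class InsufficientDataError(ValueError):
    """Too few points for smoothing."""


def _local_linear(days: np.ndarray, values: np.ndarray, span: float) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric nearest-neighbour local-linear fit and its leave-one-out residuals."""
    n = days.size
    k = max(2, int(math.ceil(span * n)))
    fitted = np.empty(n)
    loo = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - k // 2, n - k))
        hi = lo + k
        x = days[lo:hi]
        y = values[lo:hi]
        xbar = x.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        if sxx == 0:
            yhat = y.mean()
            h = 1.0 / k
        else:
            beta = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
            yhat = y.mean() + beta * (days[i] - xbar)
            h = 1.0 / k + (days[i] - xbar) ** 2 / sxx
        fitted[i] = yhat
        if h >= 1.0 - 1e-10:
            # saturated window (e.g. two points): the fit interpolates and
            # cannot be cross-validated; never select this span here
            loo[i] = math.inf
        else:
            loo[i] = (values[i] - yhat) / (1.0 - h)
    return fitted, loo


def supersmoother(
    days: Sequence[float], log_values: Sequence[float], spans: Sequence[float] = SPANS
) -> np.ndarray:
    """Variable-span local-linear smoother of log CA-125 against day.

    For each point the candidate span with the smallest leave-one-out
    cross-validated residual is selected; the selected spans are themselves
    smoothed at the midrange span, and the final fit interpolates between the
    candidate-span fits. Fewer than 10 points fall back to the single
    largest-span local-linear fit. Requires at least 5 points. Exactly
    collinear input is reproduced exactly, and adding a constant to the
    values shifts the output by that constant.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(log_values, dtype=float)
    if days.size != values.size:
        raise ValueError("days and values must have equal length")
    # collapse duplicate days by averaging
    if np.any(np.diff(days) < 0):
        order = np.argsort(days, kind="stable")
        days, values = days[order], values[order]
    else:
        order = None
    uniq, inverse = np.unique(days, return_inverse=True)
    if uniq.size != days.size:
        collapsed = np.zeros(uniq.size)
        counts = np.bincount(inverse)
        np.add.at(collapsed, inverse, values)
        cvalues = collapsed / counts
        fitted_u = supersmoother(uniq, cvalues, spans)
        fitted = fitted_u[inverse]
        if order is not None:
            out = np.empty_like(fitted)
            out[order] = fitted
            return out
        return fitted
    if days.size < 5:
        raise InsufficientDataError(f"need at least 5 points, got {days.size}")

    spans = tuple(sorted(spans))
    if days.size < 10:
        fitted, _ = _local_linear(days, values, spans[-1])
        result = fitted
    else:
        fits, loos = [], []
        for s in spans:
            f, l = _local_linear(days, values, s)
            fits.append(f)
            loos.append(np.abs(l))
        loos = np.vstack(loos)
        choice = np.asarray(spans, dtype=float)[np.argmin(loos, axis=0)]
        smooth_choice, _ = _local_linear(days, choice, MID_SPAN)
        smooth_choice = np.clip(smooth_choice, spans[0], spans[-1])
        fits_arr = np.vstack(fits)
        result = np.empty(days.size)
        span_arr = np.asarray(spans, dtype=float)
        for i in range(days.size):
            s = smooth_choice[i]
            j = int(np.searchsorted(span_arr, s, side="right")) - 1
            j = min(max(j, 0), len(spans) - 2)
            s0, s1 = span_arr[j], span_arr[j + 1]
            w = 0.0 if s1 == s0 else (s - s0) / (s1 - s0)
            result[i] = (1 - w) * fits_arr[j, i] + w * fits_arr[j + 1, i]
    if order is not None:
        out = np.empty_like(result)
        out[order] = result
        return out
    return result


def rss_ratio(rss_sup: float, rss_model: float) -> float:
    """Reference-smoother RSS over model RSS; near 1 means smoother-grade fit.

    A zero model RSS yields +inf (flagged, not raised).
    """
    if rss_sup < 0 or rss_model < 0:
        raise ValueError("residual sums of squares must be non-negative")
    if rss_model == 0:
        return math.inf
    return rss_sup / rss_model


def aic(rss: float, n_obs: int, k: int) -> float:
    """AIC = 2k - 2 ln L with the profiled-variance Gaussian log likelihood.

    ``k`` should count the free model parameters plus one for the profiled
    variance. A zero RSS gives -inf (perfect-fit sentinel).
    """
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if k < 1:
        raise ValueError("k must be at least 1")
    if rss == 0:
        return -math.inf
    log_l = -(n_obs / 2.0) * (math.log(2 * math.pi * rss / n_obs) + 1.0)
    return 2 * k - 2 * log_l


def _r2(y: np.ndarray, yhat: np.ndarray) -> float | None:
    if y.size < 2:
        return None
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return None
    rss = float(np.sum((y - yhat) ** 2))
    return 1.0 - rss / tss


@dataclass(frozen=True)
class EvaluationResult:
    patient_id: str
    variant: str
    window: str
    ratio: float | None
    aic: float | None
    r2_fitted: float | None
    r2_next: float | None
    r2_later: float | None


def r_squared_triplet(
    fit: FitResult, patient: PatientRecord
) -> tuple[float | None, float | None, float | None]:
    """(R2 fitted, R2 next line, R2 all later lines) on log CA-125.

    The fitted set is the fitting window; the next-line set runs from the
    window cutoff through the end of the gap following the next line; the
    later set is everything past the cutoff. Entries are ``None`` when the
    point set has fewer than 2 points (always for the all-line window's
    out-of-sample entries).
    """
    window = FittingWindow(fit.window)
    cutoff = window.cutoff_day(patient.schedule)
    traj = predict_future(fit, patient)
    days = patient.days
    log_y = np.log(patient.values)
    with np.errstate(all="ignore"):
        log_pred = np.log(traj.C)

    fitted_mask = days <= cutoff
    r2_fitted = _r2(log_y[fitted_mask], log_pred[fitted_mask])

    r2_next = r2_later = None
    if math.isfinite(cutoff):
        later_mask = days > cutoff
        r2_later = _r2(log_y[later_mask], log_pred[later_mask])
        k = window.n_lines
        if k is not None:
            # next line is line k+1; its following gap ends at the start of line k+2
            next_cutoff = (
                patient.schedule.lines[k + 1].start_day
                if patient.schedule.n_lines > k + 1
                else math.inf
            )
            next_mask = (days > cutoff) & (days <= next_cutoff)
            r2_next = _r2(log_y[next_mask], log_pred[next_mask])
    return r2_fitted, r2_next, r2_later


def evaluate_fit(fit: FitResult, patient: PatientRecord) -> EvaluationResult:
    """Full metric set for one converged fit.

    The smoother and the model are compared on the same fitting-window
    points; the AIC's parameter count is the variant's free parameters plus
    one for the profiled variance.
    """
    window = FittingWindow(fit.window)
    days, values = window_measurements(patient, window)
    log_y = np.log(values)
    ratio = None
    if fit.converged and days.size >= 5:
        smooth = supersmoother(days, log_y)
        rss_sup = float(np.sum((log_y - smooth) ** 2))
        ratio = rss_ratio(rss_sup, fit.rss)
    aic_val = None
    if fit.converged:
        k = VARIANTS[fit.variant].n_free + 1
        aic_val = aic(fit.rss, fit.n_obs, k)
    if fit.converged:
        r2_fitted, r2_next, r2_later = r_squared_triplet(fit, patient)
    else:
        r2_fitted = r2_next = r2_later = None
    return EvaluationResult(
        patient_id=fit.patient_id, variant=fit.variant, window=fit.window,
        ratio=ratio, aic=aic_val,
        r2_fitted=r2_fitted, r2_next=r2_next, r2_later=r2_later,
    )


def evaluate_cohort(fits: Sequence[FitResult], cohort: Cohort) -> pd.DataFrame:
    """Evaluate every fit against its patient; one row per fit."""
    rows = []
    for fit in fits:
        if fit.patient_id not in cohort:
            continue
        res = evaluate_fit(fit, cohort[fit.patient_id])
        rows.append(
            {
                "patient_id": res.patient_id, "variant": res.variant,
                "window": res.window, "ratio": res.ratio, "aic": res.aic,
                "r2_fitted": res.r2_fitted, "r2_next": res.r2_next,
                "r2_later": res.r2_later,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "variant", "window", "ratio", "aic",
                 "r2_fitted", "r2_next", "r2_later"],
    )
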