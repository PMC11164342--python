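"""Objective correctness, constrained reparameterization, parameter recovery."""
from __future__ import annotations

import math

import numpy as np
import pytest

import ca125kin as ck
from ca125kin.fitting import (
    FitConfig,
    FittingWindow,
    InsufficientDataError,
    VARIANTS,
    _to_natural,
    _to_unconstrained,
    fit_cohort,
    fit_patient,
    fits_to_frame,
    objective,
    predict_future,
)
from ca125kin.sr import SRParams, simulate_sr
from conftest import make_patient, make_schedule


def _sr_patient(theta: dict, schedule, C0=300.0, extra_days=(), pid="P1", noise=None):
    days = sorted({0.0} | {d for ln in schedule.lines for d in ln.cycle_days} | set(extra_days))
    days = np.asarray(days, float)
    p = SRParams(**theta)
    traj = simulate_sr(p, schedule, C0, days)
    values = traj.C if noise is None else traj.C * np.exp(noise)
    return make_patient(schedule, days, values, patient_id=pid)


@pytest.fixture
def four_line_schedule():
    return make_schedule(
        (7, 28, 49, 70, 91), (280, 301, 322, 343), (560, 581, 602, 623), (840, 861, 882)
    )


@pytest.fixture
def truth_theta():
    return dict(gamma_R=0.01024, gamma_S=0.0142, delta_R=-0.00018, delta_S=0.04421,
                mu=0.0, R0=60.0)


class TestObjective:
    def test_zero_at_generating_parameters(self, four_line_schedule, truth_theta):
        patient = _sr_patient(truth_theta, four_line_schedule,
                              extra_days=(150, 215, 430, 495, 700, 765, 950))
        C0 = patient.values[0]
        theta = {k: truth_theta[k] for k in ("gamma_R", "gamma_S", "delta_R", "delta_S")}
        theta["r0_frac"] = truth_theta["R0"] / C0
        assert objective(theta, patient, "sr_r0", "all") < 1e-10

    def test_prediction_off_by_factor_e(self):
        sched = make_schedule((10.0, 31.0))
        patient = make_patient(sched, [0.0], [100.0 * math.e])
        # single-cell prediction at day 0 is C(0) = the observation itself,
        # so force the mismatch through a two-point window
        patient = make_patient(sched, [0.0, 10.0], [100.0, 100.0 * math.e])
        theta = dict(gamma_S=0.0, delta_S=0.0)  # flat prediction = 100 at day 10
        assert objective(theta, patient, "single", "all") == pytest.approx(1.0, rel=1e-12)

    def test_hand_computed_residual_sum(self):
        sched = make_schedule((100.0, 400.0))
        days = [0.0, 10.0, 20.0, 30.0, 40.0]
        values = [100.0, 120.0, 90.0, 150.0, 80.0]
        patient = make_patient(sched, days, values)
        gamma_S = 0.005
        theta = dict(gamma_S=gamma_S, delta_S=0.02)
        pred = 100.0 * np.exp(gamma_S * np.asarray(days))  # all days pre-treatment
        expected = float(np.sum((np.log(values) - np.log(pred)) ** 2))
        assert objective(theta, patient, "single", "all") == pytest.approx(expected, rel=1e-12)

    def test_infeasible_simulation_returns_penalty(self, four_line_schedule, truth_theta):
        patient = _sr_patient(truth_theta, four_line_schedule)
        theta = dict(gamma_R=0.0, gamma_S=50.0, delta_R=0.0, delta_S=0.0, r0_frac=0.5)
        val = objective(theta, patient, "sr_r0", "all")
        assert math.isfinite(val) and val >= 1e11


class TestWindows:
    def test_cutoffs(self, four_line_schedule):
        assert FittingWindow("two").cutoff_day(four_line_schedule) == 560
        assert FittingWindow("three").cutoff_day(four_line_schedule) == 840
        assert FittingWindow("four").cutoff_day(four_line_schedule) == math.inf
        assert FittingWindow("all").cutoff_day(four_line_schedule) == math.inf

    def test_boundary_measurement_included(self, four_line_schedule, truth_theta):
        patient = _sr_patient(truth_theta, four_line_schedule, extra_days=(560.0,))
        from ca125kin.fitting import window_measurements

        days, _ = window_measurements(patient, FittingWindow("two"))
        assert 560.0 in days

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            FittingWindow("five")


class TestReparameterization:
    @pytest.mark.parametrize("variant_name", list(VARIANTS))
    def test_round_trip_identity(self, variant_name):
        rng = np.random.default_rng(9)
        v = VARIANTS[variant_name]
        for _ in range(50):
            natural = []
            for kind in v.transforms:
                if kind == "log":
                    natural.append(float(rng.uniform(1e-6, 0.5)))
                elif kind == "logit01":
                    natural.append(float(rng.uniform(1e-6, 1 - 1e-6)))
                else:
                    natural.append(float(rng.normal(0, 0.05)))
            back = _to_natural(_to_unconstrained(natural, v.transforms), v.transforms)
            np.testing.assert_allclose(back, natural, rtol=1e-12, atol=1e-15)


class TestFitPatient:
    def test_noiseless_sr_r0_recovery(self, four_line_schedule, truth_theta):
        patient = _sr_patient(truth_theta, four_line_schedule,
                              extra_days=(150, 215, 430, 495, 700, 765, 950, 1000))
        fit = fit_patient(patient, "sr_r0", "all", FitConfig(seed=1, n_restarts=10))
        assert fit.converged and fit.rss < 1e-16
        C0 = patient.values[0]
        for name, true in (("gamma_R", 0.01024), ("gamma_S", 0.0142),
                           ("delta_R", -0.00018), ("delta_S", 0.04421),
                           ("r0_frac", 60.0 / C0)):
            assert fit.theta[name] == pytest.approx(true, rel=1e-2, abs=1e-7)

    def test_noiseless_sr_mu_recovery(self, four_line_schedule):
        theta = dict(gamma_R=0.012, gamma_S=0.0142, delta_R=-0.002, delta_S=0.04421,
                     mu=0.0008, R0=0.0)
        patient = _sr_patient(theta, four_line_schedule,
                              extra_days=(150, 215, 430, 495, 700, 765, 950))
        fit = fit_patient(patient, "sr_mu", "all", FitConfig(seed=1, n_restarts=10))
        assert fit.converged and fit.rss < 1e-14

    def test_single_variant_nesting(self, four_line_schedule):
        # data generated by the single-cell model: the richer variant cannot
        # do materially better and the simple one already fits exactly
        theta = dict(gamma_R=0.0, gamma_S=0.0142, delta_R=0.0, delta_S=0.04421,
                     mu=0.0, R0=0.0)
        patient = _sr_patient(theta, four_line_schedule, extra_days=(150, 430, 700))
        cfg = FitConfig(seed=1, n_restarts=6)
        f_single = fit_patient(patient, "single", "all", cfg)
        f_sr = fit_patient(patient, "sr_r0", "all", cfg)
        assert f_single.rss < 1e-16
        assert f_sr.rss < 1e-10  # no material improvement available

    def test_reproducible_bit_for_bit(self, four_line_schedule, truth_theta):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 0.2, size=25)
        patient = _sr_patient(truth_theta, four_line_schedule,
                              extra_days=(150, 215, 430, 495, 700, 765, 950, 1000),
                              noise=noise[: 25])
        cfg = FitConfig(seed=42, n_restarts=4)
        a = fit_patient(patient, "sr_r0", "all", cfg)
        b = fit_patient(patient, "sr_r0", "all", cfg)
        assert a.rss == b.rss
        assert a.theta == b.theta

    def test_insufficient_data_refused(self):
        sched = make_schedule((10.0, 31.0, 52.0))
        patient = make_patient(sched, [0.0, 10.0, 31.0], [100, 80, 70])
        with pytest.raises(InsufficientDataError):
            fit_patient(patient, "sr_r0", "all")  # 3 points < 5 + 1

    def test_restart_monotonicity(self, four_line_schedule, truth_theta):
        rng = np.random.default_rng(5)
        patient = _sr_patient(truth_theta, four_line_schedule,
                              extra_days=(150, 430, 700),
                              noise=rng.normal(0, 0.25, size=20))
        cfg_few = FitConfig(seed=7, n_restarts=1, polish=False, early_stop_rss=0.0)
        cfg_many = FitConfig(seed=7, n_restarts=6, polish=False, early_stop_rss=0.0)
        assert fit_patient(patient, "sr_r0", "all", cfg_many).rss <= \
            fit_patient(patient, "sr_r0", "all", cfg_few).rss + 1e-12

    def test_ad_objective_reaches_zero_on_own_data(self):
        """Adaptive-dynamics self-fit: objective at the optimum is ~0 (the
        parameters themselves may be ridge-identifiable)."""
        from ca125kin.ad import ADParams, simulate_ad

        sched = make_schedule((7, 28, 49, 70, 91), (280, 301, 322, 343))
        days = np.asarray(sorted({0.0} | {d for ln in sched.lines for d in ln.cycle_days}
                                 | {150.0, 215.0, 430.0, 500.0}))
        p = ADParams(gamma_R=0.01, gamma_S=0.0142, delta_R=-0.002, delta_S=0.04421,
                     A_gamma=0.3, A_delta=-0.2, B_gamma=1.0, B_delta=0.8)
        traj = simulate_ad(p, sched, 300.0, days)
        patient = make_patient(sched, days, traj.C)
        fit = fit_patient(patient, "ad", "all",
                          FitConfig(seed=1, n_restarts=2, max_iter=2500, polish=False,
                                    early_stop_rss=1e-8))
        assert fit.converged
        assert fit.rss < 1e-6


class TestFitCohort:
    def test_cartesian_product_rows(self, four_line_schedule, truth_theta):
        p1 = _sr_patient(truth_theta, four_line_schedule, pid="A",
                         extra_days=(150, 430, 700))
        p2 = _sr_patient(truth_theta, four_line_schedule, pid="B",
                         extra_days=(160, 440, 710))
        cohort = ck.Cohort(patients={"A": p1, "B": p2})
        fits = fit_cohort(cohort, ("single", "sr_r0"), ("all",),
                          FitConfig(seed=1, n_restarts=2))
        assert len(fits) == 4
        frame = fits_to_frame(fits)
        assert list(frame.patient_id) == ["A", "A", "B", "B"]

    def test_failure_recorded_not_fatal(self, four_line_schedule, truth_theta):
        ok = _sr_patient(truth_theta, four_line_schedule, pid="A",
                         extra_days=(150, 430, 700))
        sched = make_schedule((10.0, 31.0, 52.0))
        tiny = make_patient(sched, [0.0, 10.0, 31.0], [100, 80, 70], patient_id="B")
        cohort = ck.Cohort(patients={"A": ok, "B": tiny})
        fits = fit_cohort(cohort, ("sr_r0",), ("all",), FitConfig(seed=1, n_restarts=2))
        by_id = {f.patient_id: f for f in fits}
        assert by_id["A"].converged
        assert not by_id["B"].converged and by_id["B"].message


class TestPredictFuture:
    def test_all_line_prediction_days_equal_fitting_days(self, four_line_schedule, truth_theta):
        patient = _sr_patient(truth_theta, four_line_schedule, extra_days=(150, 430, 700))
        fit = fit_patient(patient, "sr_r0", "all", FitConfig(seed=1, n_restarts=4))
        traj = predict_future(fit, patient)
        np.testing.assert_array_equal(traj.days, patient.days)

    def test_two_line_noiseless_future_exact(self, four_line_schedule, truth_theta):
        patient = _sr_patient(truth_theta, four_line_schedule,
                              extra_days=(150, 215, 430, 495, 700, 765, 950))
        fit = fit_patient(patient, "sr_r0", "two", FitConfig(seed=1, n_restarts=8))
        assert fit.rss < 1e-14
        traj = predict_future(fit, patient)
        np.testing.assert_allclose(traj.C, patient.values, rtol=1e-4)

    def test_nonconverged_fit_rejected(self, four_line_schedule, truth_theta):
        patient = _sr_patient(truth_theta, four_line_schedule)
        from ca125kin.fitting import FitResult

        bad = FitResult(patient_id="P1", variant="sr_r0", window="all", theta={},
                        rss=math.inf, n_obs=5, converged=False)
        with pytest.raises(ValueError):
            predict_future(bad, patient)
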