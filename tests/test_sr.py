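"""Closed-form sensitive/resistant dynamics against independent integration."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ca125kin.sr import (
    SRParams,
    SRState,
    propagate_interval,
    simulate_single,
    simulate_sr,
    simulate_sr_extended,
)
from conftest import make_schedule, random_sr_draw, sr_rhs_oracle


class TestPropagateInterval:
    def test_single_exponential_growth(self):
        p = SRParams(gamma_R=0.0, gamma_S=0.01, delta_R=0.0, delta_S=0.0)
        out = propagate_interval(SRState(R=0.0, S=100.0), p, alpha=0, dt=100.0)
        assert out.S == pytest.approx(100.0 * math.e, rel=1e-12)
        assert out.R == 0.0

    def test_mean_kill_rate_over_ten_days(self):
        # delta_S at the cohort-mean value: ten days of treatment leaves e^{-0.4421}
        p = SRParams(gamma_R=0.0, gamma_S=0.0, delta_R=0.0, delta_S=0.04421)
        out = propagate_interval(SRState(R=0.0, S=100.0), p, alpha=1, dt=10.0)
        assert out.S == pytest.approx(100.0 * math.exp(-0.4421), rel=1e-12)
        assert out.S == pytest.approx(64.27, abs=0.01)

    def test_degenerate_equal_eigenvalues_match_oracle(self):
        # a == b exactly: off treatment with gamma_R = gamma_S - mu
        mu = 0.004
        p = SRParams(gamma_R=0.01, gamma_S=0.01 + mu, delta_R=0.0, delta_S=0.0, mu=mu)
        state = SRState(R=5.0, S=100.0)
        out = propagate_interval(state, p, alpha=0, dt=80.0)
        sched = make_schedule()  # no treatment
        oracle = sr_rhs_oracle(
            SRParams(gamma_R=p.gamma_R, gamma_S=p.gamma_S, delta_R=0, delta_S=0,
                     mu=mu, R0=5.0),
            sched, 105.0, [80.0],
        )
        assert out.C == pytest.approx(float(oracle[0]), rel=1e-6)
        # the t e^{at} secular term is present
        assert out.R > state.R * math.exp(0.01 * 80.0)

    def test_negative_dt_rejected(self):
        p = SRParams(gamma_R=0.0, gamma_S=0.01, delta_R=0.0, delta_S=0.0)
        with pytest.raises(ValueError):
            propagate_interval(SRState(R=0.0, S=1.0), p, 0, -1.0)

    def test_semigroup_within_regime(self):
        p = SRParams(gamma_R=0.02, gamma_S=0.03, delta_R=-0.01, delta_S=0.05, mu=0.002)
        s0 = SRState(R=10.0, S=90.0)
        one = propagate_interval(s0, p, 1, 35.0)
        two = propagate_interval(propagate_interval(s0, p, 1, 14.0), p, 1, 21.0)
        assert one.R == pytest.approx(two.R, rel=1e-12)
        assert one.S == pytest.approx(two.S, rel=1e-12)

    @given(
        st.floats(0, 0.05), st.floats(0, 0.08), st.floats(-0.03, 0.05),
        st.floats(0, 0.09), st.floats(0, 0.01), st.integers(0, 1),
    )
    @settings(max_examples=80, deadline=None)
    def test_positivity(self, gR, gS, dR, dS, mu, a):
        p = SRParams(gamma_R=gR, gamma_S=gS, delta_R=dR, delta_S=dS, mu=mu)
        out = propagate_interval(SRState(R=3.0, S=50.0), p, a, 120.0)
        assert out.R >= 0 and out.S >= 0


class TestSimulateSR:
    def test_no_treatment_pure_exponential(self):
        sched = make_schedule()
        p = SRParams(gamma_R=0.0, gamma_S=0.0142, delta_R=0.0, delta_S=0.04421)
        days = np.array([0.0, 50.0, 200.0])
        traj = simulate_sr(p, sched, 300.0, days)
        np.testing.assert_allclose(traj.C, 300.0 * np.exp(0.0142 * days), rtol=1e-12)

    def test_pure_resistant_grows_under_treatment(self):
        # negative death rate = net growth while on therapy
        sched = make_schedule((0.0, 1000.0))
        p = SRParams(gamma_R=0.02, gamma_S=0.0142, delta_R=-0.01, delta_S=0.04421,
                     R0=200.0)
        traj = simulate_sr(p, sched, 200.0, [0.0, 100.0])
        assert traj.C[1] == pytest.approx(200.0 * math.exp(0.01 * 100.0), rel=1e-12)

    def test_oracle_equivalence_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            params, sched, C0 = random_sr_draw(rng)
            horizon = sched.lines[-1].end_day + 200.0
            days = np.sort(rng.uniform(0, horizon, size=12))
            days = np.unique(np.round(days, 6))
            traj = simulate_sr(params, sched, C0, days)
            oracle = sr_rhs_oracle(params, sched, C0, days)
            np.testing.assert_allclose(traj.C, oracle, rtol=1e-6)

    def test_monotone_decay_on_treatment(self):
        sched = make_schedule((0.0, 500.0))
        p = SRParams(gamma_R=0.02, gamma_S=0.03, delta_R=0.005, delta_S=0.05,
                     mu=0.001, R0=50.0)
        days = np.linspace(0, 500, 60)
        traj = simulate_sr(p, sched, 400.0, days)
        assert np.all(np.diff(traj.C) < 0)

    def test_resistant_fraction_nondecreasing_under_treatment(self):
        sched = make_schedule((0.0, 400.0))
        p = SRParams(gamma_R=0.0, gamma_S=0.0, delta_R=0.001, delta_S=0.05, R0=40.0)
        traj = simulate_sr(p, sched, 400.0, np.linspace(0, 400, 40))
        frac = traj.R / traj.C
        assert np.all(np.diff(frac) >= -1e-12)

    def test_infeasible_r0_rejected(self):
        sched = make_schedule((10, 31))
        p = SRParams(gamma_R=0.01, gamma_S=0.01, delta_R=0.0, delta_S=0.01, R0=500.0)
        with pytest.raises(ValueError, match="R0"):
            simulate_sr(p, sched, 100.0, [0.0, 50.0])


class TestSimulateSingle:
    def test_matches_sr_special_case(self, two_line_schedule):
        days = np.linspace(0, 400, 30)
        a = simulate_single(0.0142, 0.04421, two_line_schedule, 250.0, days)
        p = SRParams(gamma_R=0.0, gamma_S=0.0142, delta_R=0.0, delta_S=0.04421)
        b = simulate_sr(p, two_line_schedule, 250.0, days)
        np.testing.assert_allclose(a.C, b.C, rtol=1e-14)

    def test_log_piecewise_linear_slopes(self):
        sched = make_schedule((100.0, 200.0))
        gamma_S, delta_S = 0.0142, 0.04421
        days = np.array([0.0, 50.0, 100.0, 150.0, 200.0, 260.0])
        traj = simulate_single(gamma_S, delta_S, sched, 300.0, days)
        logc = np.log(traj.C)
        assert (logc[1] - logc[0]) / 50.0 == pytest.approx(gamma_S, rel=1e-10)
        assert (logc[3] - logc[2]) / 50.0 == pytest.approx(-delta_S, rel=1e-10)
        assert (logc[5] - logc[4]) / 60.0 == pytest.approx(gamma_S, rel=1e-10)


class TestExtendedModel:
    def test_fast_turnover_converges_to_instantaneous(self, two_line_schedule):
        p = SRParams(gamma_R=0.01, gamma_S=0.02, delta_R=-0.005, delta_S=0.05,
                     R0=30.0, delta_C=1000.0)
        days = np.linspace(30, 400, 20)  # past the short initial transient
        ext = simulate_sr_extended(p, two_line_schedule, 300.0, days)
        inst = simulate_sr(p, two_line_schedule, 300.0, days)
        np.testing.assert_allclose(ext.C, inst.C, rtol=1e-3)

    def test_constant_population_exponential_relaxation(self):
        # gamma_S = 0 off treatment keeps R + S constant; C relaxes at delta_C
        sched = make_schedule()
        p = SRParams(gamma_R=0.0, gamma_S=0.0, delta_R=0.0, delta_S=0.0,
                     R0=0.0, delta_C=0.05)
        days = np.array([0.0, 10.0, 40.0, 100.0])
        traj = simulate_sr_extended(p, sched, 200.0, days)
        np.testing.assert_allclose(traj.C, 200.0, rtol=1e-8)

    def test_requires_positive_delta_c(self, two_line_schedule):
        p = SRParams(gamma_R=0.01, gamma_S=0.02, delta_R=0.0, delta_S=0.05)
        with pytest.raises(ValueError):
            simulate_sr_extended(p, two_line_schedule, 100.0, [0.0, 10.0])

    def test_generic_parameters_match_lagged_oracle(self, two_line_schedule):
        from scipy.integrate import solve_ivp
        from ca125kin.sr import regime_segments

        p = SRParams(gamma_R=0.015, gamma_S=0.025, delta_R=-0.002, delta_S=0.06,
                     mu=0.001, R0=40.0, delta_C=0.1)
        days = np.linspace(0, 380, 25)
        ext = simulate_sr_extended(p, two_line_schedule, 300.0, days)

        y = np.array([40.0, 260.0, 300.0])
        out = [300.0]
        for t0, t1, a in regime_segments(two_line_schedule, 0.0, 380.0):
            def rhs(_t, z):
                R, S, C = z
                dR = (1 - a) * p.gamma_R * R - a * p.delta_R * R + p.mu * S
                dS = (1 - a) * p.gamma_S * S - a * p.delta_S * S - p.mu * S
                return [dR, dS, p.delta_C * (R + S - C)]

            inside = days[(days > t0) & (days <= t1)]
            t_eval = np.unique(np.append(inside, t1))
            sol = solve_ivp(rhs, (t0, t1), y, t_eval=t_eval, rtol=1e-11, atol=1e-12)
            for k, td in enumerate(sol.t):
                if td in days[1:]:
                    out.append(sol.y[2, k])
            y = sol.y[:, -1]
        np.testing.assert_allclose(ext.C, np.array(out), rtol=1e-6)
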