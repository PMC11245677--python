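"""Delayed-autorepression integrator, steady state and Hopf threshold."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from segclock.clock_dde import (
    critical_delay,
    hill_repression,
    integrate,
    steady_state,
)
from segclock.errors import ConfigurationError, DomainError
from segclock.oscillation_metrics import estimate_period, summarize_solution
from segclock.species_params import ClockParameters, DelayBreakdown


def _params(a=4.5, k=33.0, h_p=15.0, h_m=3.0, p_crit=420.0, t_m=31.64, t_p=2.18, n=2.0):
    return ClockParameters(
        a=a, k=k, h_p=h_p, h_m=h_m, p_crit=p_crit, n=n,
        delays=DelayBreakdown(T_tx=0.0, T_in=0.0, T_exp=t_m, T_p=t_p),
    )


class TestHillRepression:
    def test_limits(self):
        assert hill_repression(0.0, 33.0, 420.0) == 33.0
        assert hill_repression(420.0, 33.0, 420.0) == pytest.approx(16.5)
        assert hill_repression(1e9, 33.0, 420.0) < 1e-4

    def test_monotone_decreasing(self):
        p = np.linspace(0, 5000, 200)
        f = hill_repression(p, 33.0, 420.0)
        assert np.all(np.diff(f) < 0)

    def test_rejects_negative_protein(self):
        with pytest.raises(DomainError):
            hill_repression(-1.0, 33.0, 420.0)


class TestIntegrate:
    def test_no_transcription_is_absorbing(self):
        sol = integrate(_params(k=0.0), t_end=200.0, step=0.02)
        assert np.all(sol.mrna == 0.0)
        assert np.all(sol.protein == 0.0)

    def test_zero_delay_converges_to_fixed_point(self):
        """Without delays the feedback loop is a stable ODE; cross-check
        the endpoint against a stiff ODE solve of the same vector field."""
        params = _params(t_m=0.0, t_p=0.0)
        sol = integrate(params, t_end=400.0, step=0.02)
        m_star, p_star = steady_state(params)
        assert sol.mrna[-1] == pytest.approx(m_star, rel=1e-6)
        assert sol.protein[-1] == pytest.approx(p_star, rel=1e-6)

        def rhs(_t, y):
            m, p = y
            return [
                hill_repression(p, params.k, params.p_crit, params.n) - params.c * m,
                params.a * m - params.b * p,
            ]

        oracle = solve_ivp(rhs, (0, 400.0), [0.0, 0.0], method="LSODA", rtol=1e-10)
        assert sol.mrna[-1] == pytest.approx(oracle.y[0, -1], rel=1e-5)
        assert sol.protein[-1] == pytest.approx(oracle.y[1, -1], rel=1e-5)

    def test_step_halving_changes_period_below_0p1_percent(self, amex_bm_baseline):
        p1 = summarize_solution(integrate(amex_bm_baseline, step=0.02)).period
        p2 = summarize_solution(integrate(amex_bm_baseline, step=0.01)).period
        assert abs(p1 - p2) / p2 < 1e-3

    def test_non_negative_from_non_negative_history(self, amex_bm_solution):
        assert np.all(amex_bm_solution.mrna >= 0)
        assert np.all(amex_bm_solution.protein >= 0)

    def test_period_independent_of_history(self, amex_bm_baseline):
        ref = summarize_solution(integrate(amex_bm_baseline)).period
        alt = summarize_solution(
            integrate(amex_bm_baseline, history=(5.0, 300.0))
        ).period
        assert alt == pytest.approx(ref, abs=0.1)

    def test_delay_split_equivalence(self, amex_bm_baseline):
        """Dynamics depend on the delays only through T_m + T_p."""
        total = amex_bm_baseline.total_delay
        periods = []
        for t_p in (0.5, 2.18, 11.0):
            params = _params(t_m=total - t_p, t_p=t_p)
            periods.append(summarize_solution(integrate(params)).period)
        assert max(periods) - min(periods) < 0.05

    def test_mrna_and_protein_periods_agree(self, amex_bm_solution):
        pm = summarize_solution(amex_bm_solution, variable="mrna").period
        pp = summarize_solution(amex_bm_solution, variable="protein").period
        assert abs(pm - pp) <= 0.2

    def test_step_too_large_for_delay_rejected(self, amex_bm_baseline):
        with pytest.raises(ConfigurationError):
            integrate(amex_bm_baseline, t_end=100.0, step=0.5)

    def test_solution_frame_round_trip(self, amex_bm_solution):
        frame = amex_bm_solution.to_frame()
        assert list(frame.columns) == ["t", "mrna", "protein"]
        summary = estimate_period(frame["mrna"].to_numpy(), amex_bm_solution.step)
        assert summary.robust


class TestSteadyState:
    def test_residuals_vanish(self, amex_bm_baseline):
        m_star, p_star = steady_state(amex_bm_baseline)
        p = amex_bm_baseline
        assert p.b * p_star - p.a * m_star == pytest.approx(0.0, abs=1e-9)
        assert hill_repression(p_star, p.k, p.p_crit, p.n) - p.c * m_star == pytest.approx(
            0.0, abs=1e-9
        )

    def test_matches_dense_grid_scan(self, amex_bm_baseline):
        p = amex_bm_baseline
        grid = np.linspace(1e-6, p.a * p.k / (p.b * p.c), 2_000_001)
        resid = np.abs(grid - (p.a / (p.b * p.c)) * hill_repression(grid, p.k, p.p_crit, p.n))
        _, p_star = steady_state(p)
        assert abs(grid[np.argmin(resid)] - p_star) < grid[1] - grid[0]

    def test_vanishing_transcription_limit(self):
        assert steady_state(_params(k=0.0)) == (0.0, 0.0)

    def test_weak_repression_limit(self):
        params = _params(p_crit=1e12)
        _, p_star = steady_state(params)
        expected = params.a * params.k / (params.b * params.c)
        assert p_star == pytest.approx(expected, rel=1e-4)


class TestCriticalDelay:
    def test_threshold_increases_with_protein_halflife(self):
        t_crits = [critical_delay(_params(h_p=h)).T_crit for h in (3, 7, 11, 15, 19, 22)]
        assert all(b > a for a, b in zip(t_crits, t_crits[1:]))

    def test_weak_gain_means_no_hopf(self):
        res = critical_delay(_params(p_crit=1e9))
        assert not res.oscillation_possible
        assert res.T_crit == math.inf
        assert abs(res.gain) <= res.sqrt_k**2

    def test_simulation_brackets_the_hopf_point(self):
        """Trajectories decay just below T_crit and grow just above it."""
        base = _params()
        res = critical_delay(base)
        assert res.oscillation_possible
        assert 16.91 < res.T_crit < 33.82  # damped at -50% delay, robust at baseline
        for factor, should_oscillate in ((0.85, False), (1.15, True)):
            total = factor * res.T_crit
            sol = integrate(base.with_total_delay(total), t_end=6000.0)
            half = sol.mrna[len(sol.mrna) // 2 :]
            late_swing = float(half.max() - half.min())
            if should_oscillate:
                assert late_swing > 1.0
            else:
                assert late_swing < 0.5

    def test_period_near_hopf_matches_crossing_frequency(self):
        base = _params()
        res = critical_delay(base)
        sol = integrate(base.with_total_delay(1.03 * res.T_crit), t_end=12_000.0)
        tail = sol.mrna[len(sol.mrna) // 2 :]
        summary = estimate_period(tail, sol.step, min_amplitude=1e-6)
        assert summary.period == pytest.approx(res.period_at_crossing, rel=0.05)
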