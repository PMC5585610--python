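"""Impulsive stop–restart integration and trajectory summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from dctherapy import (
    Schedule,
    SolverSettings,
    TherapyConfig,
    gompertz_closed_form,
    oscillation_peaks,
    rhs,
    simulate,
    tumor_final,
    tumor_max,
)
from dctherapy.simulate import Trajectory


@pytest.fixture(scope="module")
def therapy():
    return TherapyConfig(V=1e6, tau=232.0, e_f=0.05, apply_efficiency=False)


class TestSimulate:
    def test_empty_schedule_matches_direct_integration(self, params, x0):
        """Without impulses the event machinery must be inert."""
        traj = simulate(x0, Schedule([], 1000.0), TherapyConfig(V=0.0), params)
        ref = solve_ivp(
            lambda t, y: rhs(y, params, check=False),
            (0, 1000.0),
            x0,
            method="Radau",
            rtol=1e-10,
            atol=1e-10 * np.maximum(np.abs(x0), 1),
            t_eval=traj.times,
        )
        assert np.allclose(traj.states[:, 0], ref.y[0], rtol=1e-5)

    def test_single_injection_jumps_d_exactly(self, params, x0, therapy):
        """A bolus at t=10 h takes effect as a jump in D at t=242 h only."""
        traj = simulate(x0, Schedule([10.0], 1000.0), therapy, params)
        (t_imp, jump) = traj.events[0]
        assert t_imp == 242.0
        assert jump == 1e6
        i = np.where(traj.times == 242.0)[0]
        assert len(i) == 2  # pre- and post-jump samples
        pre, post = traj.states[i[0]], traj.states[i[1]]
        assert post[3] - pre[3] == 1e6
        others = [k for k in range(8) if k != 3]
        assert np.allclose(pre[others], post[others], rtol=0, atol=0)

    def test_coincident_injections_merge(self, params, x0, therapy):
        traj = simulate(x0, Schedule([10.0, 10.0], 1000.0), therapy, params)
        assert len(traj.events) == 1
        assert traj.events[0][1] == 2e6
        ref = simulate(x0, Schedule([10.0], 1000.0), TherapyConfig(V=2e6, tau=232.0, apply_efficiency=False), params)
        assert tumor_final(traj) == pytest.approx(tumor_final(ref), rel=1e-9)

    def test_impulse_conservation(self, params, x0, therapy):
        sched = Schedule([10.0, 50.0, 100.0, 100.0], 1000.0)
        traj = simulate(x0, sched, therapy, params)
        assert sum(j for _, j in traj.events) == pytest.approx(4 * therapy.jump, rel=0)

    def test_efficiency_scales_jump(self, params, x0):
        th = TherapyConfig(V=1e6, tau=232.0, e_f=0.05, apply_efficiency=True)
        traj = simulate(x0, Schedule([10.0], 1000.0), th, params)
        assert traj.events[0][1] == 5e4

    def test_time_shift_equivariance(self, params, x0, therapy):
        """The field is autonomous: shifting start, times and horizon shifts
        the trajectory."""
        delta = 137.0
        tight = SolverSettings(rtol=1e-10, atol_scale=1e-10)
        a = simulate(x0, Schedule([50.0], 800.0), therapy, params, solver=tight)
        b = simulate(
            x0, Schedule([50.0 + delta], 800.0 + delta), therapy, params, solver=tight, t0=delta
        )
        for t in (0.0, 100.0, 282.0, 500.0, 799.0):
            np.testing.assert_allclose(
                a.eval(t), b.eval(t + delta), rtol=1e-6, atol=1e-12
            )

    def test_inadmissible_schedule_rejected(self, params, x0, therapy):
        with pytest.raises(ValueError, match="horizon"):
            simulate(x0, Schedule([900.0], 1000.0), therapy, params)  # 900+232 >= 1000
        with pytest.raises(ValueError, match="negative"):
            simulate(x0, Schedule([-5.0], 1000.0), therapy, params)

    def test_nonnegativity_preserved_long_horizon(self, params, rng):
        """Componentwise nonnegativity holds over 20000 h from random
        nonnegative starts."""
        solver = SolverSettings(dt_out=20.0)
        for _ in range(3):
            x = np.array(
                [10 ** rng.uniform(2, 10), rng.uniform(0, 1), rng.uniform(0, 1),
                 10 ** rng.uniform(0, 5), 0.0, 0.0, 0.0, rng.uniform(50, 150)]
            )
            traj = simulate(x, Schedule([], 20000.0), TherapyConfig(V=0.0), params, solver=solver)
            assert traj.states.min() >= -1e-9

    def test_tumor_matches_gompertz_when_ctl_suppressed(self, params, x0):
        """With the CD8 compartment switched off the tumor follows the
        closed-form Gompertz solution."""
        p = params.replace(a_C=1e-300)
        traj = simulate(x0, Schedule([], 1000.0), TherapyConfig(V=0.0), p)
        ref = gompertz_closed_form(6e4, traj.times, p)
        assert np.max(np.abs(traj.tumor - ref) / ref) < 1e-5

    def test_dc_decay_exact_between_impulses(self, params, x0):
        th = TherapyConfig(V=1e6, tau=232.0, apply_efficiency=False)
        tight = SolverSettings(method="Radau", rtol=1e-11, atol_scale=1e-12)
        traj = simulate(x0, Schedule([10.0], 1000.0), th, params, solver=tight)
        sel = traj.times >= 242.0
        t = traj.times[sel][1:]  # skip the duplicated pre-jump sample
        D = traj.states[sel][1:, 3]
        ref = 1e6 * np.exp(-params.mu_D * (t - 242.0))
        assert np.max(np.abs(D - ref) / ref) < 1e-6

    def test_solver_tolerance_refinement_stable(self, params, x0, therapy):
        sched = Schedule([168.0, 336.0, 504.0], 1000.0)
        coarse = simulate(x0, sched, therapy, params)
        fine = simulate(x0, sched, therapy, params, solver=SolverSettings(rtol=5e-9, atol_scale=5e-9))
        assert tumor_final(fine) == pytest.approx(tumor_final(coarse), rel=1e-3)


class TestImpulseBookkeeping:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        times=st.lists(st.floats(min_value=0.0, max_value=700.0), min_size=0, max_size=6),
        tau=st.floats(min_value=0.0, max_value=250.0),
    )
    def test_merged_impulses_conserve_dose_and_order(self, times, tau):
        """Merging coincident impulses never loses dose and keeps times sorted."""
        from dctherapy.simulate import _merged_impulses

        th = TherapyConfig(V=1e5, tau=tau, e_f=0.05, apply_efficiency=True)
        sched = Schedule(times, 1200.0)
        merged = _merged_impulses(sched, th)
        assert sum(j for _, j in merged) == pytest.approx(len(times) * th.jump)
        ts = [t for t, _ in merged]
        assert ts == sorted(ts)
        assert all(b - a > 1e-9 for a, b in zip(ts, ts[1:]))


class TestSummaries:
    def test_final_and_max_order(self, params, x0, therapy):
        traj = simulate(x0, Schedule([168.0, 336.0, 504.0], 1000.0), therapy, params)
        assert tumor_max(traj) >= tumor_final(traj)

    def test_monotone_growth_max_is_final(self, params, x0):
        traj = simulate(x0, Schedule([], 1000.0), TherapyConfig(V=0.0), params)
        assert tumor_max(traj) == tumor_final(traj)

    def test_peaks_of_sine(self):
        t = np.linspace(0, 6 * np.pi, 4000)
        T = 5e8 * (1 + np.sin(t))
        traj = Trajectory(times=t, states=np.column_stack([T] + [np.zeros_like(t)] * 7))
        osc = oscillation_peaks(traj, settle_fraction=0.5)
        assert osc.max_amplitude == pytest.approx(1e9, rel=1e-4)
        expected = np.pi / 2 + 2 * np.pi * np.arange(3)
        assert np.allclose(np.sort(osc.peak_times), expected, atol=0.02)

    def test_monotone_trajectory_has_no_peaks(self, params, x0):
        traj = simulate(x0, Schedule([], 1000.0), TherapyConfig(V=0.0), params)
        osc = oscillation_peaks(traj)
        assert math.isnan(osc.max_amplitude)
        assert math.isnan(osc.stable_amplitude)

    def test_small_late_oscillations_survive_early_transient(self):
        """An early large transient must not mask genuinely small stable
        oscillations (the well-controlled-tumor signature)."""
        t = np.linspace(0, 100, 5000)
        T = 1e9 * np.exp(-((t - 5) ** 2)) + 1e6 * (1 + np.sin(t)) * (t > 20)
        traj = Trajectory(times=t, states=np.column_stack([T] + [np.zeros_like(t)] * 7))
        osc = oscillation_peaks(traj, settle_fraction=0.5)
        assert osc.max_amplitude == pytest.approx(1e9, rel=1e-2)
        assert osc.stable_amplitude == pytest.approx(2e6, rel=0.1)
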