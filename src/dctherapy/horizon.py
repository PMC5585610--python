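"""Interval-wise schedule optimization for long therapy horizons.

Plain steepest descent over a very long horizon (tens of thousands of
hours) converges poorly: early injections barely influence the terminal
tumor mass.  The interval scheme splits ``[0, t_f]`` into ``m`` equal
windows, optimizes a fixed-size schedule inside each window with the
carried-over end state as initial condition, and finally re-simulates the
union of all per-window schedules over the full horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParams
from .optimize import OptimizerConfig, OptRun, optimize
from .simulate import (
    Schedule,
    SolverSettings,
    TherapyConfig,
    Trajectory,
    simulate,
    tumor_max,
)

__all__ = ["IntervalPlan", "optimize_intervals", "viability_check"]


@dataclass
class IntervalPlan:
    """Result of interval-wise optimization.

    ``interval_runs`` holds one :class:`~dctherapy.optimize.OptRun` per
    window; ``schedule`` is the union schedule over the whole horizon and
    ``trajectory`` its full-horizon re-simulation.
    """

    t_f: float
    m: int
    interval_runs: list
    schedule: Schedule
    trajectory: Trajectory

    @property
    def interval_length(self) -> float:
        return self.t_f / self.m


def optimize_intervals(
    x0,
    s0_template: Schedule,
    therapy: TherapyConfig,
    params: ModelParams,
    t_f: float,
    m: int,
    cfg: OptimizerConfig | None = None,
    solver: SolverSettings | None = None,
) -> IntervalPlan:
    """Optimize ``m`` per-window schedules and re-simulate their union.

    ``s0_template`` gives the initial injection times inside one window of
    length ``t_f / m`` (its own ``t_f`` is ignored); the template is
    translated by ``(i-1) t_f/m`` into window ``i``.  Every window's
    optimization clamps its times so impulses land inside the window
    (``t + tau <`` window end).  The carried state at each window end seeds
    the next window.

    With ``m = 1`` this is exactly a single descent run on ``[0, t_f]``.
    """
    if m < 1:
        raise ValueError(f"interval count m must be >= 1, got {m}")
    L = t_f / m
    template = np.asarray(s0_template.times, dtype=float)
    if len(template) and (template.min() < 0 or template.max() + therapy.tau >= L):
        raise ValueError(
            f"template times {template.tolist()} (+ tau {therapy.tau}) must fit inside one "
            f"interval of length {L}"
        )

    x = np.asarray(x0, dtype=float)
    runs: list[OptRun] = []
    union_times: list[float] = []
    for i in range(m):
        a = i * L
        local = Schedule(template + a, a + L)
        run = optimize(x, local, therapy, params, cfg=cfg, solver=solver, t0=a)
        runs.append(run)
        union_times.extend(run.final_schedule.times)
        x = run.trajectory.final_state

    union = Schedule(union_times, t_f)
    traj = simulate(x0, union, therapy, params, solver=solver)
    return IntervalPlan(t_f=t_f, m=m, interval_runs=runs, schedule=union, trajectory=traj)


def viability_check(traj: Trajectory, M_max: float = 1.6e10) -> tuple[bool, float | None]:
    """Does the tumor stay below the survivable burden ``M_max``?

    Returns ``(True, None)`` if ``max T < M_max`` over the whole grid,
    otherwise ``(False, first_crossing_time)``.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    above = traj.tumor >= M_max
    if not above.any():
        return True, None
    return False, float(traj.times[int(np.argmax(above))])
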