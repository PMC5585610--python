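"""Steepest-descent optimization of injection times.

The cost of a schedule is the final tumor burden ``T(t_f)``.  Its gradient
with respect to an injection time is obtained from the variational
(linearized) equation: along the reference trajectory ``x_s`` the
perturbation ``v`` satisfies ``v' = D_x f(x_s(t)) v``.  Nudging the i-th
impulse later by ``dt`` perturbs the state just after the impulse by
``[f(x-) - f(x- + e_D * dose)] dt`` (the flow runs a little longer before the
jump instead of after it), so integrating ``v`` from the impulse time to the
horizon with that initial condition yields ``v_i(t_f) = d x(t_f) / d t_i``.
A descent step moves every injection time against the projected sensitivity,
either with a fixed step or with a golden-section line search that
re-simulates the full system at each trial step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import IDX_D, IDX_T, ModelParams, jacobian, rhs
from .simulate import (
    Schedule,
    SolverSettings,
    TherapyConfig,
    Trajectory,
    simulate,
    tumor_final,
)

__all__ = [
    "OptimizerConfig",
    "OptRun",
    "sensitivity",
    "gradient",
    "golden_section_step",
    "optimize",
    "merged_injections",
]

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for the schedule descent.

    ``projection`` selects which coordinate of the terminal sensitivity
    ``v_i(t_f)`` is used as the gradient: ``"tumor"`` (the coordinate the
    cost actually measures, default) or ``"dc"`` (the literal DC-coordinate
    update kept for fidelity experiments — note the DC sensitivity is always
    positive, so it shifts every time uniformly earlier).

    ``ic_at_impulse`` starts the variational equation at the physical jump
    time ``t_i + tau`` (default); off starts it at the nominal injection
    time ``t_i``.

    Step modes: ``"golden_section"`` line-searches the step on
    ``[0, gss_move_cap / max|g|]`` (so no time moves more than
    ``gss_move_cap`` hours per outer step) down to a bracket narrower than
    ``gss_time_tol`` hours; ``"fixed"`` uses the raw step ``h_fixed``;
    ``"fixed_normalized"`` moves the steepest time by ``step_scale`` hours
    each iteration (``h = step_scale / max|g|``).
    """

    n_steps: int = 10
    step_mode: str = "golden_section"
    h_fixed: float = 1e-6
    step_scale: float = 1.0
    gss_move_cap: float = 250.0
    gss_time_tol: float = 1.0
    projection: str = "tumor"
    ic_at_impulse: bool = True
    merge_tol: float = 0.5
    sens_rtol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.step_mode not in ("fixed", "fixed_normalized", "golden_section"):
            raise ValueError(f"unknown step_mode {self.step_mode!r}")
        if self.projection not in ("tumor", "dc"):
            raise ValueError(f"unknown projection {self.projection!r}")
        if self.h_fixed <= 0 or self.step_scale <= 0 or self.gss_move_cap <= 0:
            raise ValueError("step sizes must be positive")

    @property
    def proj_index(self) -> int:
        return IDX_T if self.projection == "tumor" else IDX_D


@dataclass
class OptRun:
    """Per-iteration history of a descent run.

    ``schedules`` has one entry per iterate plus the final schedule;
    ``costs`` the matching ``T(t_f)`` values; ``gradients`` one entry per
    completed descent step.  ``trajectory`` is the simulation of the final
    schedule.
    """

    schedules: list
    costs: list
    gradients: list
    trajectory: Trajectory

    @property
    def final_schedule(self) -> Schedule:
        return self.schedules[-1]

    @property
    def final_cost(self) -> float:
        return self.costs[-1]


def sensitivity(
    traj: Trajectory,
    schedule: Schedule,
    i: int,
    therapy: TherapyConfig,
    params: ModelParams,
    cfg: OptimizerConfig | None = None,
) -> np.ndarray:
    """Terminal sensitivity ``v_i(t_f) = d x(t_f)/d t_i`` for injection ``i``.

    Integrates the linear time-varying system ``v' = D_x f(x_s(t)) v`` from
    the impulse time to the horizon.  The initial condition is the flow
    mismatch created by delaying the jump:
    ``f(x_post - e_D dose) - f(x_post)`` where ``x_post`` is the post-jump
    state (for coincident injections this perturbs only the one being
    moved).  The reference trajectory is evaluated by dense interpolation;
    later impulses are time-fixed and contribute no first-order term, so the
    linear flow integrates straight through them.
    """
    cfg = cfg or OptimizerConfig()
    if not 0 <= i < schedule.n:
        raise IndexError(f"injection index {i} out of range for {schedule.n} injections")
    jump = therapy.jump
    t_start = schedule.times[i] + (therapy.tau if cfg.ic_at_impulse else 0.0)
    if not traj.t0 <= t_start < schedule.t_f:
        raise IndexError(f"sensitivity start time {t_start} outside [{traj.t0}, {schedule.t_f})")
    if jump == 0.0:
        return np.zeros(8)

    x_post = traj.eval(t_start, side="post")
    x_pre = x_post.copy()
    x_pre[IDX_D] -= jump
    v0 = rhs(x_pre, params, check=False) - rhs(x_post, params, check=False)

    def A(t):
        x = traj.eval(t)
        if x[IDX_T] <= 0.0:
            x[IDX_T] = 1e-300
        return jacobian(x, params)

    def vf(t, v):
        return A(t) @ v

    atol = 1e-10 * max(float(np.max(np.abs(v0))), 1.0)
    sol = solve_ivp(
        vf,
        (t_start, schedule.t_f),
        v0,
        method="BDF",
        rtol=cfg.sens_rtol,
        atol=atol,
        jac=lambda t, v: A(t),  # the system is linear: its Jacobian is A(t)
    )
    if not sol.success:
        raise RuntimeError(f"variational integration failed: {sol.message}")
    return sol.y[:, -1]


def gradient(
    traj: Trajectory,
    schedule: Schedule,
    therapy: TherapyConfig,
    params: ModelParams,
    cfg: OptimizerConfig | None = None,
) -> np.ndarray:
    """Per-injection gradient ``g_i`` of the cost with respect to ``t_i``.

    ``g_i`` is the configured projection of ``v_i(t_f)``; in ``"tumor"``
    mode this is exactly ``dT(t_f)/dt_i``.
    """
    cfg = cfg or OptimizerConfig()
    return np.array(
        [sensitivity(traj, schedule, i, therapy, params, cfg)[cfg.proj_index] for i in range(schedule.n)]
    )


def golden_section_step(objective, h_max: float, tol: float) -> tuple[float, float]:
    """Golden-section search for the step size on ``[0, h_max]``.

    Shrinks the bracket until its width is below ``tol`` and returns
    ``(h*, objective(h*))``.  A degenerate bracket returns step 0.
    """
    if h_max <= 0 or not math.isfinite(h_max):
        return 0.0, objective(0.0)
    a, b = 0.0, h_max
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = objective(c), objective(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = objective(d)
    h = c if fc < fd else d
    return (h, fc if fc < fd else fd)


def _clamped(times: np.ndarray, tau: float, t_f: float, margin: float = 1e-6) -> np.ndarray:
    hi = t_f - tau - margin
    return np.sort(np.clip(times, 0.0, hi))


def optimize(
    x0,
    schedule0: Schedule,
    therapy: TherapyConfig,
    params: ModelParams,
    cfg: OptimizerConfig | None = None,
    solver: SolverSettings | None = None,
    t0: float = 0.0,
) -> OptRun:
    """Steepest-descent loop over injection times.

    Each iteration simulates the current schedule, computes the variational
    gradient, takes a descent step ``t <- t - h g`` (fixed or line-searched),
    clamps to the admissible window ``[0, t_f - tau)`` and re-sorts.  The
    number of injections and the dose never change; only the times move.
    In golden-section mode a step is rejected (h = 0) if no trial improves
    the cost, so the cost history is non-increasing.
    """
    cfg = cfg or OptimizerConfig()
    times = _clamped(np.asarray(schedule0.times, dtype=float), therapy.tau, schedule0.t_f)
    t_f = schedule0.t_f

    def run(tvec: np.ndarray) -> Trajectory:
        return simulate(x0, Schedule(tvec, t_f), therapy, params, solver=solver, t0=t0)

    schedules: list[Schedule] = []
    costs: list[float] = []
    grads: list[np.ndarray] = []

    traj = run(times)
    for _ in range(cfg.n_steps):
        cost = tumor_final(traj)
        sch = Schedule(times, t_f)
        schedules.append(sch)
        costs.append(cost)
        g = gradient(traj, sch, therapy, params, cfg)
        grads.append(g)
        gmax = float(np.max(np.abs(g))) if len(g) else 0.0
        if gmax == 0.0:
            break
        if cfg.step_mode == "fixed":
            h = cfg.h_fixed
        elif cfg.step_mode == "fixed_normalized":
            h = cfg.step_scale / gmax
        else:
            cache: dict[float, float] = {0.0: cost}

            def phi(h: float) -> float:
                if h not in cache:
                    cache[h] = tumor_final(run(_clamped(times - h * g, therapy.tau, t_f)))
                return cache[h]

            h, c_star = golden_section_step(phi, cfg.gss_move_cap / gmax, cfg.gss_time_tol / gmax)
            if c_star >= cost:
                h = 0.0
        times = _clamped(times - h * g, therapy.tau, t_f)
        traj = run(times)
        if h == 0.0 and cfg.step_mode == "golden_section":
            break

    schedules.append(Schedule(times, t_f))
    costs.append(tumor_final(traj))
    return OptRun(schedules=schedules, costs=costs, gradients=grads, trajectory=traj)


def merged_injections(schedule: Schedule, dose: float, tol: float = 0.5) -> list[tuple[float, float]]:
    """Group injection times closer than ``tol`` hours into combined doses.

    Returns ``(mean_time, total_dose)`` pairs — the natural reading of a
    converged schedule whose times have coalesced.
    """
    out: list[tuple[list[float], float]] = []
    for t in schedule.times:
        if out and t - out[-1][0][-1] <= tol:
            out[-1][0].append(t)
            out[-1] = (out[-1][0], out[-1][1] + dose)
        else:
            out.append(([t], dose))
    return [(float(np.mean(ts)), d) for ts, d in out]
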