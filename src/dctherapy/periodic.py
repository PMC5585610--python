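"""Poincaré-map analysis of periodically pulsed therapy.

A pulsed schedule repeated with period ``sigma`` induces the stroboscopic
map ``F(x0) = x(sigma)``: integrate one period of the pulsed system from
``x0``.  Fixed points of ``F`` are periodic solutions; the eigenvalue moduli
(Floquet multipliers) of the Jacobian of ``F`` (the monodromy matrix)
classify their stability.  The module builds the map, the fixed-point
residual, a Newton refinement, and the multiplier classification — no
continuation or bifurcation tracking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import N_STATES, ModelParams
from .simulate import Schedule, SolverSettings, TherapyConfig, simulate

__all__ = [
    "PeriodicResult",
    "poincare_map",
    "periodic_residual",
    "residual_norm",
    "monodromy",
    "stability",
    "refine_fixed_point",
]

#: Tight tolerances for monodromy finite differences: the difference quotient
#: amplifies solver error by 1/step, so the map must be integrated well below
#: the differencing step.
MONODROMY_SOLVER = SolverSettings(rtol=1e-10, atol_scale=1e-10, dt_out=math.inf)


@dataclass
class PeriodicResult:
    """Stability summary of a candidate periodic state.

    ``multipliers`` are the eigenvalue moduli of the monodromy matrix in
    decreasing order; classification is ``stable`` when all lie below
    ``1 - tol``, ``unstable`` when any exceeds ``1 + tol``, else
    ``marginal``.  ``fixed_point_ok`` records whether the residual met the
    fixed-point precondition.
    """

    residual_norm: float
    monodromy: np.ndarray
    multipliers: np.ndarray
    classification: str
    fixed_point_ok: bool


def poincare_map(
    x0,
    sigma: float,
    period_schedule: Schedule | list | tuple,
    therapy: TherapyConfig,
    params: ModelParams,
    solver: SolverSettings | None = None,
) -> np.ndarray:
    """One-period stroboscopic map ``F(x0) = x(sigma)``.

    ``period_schedule`` lists the injection times of one period (a bare
    sequence is accepted); impulses must land inside ``[0, sigma)``.
    """
    if sigma <= 0:
        raise ValueError(f"period sigma must be positive, got {sigma}")
    times = period_schedule.times if isinstance(period_schedule, Schedule) else period_schedule
    sched = Schedule(times, sigma)
    solver = solver or SolverSettings(dt_out=max(sigma / 64.0, 1.0))
    traj = simulate(x0, sched, therapy, params, solver=solver)
    return traj.final_state


def periodic_residual(
    x0,
    sigma: float,
    period_schedule,
    therapy: TherapyConfig,
    params: ModelParams,
    solver: SolverSettings | None = None,
) -> np.ndarray:
    """Fixed-point residual ``F(x0) - x0``, componentwise."""
    x0 = np.asarray(x0, dtype=float)
    return poincare_map(x0, sigma, period_schedule, therapy, params, solver) - x0


def residual_norm(residual: np.ndarray, x0) -> float:
    """Relative residual norm across 12 orders of magnitude of state scale.

    Each coordinate is scaled by ``max(|x0_k|, 1)`` before taking the
    Euclidean norm.
    """
    x0 = np.asarray(x0, dtype=float)
    return float(np.linalg.norm(residual / np.maximum(np.abs(x0), 1.0)))


def monodromy(
    x0,
    sigma: float,
    period_schedule,
    therapy: TherapyConfig,
    params: ModelParams,
    rel_step: float = 1e-6,
    solver: SolverSettings | None = None,
) -> np.ndarray:
    """Jacobian of the Poincaré map by central finite differences.

    Per-coordinate step ``rel_step * max(|x0_k|, 1)``.  A coordinate at zero
    uses a one-sided (forward) difference so the state never leaves the
    nonnegative cone.
    """
    x0 = np.asarray(x0, dtype=float)
    solver = solver or MONODROMY_SOLVER
    M = np.empty((N_STATES, N_STATES))
    for k in range(N_STATES):
        h = rel_step * max(abs(x0[k]), 1.0)
        xp = x0.copy()
        xp[k] += h
        Fp = poincare_map(xp, sigma, period_schedule, therapy, params, solver)
        if x0[k] - h >= 0.0:
            xm = x0.copy()
            xm[k] -= h
            Fm = poincare_map(xm, sigma, period_schedule, therapy, params, solver)
            M[:, k] = (Fp - Fm) / (2.0 * h)
        else:
            F0 = poincare_map(x0, sigma, period_schedule, therapy, params, solver)
            M[:, k] = (Fp - F0) / h
    return M


def stability(
    x_p,
    sigma: float,
    period_schedule,
    therapy: TherapyConfig,
    params: ModelParams,
    rel_step: float = 1e-6,
    residual_threshold: float = 1e-3,
    tol: float = 1e-3,
    solver: SolverSettings | None = None,
) -> PeriodicResult:
    """Classify a candidate periodic state by its Floquet multipliers.

    ``x_p`` should be an (approximate) fixed point of the map; if its scaled
    residual exceeds ``residual_threshold`` the result carries
    ``fixed_point_ok=False`` rather than raising — the multipliers of a
    near-cycle are still informative.
    """
    x_p = np.asarray(x_p, dtype=float)
    res = periodic_residual(x_p, sigma, period_schedule, therapy, params, solver)
    rnorm = residual_norm(res, x_p)
    M = monodromy(x_p, sigma, period_schedule, therapy, params, rel_step, solver)
    mults = np.sort(np.abs(np.linalg.eigvals(M)))[::-1]
    if np.all(mults < 1.0 - tol):
        cls = "stable"
    elif np.any(mults > 1.0 + tol):
        cls = "unstable"
    else:
        cls = "marginal"
    return PeriodicResult(
        residual_norm=rnorm,
        monodromy=M,
        multipliers=mults,
        classification=cls,
        fixed_point_ok=bool(rnorm <= residual_threshold),
    )


def refine_fixed_point(
    x0,
    sigma: float,
    period_schedule,
    therapy: TherapyConfig,
    params: ModelParams,
    n_iter: int = 5,
    solver: SolverSettings | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Newton iteration on ``F(x) - x = 0`` with the finite-difference Jacobian.

    Returns the refined state and the scaled residual-norm history
    (including the starting residual).  Iterates are clipped to the
    nonnegative cone.
    """
    x = np.asarray(x0, dtype=float).copy()
    history = []
    res = periodic_residual(x, sigma, period_schedule, therapy, params, solver)
    history.append(residual_norm(res, x))
    for _ in range(n_iter):
        M = monodromy(x, sigma, period_schedule, therapy, params, solver=solver)
        try:
            delta = np.linalg.solve(M - np.eye(N_STATES), -res)
        except np.linalg.LinAlgError:
            break
        x = np.maximum(x + delta, 0.0)
        res = periodic_residual(x, sigma, period_schedule, therapy, params, solver)
        history.append(residual_norm(res, x))
    return x, history
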