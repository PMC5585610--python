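"""Core vector field of the murine tumor–immune interaction model.

Eight coupled ordinary differential equations describe a melanoma-bearing
mouse under dendritic-cell (DC) immunotherapy:

* ``T``       tumor cells, growing by a Gompertz law with carrying capacity
              ``K_T`` and killed by cytotoxic CD8 T cells.  The kill term is
              modulated by two Michaelis–Menten factors: the density of MHC
              class-1 receptors on the melanoma cells (recognition) and the
              immunosuppressive cytokine TGF-beta.
* ``H``       CD4 helper T cells, activated by antigen-loaded DCs
              (logistic proliferation, normalized carrying capacity).
* ``C``       CD8 cytotoxic T cells, driven by interleukin-2 rather than by
              the injected DCs directly (the vaccine transfers antigen; it
              does not prime CD8 cells itself).
* ``D``       antigen-loaded dendritic cells, subject only to exponential
              decay between injections; bolus injections enter as impulsive
              jumps handled outside this module.
* ``I``       interleukin-2, produced by DC–CD4 interaction and consumed by
              CD8 cells.
* ``F_beta``  TGF-beta, secreted proportionally to tumor mass.
* ``F_gamma`` IFN-gamma, secreted by CD8 cells; upregulates MHC class 1.
* ``M_I``     MHC class-1 receptors per melanoma cell.

The vector field here is the *autonomous* part ``f(x)``; the injection
control is a sum of Dirac impulses and lives in :mod:`dctherapy.simulate`.

Units: time in hours, cell populations in cells (CD4/CD8 are normalized,
carrying capacity 1), cytokines in pg, MHC receptors in receptors/cell.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "ImmuneState",
    "ModelParams",
    "InvalidStateError",
    "rhs",
    "jacobian",
    "gompertz_closed_form",
    "tumor_free_steady_state",
]

#: Coordinate order used by every array in the package.
STATE_NAMES = ("T", "H", "C", "D", "I", "F_beta", "F_gamma", "M_I")
N_STATES = 8

# index constants
IDX_T, IDX_H, IDX_C, IDX_D, IDX_I, IDX_FB, IDX_FG, IDX_MI = range(8)

#: Threshold below which a negative solver excursion is treated as zero.
NEG_CLIP = 1e-9


class InvalidStateError(ValueError):
    """State vector is non-finite or meaningfully negative."""


class ImmuneState(NamedTuple):
    """Named view of the 8-dimensional state (tumor, immune cells, cytokines)."""

    T: float
    H: float
    C: float
    D: float
    I: float
    F_beta: float
    F_gamma: float
    M_I: float

    @classmethod
    def from_array(cls, x) -> "ImmuneState":
        x = np.asarray(x, dtype=float)
        if x.shape != (N_STATES,):
            raise InvalidStateError(f"state must have {N_STATES} coordinates, got shape {x.shape}")
        return cls(*x)

    def to_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and Michaelis constants of the model.

    Defaults are the published murine calibration.  All rates are per hour;
    ``K_T`` is in cells, the CD4/CD8 carrying capacities are normalized to 1,
    cytokine constants in pg.  The injection delay ``tau`` and delivery
    efficiency ``e_f`` are therapy properties and live in
    :class:`dctherapy.simulate.TherapyConfig`.
    """

    # tumor growth and CD8 kill term
    r_T: float = 0.002          # Gompertz growth rate, 1/h
    a_T: float = 0.1136         # max kill efficiency of CD8 cells, 1/h
    K_T: float = 1e12           # tumor carrying capacity, cells
    e_T: float = 50.0           # Michaelis constant of MHC-1 recognition
    # CD4 helper T cells
    a_H: float = 1e-4           # thymic supply, cells/h
    r_H: float = 1.0            # DC-driven proliferation, 1/(cell h)
    K_H: float = 1.0            # carrying capacity (normalized)
    mu_H: float = 0.005         # death rate, 1/h
    # CD8 cytotoxic T cells
    a_C: float = 1e-4           # supply, cells/h
    r_C: float = 4e-7           # IL-2-driven proliferation, 1/(unit h)
    K_C: float = 1.0            # carrying capacity (normalized)
    mu_C: float = 0.005         # death rate, 1/h
    # dendritic cells
    mu_D: float = 0.009625      # DC death rate, 1/h
    # interleukin-2
    r_I: float = 1e-2           # production by DC-CD4 interaction
    mu_IC: float = 1e-7         # uptake by CD8 cells, 1/(cell h)
    mu_I: float = 1e-2          # degradation, 1/h
    # TGF-beta
    r_Tbeta: float = 5.57e-6    # secretion per tumor cell, pg/(cell h)
    mu_beta: float = 6.93       # degradation, 1/h
    a_Tbeta: float = 0.69       # residual kill efficiency under saturating TGF-beta
    e_Tbeta: float = 1e4        # Michaelis constant of TGF-beta suppression, pg
    # IFN-gamma
    a_gammaC: float = 1.02e-4   # release per CD8 cell, pg/(cell h)
    mu_gamma: float = 0.102     # degradation, 1/h
    # MHC class 1
    g_Ml: float = 1.44          # basal receptor production, rec/(cell h)
    a_Mlgamma: float = 2.89     # max IFN-gamma-driven production, rec/(cell h)
    e_Mlgamma: float = 3.38e5   # Michaelis constant, pg
    mu_Ml: float = 0.0144       # receptor degradation, 1/h

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"parameter {f.name} must be a finite number, got {v!r}")
            if v <= 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown model parameter(s): {', '.join(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


def _validate_state(x: np.ndarray) -> None:
    if x.shape != (N_STATES,):
        raise InvalidStateError(f"state must have {N_STATES} coordinates, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidStateError(f"non-finite state: {x}")
    if x[IDX_T] < -NEG_CLIP:
        raise InvalidStateError(f"negative tumor coordinate T={x[IDX_T]}")


def rhs(x, p: ModelParams, *, check: bool = True) -> np.ndarray:
    """Autonomous vector field ``f(x)``.

    The Gompertz term ``r_T T log(K_T/T)`` is defined as 0 at ``T = 0`` (its
    continuous limit), so the tumor-free hyperplane is invariant.  Tiny
    negative solver excursions of ``T`` (magnitude below 1e-9) are treated
    as 0.

    Parameters
    ----------
    x : array-like, shape (8,)
        State in the order ``(T, H, C, D, I, F_beta, F_gamma, M_I)``.
    p : ModelParams
    check : bool
        Validate finiteness/nonnegativity of ``T``.  Internal integrators
        disable this on the hot path.
    """
    x = np.asarray(x, dtype=float)
    if check:
        _validate_state(x)
    T, H, C, D, I, Fb, Fg, Mi = x

    Tc = T if T > 0.0 else 0.0
    # log(K_T) - log(T) stays finite for any positive double; K_T/T can overflow
    gompertz = p.r_T * Tc * (math.log(p.K_T) - math.log(Tc)) if Tc > 0.0 else 0.0
    mhc_sat = Mi / (p.e_T + Mi)
    beta_sup = (p.a_Tbeta * Fb + p.e_Tbeta) / (p.e_Tbeta + Fb)
    dT = gompertz - p.a_T * C * Tc * mhc_sat * beta_sup

    dH = p.a_H + p.r_H * D * H * (1.0 - H / p.K_H) - p.mu_H * H
    dC = p.a_C + p.r_C * I * C * (1.0 - C / p.K_C) - p.mu_C * C
    dD = -p.mu_D * D
    dI = -p.mu_IC * C * I + p.r_I * D * H - p.mu_I * I
    dFb = p.r_Tbeta * Tc - p.mu_beta * Fb
    dFg = p.a_gammaC * C - p.mu_gamma * Fg
    dMi = p.a_Mlgamma * Fg / (p.e_Mlgamma + Fg) + p.g_Ml - p.mu_Ml * Mi
    return np.array([dT, dH, dC, dD, dI, dFb, dFg, dMi])


def jacobian(x, p: ModelParams) -> np.ndarray:
    """Analytic Jacobian ``D_x f(x)`` of :func:`rhs`.

    Requires ``T > 0``: the derivative of the Gompertz term,
    ``r_T (log(K_T/T) - 1)``, diverges logarithmically as ``T -> 0``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (N_STATES,):
        raise InvalidStateError(f"state must have {N_STATES} coordinates, got shape {x.shape}")
    T, H, C, D, I, Fb, Fg, Mi = x
    if T <= 0.0:
        raise ValueError("jacobian requires T > 0 (Gompertz derivative is singular at T = 0)")

    J = np.zeros((N_STATES, N_STATES))
    mhc_sat = Mi / (p.e_T + Mi)
    beta_sup = (p.a_Tbeta * Fb + p.e_Tbeta) / (p.e_Tbeta + Fb)
    # d(beta_sup)/dFb and d(mhc_sat)/dMi
    dbeta = p.e_Tbeta * (p.a_Tbeta - 1.0) / (p.e_Tbeta + Fb) ** 2
    dmhc = p.e_T / (p.e_T + Mi) ** 2

    J[IDX_T, IDX_T] = p.r_T * (math.log(p.K_T) - math.log(T) - 1.0) - p.a_T * C * mhc_sat * beta_sup
    J[IDX_T, IDX_C] = -p.a_T * T * mhc_sat * beta_sup
    J[IDX_T, IDX_FB] = -p.a_T * C * T * mhc_sat * dbeta
    J[IDX_T, IDX_MI] = -p.a_T * C * T * dmhc * beta_sup

    J[IDX_H, IDX_H] = p.r_H * D * (1.0 - 2.0 * H / p.K_H) - p.mu_H
    J[IDX_H, IDX_D] = p.r_H * H * (1.0 - H / p.K_H)

    J[IDX_C, IDX_C] = p.r_C * I * (1.0 - 2.0 * C / p.K_C) - p.mu_C
    J[IDX_C, IDX_I] = p.r_C * C * (1.0 - C / p.K_C)

    J[IDX_D, IDX_D] = -p.mu_D

    J[IDX_I, IDX_C] = -p.mu_IC * I
    J[IDX_I, IDX_I] = -p.mu_IC * C - p.mu_I
    J[IDX_I, IDX_D] = p.r_I * H
    J[IDX_I, IDX_H] = p.r_I * D

    J[IDX_FB, IDX_T] = p.r_Tbeta
    J[IDX_FB, IDX_FB] = -p.mu_beta

    J[IDX_FG, IDX_C] = p.a_gammaC
    J[IDX_FG, IDX_FG] = -p.mu_gamma

    J[IDX_MI, IDX_FG] = p.a_Mlgamma * p.e_Mlgamma / (p.e_Mlgamma + Fg) ** 2
    J[IDX_MI, IDX_MI] = -p.mu_Ml
    return J


def gompertz_closed_form(T0: float, t, p: ModelParams):
    """Exact solution of the isolated Gompertz equation ``T' = r_T T log(K_T/T)``.

    ``T(t) = K_T exp(log(T0/K_T) exp(-r_T t))`` — monotone approach to the
    carrying capacity ``K_T`` from below when ``T0 < K_T``.  Accepts scalar
    or array ``t`` (hours).
    """
    if T0 <= 0:
        raise ValueError(f"T0 must be positive, got {T0}")
    t = np.asarray(t, dtype=float)
    out = p.K_T * np.exp(np.log(T0 / p.K_T) * np.exp(-p.r_T * t))
    return float(out) if out.ndim == 0 else out


def tumor_free_steady_state(p: ModelParams) -> np.ndarray:
    """Closed-form tumor-free equilibrium.

    With ``T = D = 0`` the system decouples: ``H* = a_H/mu_H``,
    ``C* = a_C/mu_C``, ``I* = F_beta* = 0``,
    ``F_gamma* = a_gammaC C*/mu_gamma`` and ``M_I*`` balances basal plus
    IFN-gamma-driven production against degradation.
    """
    H = p.a_H / p.mu_H
    C = p.a_C / p.mu_C
    Fg = p.a_gammaC * C / p.mu_gamma
    Mi = (p.a_Mlgamma * Fg / (p.e_Mlgamma + Fg) + p.g_Ml) / p.mu_Ml
    return np.array([0.0, H, C, 0.0, 0.0, 0.0, Fg, Mi])
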