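"""User/non-user compartment dynamics of lexical spread.

A word (or any cultural constituent) is modelled like an endemic pathogen
in a susceptible-infectious-susceptible (SIS) population: non-users adopt
the word from users at a propagation rate ``beta``, users abandon it at
rate ``gamma``, and turnover of the speaker population happens at the
mortality rate ``mu`` (one generation lasts ``1/mu`` years).  With the
user fraction ``u`` and non-user fraction ``n = 1 - u`` the dynamics are

    du/dt = beta * u * (1 - u) - (gamma + mu) * u

The basic reproductive ratio is ``R0 = beta / (gamma + mu)``: the expected
number of non-users that acquire the word from a single user over the
user's whole prolific period.  The word spreads iff ``R0 > 1``, in which
case the user fraction approaches the endemic equilibrium
``U* = 1 - 1/R0`` along a logistic curve with intrinsic growth rate
``r = beta - gamma - mu``.

All rates are per year; times are years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "ModelState",
    "Thresholds",
    "r0_from_params",
    "equilibrium_user_fraction",
    "intrinsic_growth_rate",
    "simulate_ode",
    "logistic_solution",
    "herd_immunity_threshold",
    "thresholds_from_params",
]

#: drift tolerance for the post-hoc [0, 1] clipping of ODE solutions
_CLIP_TOL = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """Rates of the user/non-user model (per year).

    beta
        Rate of successful propagation of the constituent per contact
        structure unit; must be positive.
    gamma
        Rate of abandoning (forgetting) the constituent; nonnegative.
        Empirically, forgetting of established words is negligible, so 0
        is the conventional default elsewhere in the package.
    mu
        Mortality (population turnover) rate; ``1/mu`` is one generation.
    """

    beta: float
    gamma: float
    mu: float

    def __post_init__(self) -> None:
        for name in ("beta", "gamma", "mu"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.mu <= 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


@dataclass(frozen=True)
class ModelState:
    """Population state at time ``t``: user fraction ``u``, non-users ``n``."""

    u: float
    n: float
    t: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.u <= 1 + 1e-9:
            raise ValueError(f"u must lie in [0, 1], got {self.u}")
        if abs(self.u + self.n - 1.0) > 1e-9:
            raise ValueError("u + n must equal 1 within 1e-9")


@dataclass(frozen=True)
class Thresholds:
    """Derived threshold quantities of one parameterization.

    ``h`` is the herd-immunity / stability threshold ``1 - 1/R0``: the
    minimum fraction of the population that must be blocked from adoption
    for the constituent to die out.  At the endemic equilibrium it equals
    the equilibrium user fraction ``u_star``.
    """

    r0: float
    u_star: float
    h: float


def r0_from_params(params: ModelParams) -> float:
    """Basic reproductive ratio ``R0 = beta / (gamma + mu)``."""
    denom = params.gamma + params.mu
    if denom <= 0:
        raise ValueError("gamma + mu must be positive")
    return params.beta / denom


def equilibrium_user_fraction(params: ModelParams) -> float:
    """Endemic equilibrium ``U* = 1 - (gamma + mu)/beta``, clamped at 0.

    Below criticality (``R0 <= 1``) the only stable equilibrium is the
    constituent-free state ``U* = 0``.
    """
    return max(0.0, 1.0 - (params.gamma + params.mu) / params.beta)


def intrinsic_growth_rate(params: ModelParams) -> float:
    """Early-phase exponential growth rate ``r = beta - gamma - mu``."""
    return params.beta - params.gamma - params.mu


def herd_immunity_threshold(r0: float) -> float:
    """Herd-immunity / stability threshold ``H = 1 - 1/R0``.

    Clamped at 0 for ``R0 <= 1`` (a subcritical constituent vanishes on
    its own; no blocking is needed).  Raises for nonpositive ``r0``.
    """
    if r0 <= 0:
        raise ValueError(f"r0 must be positive, got {r0}")
    return max(0.0, 1.0 - 1.0 / r0)


def thresholds_from_params(params: ModelParams) -> Thresholds:
    """Bundle R0, equilibrium user fraction and herd threshold."""
    r0 = r0_from_params(params)
    return Thresholds(
        r0=r0,
        u_star=equilibrium_user_fraction(params),
        h=herd_immunity_threshold(r0),
    )


def simulate_ode(
    params: ModelParams,
    u0: float,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> list[ModelState]:
    """Integrate the user-fraction ODE on ``t_grid``.

    Uses an adaptive, stiffness-capable integrator (LSODA).  The solution
    is clipped to [0, 1] afterwards; drift beyond 1e-6 outside that
    interval raises, as it indicates an integrator failure rather than
    roundoff.

    Parameters
    ----------
    u0
        Initial user fraction in [0, 1].
    t_grid
        Strictly increasing evaluation times in years.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a nonempty 1-d array")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if not 0.0 <= u0 <= 1.0:
        raise ValueError(f"u0 must lie in [0, 1], got {u0}")

    b, loss = params.beta, params.gamma + params.mu

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        u = y[0]
        return np.array([b * u * (1.0 - u) - loss * u])

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [u0],
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    u = sol.y[0]
    drift = max(0.0, float(np.max(u) - 1.0), float(-np.min(u)))
    if drift > _CLIP_TOL:
        raise RuntimeError(f"solution left [0, 1] by {drift:.3g} (> {_CLIP_TOL:g})")
    u = np.clip(u, 0.0, 1.0)
    return [ModelState(u=ui, n=1.0 - ui, t=ti) for ui, ti in zip(u, t_grid)]


def logistic_solution(u0: float, u_star: float, r: float, t) -> np.ndarray | float:
    """Closed-form logistic solution of the user-fraction ODE.

    ``U(t) = U* / (1 + (U*/U0 - 1) * exp(-r t))`` where ``U*`` is the
    carrying capacity ``1 - 1/R0`` and ``r = beta - gamma - mu``.  Equals
    ``u0`` at ``t = 0`` and approaches ``u_star`` as ``t`` grows for
    ``r > 0``.

    ``t`` may be a scalar or array (years); the return type matches.
    """
    if u0 <= 0:
        raise ValueError("closed form undefined for u0 <= 0")
    if u_star <= 0:
        raise ValueError("u_star must be positive")
    t = np.asarray(t, dtype=float)
    out = u_star / (1.0 + (u_star / u0 - 1.0) * np.exp(-r * t))
    return float(out) if out.ndim == 0 else out
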