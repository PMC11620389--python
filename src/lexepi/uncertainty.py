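"""Margins of error for the R0 estimators.

All margins are halves of 95% confidence intervals.  The input margins
are standard first-order quantities: for age-of-acquisition ratings,
``1.96 * sd / sqrt(N_AoA)``; for survey prevalence, the binomial
``1.96 * sqrt(p(1-p)/N_p)``; life expectancy's margin comes from
demographic data as a config value.

The estimator margins propagate these through the first-order Taylor
expansion (delta method) of each closed form:

    R0 = LE/AoA       ->  sqrt((dLE/AoA)^2 + (LE*dAoA/AoA^2)^2)
    R0 = 1/(1-p)      ->  dp/(1-p)^2
    R0 = 1 + r*L      ->  sqrt((L*dr)^2 + r^2*(dLE^2 + dAoA^2)),  L = LE-AoA

The growth rate ``r`` has no closed form, so its margin is bootstrapped:
for each replicate, binomial counts are drawn around the reconstructed
prevalence trajectory at the survey sample size, the logistic model is
refitted, and the margin is half the width of the percentile 95%
interval of the replicate rates.  Corpus frequencies are treated as
error-free (the corpora are large enough that their sampling error is
negligible next to the survey error).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .trajectories import Trajectory, fit_logistic
from .estimators import Demography

__all__ = [
    "MarginInputs",
    "moe_aoa_ratings",
    "moe_prevalence",
    "moe_r0_aoa",
    "moe_r0_prevalence",
    "moe_r0_growth",
    "bootstrap_delta_r",
    "item_rng",
]


@dataclass(frozen=True)
class MarginInputs:
    """95% margins of error of the four underlying estimates."""

    delta_le: float
    delta_aoa: float
    delta_p: float
    delta_r: float

    def __post_init__(self) -> None:
        for name in ("delta_le", "delta_aoa", "delta_p", "delta_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def moe_aoa_ratings(aoa_sd: float, n_aoa: int) -> float:
    """Margin of the mean AoA rating: ``1.96 * sd / sqrt(N_AoA)``."""
    if n_aoa < 1:
        raise ValueError("n_aoa must be >= 1")
    return 1.96 * aoa_sd / math.sqrt(n_aoa)


def moe_prevalence(p: float, n_p: int) -> float:
    """Binomial margin of survey prevalence: ``1.96 * sqrt(p(1-p)/N_p)``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    return 1.96 * math.sqrt(p * (1.0 - p) / n_p)


def moe_r0_aoa(demo: Demography, aoa: float, delta_aoa: float) -> float:
    """Delta-method margin of ``R0 = LE/AoA``."""
    if aoa <= 0:
        raise ValueError("aoa must be positive")
    return math.sqrt(
        (demo.delta_le / aoa) ** 2 + (demo.le * delta_aoa / aoa**2) ** 2
    )


def moe_r0_prevalence(p: float, delta_p: float) -> float:
    """Delta-method margin of ``R0 = 1/(1-p)``; diverges as p -> 1."""
    if p >= 1.0:
        raise ValueError("margin undefined at p = 1")
    return delta_p / (1.0 - p) ** 2


def moe_r0_growth(
    r: float, delta_r: float, demo: Demography, aoa: float, delta_aoa: float
) -> float:
    """Delta-method margin of ``R0 = 1 + r*(LE - AoA)``."""
    if aoa >= demo.le:
        raise ValueError("aoa must be below le")
    span = demo.le - aoa
    return math.sqrt(
        (span * delta_r) ** 2 + r**2 * (demo.delta_le**2 + delta_aoa**2)
    )


def item_rng(seed: int, item_id: str) -> np.random.Generator:
    """Deterministic per-item random stream derived from a master seed.

    Uses a CRC32 of the item id so that streams are reproducible across
    runs and independent of iteration order.
    """
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(item_id.encode())])
    )


def bootstrap_delta_r(
    traj: Trajectory,
    n_p: int,
    n_boot: int = 300,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """Bootstrap margin of the logistic growth rate.

    For each replicate, a count ``Binomial(n_p, U(t))`` is drawn
    independently at every time point, the proportion trajectory is
    refitted, and the replicate rate collected.  The margin is half the
    width of the percentile [2.5%, 97.5%] interval of the replicate
    rates.  Replicates whose refit fails are dropped and counted in the
    returned ``n_failed``; with more than half the replicates failed the
    margin is unreliable and returned as NaN.
    """
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    u = np.clip(traj.values, 0.0, 1.0)
    if rng is None:
        rng = item_rng(seed, traj.item_id)

    rates: list[float] = []
    n_failed = 0
    for _ in range(n_boot):
        counts = rng.binomial(n_p, u)
        rep = Trajectory(traj.item_id, traj.times, counts / n_p, kind="prevalence")
        fit = fit_logistic(rep, tol=1e-8)  # replicate noise dwarfs optimizer error
        if fit.converged and np.isfinite(fit.r):
            rates.append(fit.r)
        else:
            n_failed += 1
    if n_failed > n_boot // 2:
        return float("nan"), n_failed
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return float((hi - lo) / 2.0), n_failed
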