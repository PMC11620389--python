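"""Per-item estimators of the basic reproductive ratio.

Three routes to R0, each inverting a closed-form identity of the
user/non-user model at (or near) its endemic equilibrium:

``aoa``
    From mean age of acquisition, the linguistic analogue of age at
    first infection in a rectangular age distribution:
    ``R0 = LE / AoA`` with LE the population life expectancy.
``prevalence``
    From equilibrium prevalence, ``R0 = 1 / (1 - p_U)``.
``growth``
    From the fitted logistic growth rate of the reconstructed prevalence
    trajectory, ``R0 = 1 + r * L`` with the prolific period
    ``L = LE - AoA`` (how long an individual carries and can pass on the
    word).  Not computed when ``1 + r*L < 0`` (R0 is nonnegative by
    definition) or when the logistic fit failed.

Estimates that cannot be computed carry a machine-readable reason rather
than being dropped silently.  Margins of error are filled in by the
uncertainty module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ItemNorms",
    "Demography",
    "R0Estimate",
    "r0_from_aoa",
    "r0_from_prevalence",
    "r0_from_growth",
    "r0_from_network",
    "contact_share",
]


@dataclass(frozen=True)
class ItemNorms:
    """Survey-side norms for one item.

    ``aoa_mean``/``aoa_sd``/``n_aoa`` summarize subjective
    age-of-acquisition ratings averaged over raters; ``p_u`` is survey
    prevalence (fraction of respondents knowing the item) over ``n_p``
    respondents.
    """

    item_id: str
    aoa_mean: float
    aoa_sd: float
    n_aoa: int
    p_u: float
    n_p: int

    def __post_init__(self) -> None:
        if self.aoa_mean <= 0:
            raise ValueError(f"aoa_mean must be > 0, got {self.aoa_mean}")
        if self.aoa_sd < 0:
            raise ValueError(f"aoa_sd must be >= 0, got {self.aoa_sd}")
        if not 0.0 <= self.p_u <= 1.0:
            raise ValueError(f"p_u must lie in [0, 1], got {self.p_u}")
        if self.n_aoa < 1 or self.n_p < 1:
            raise ValueError("rater and respondent counts must be >= 1")


@dataclass(frozen=True)
class Demography:
    """Population life expectancy ``le`` (years) and its 95% margin."""

    le: float = 75.0
    delta_le: float = 1.0

    def __post_init__(self) -> None:
        if self.le <= 0:
            raise ValueError(f"le must be > 0, got {self.le}")
        if self.delta_le < 0:
            raise ValueError(f"delta_le must be >= 0, got {self.delta_le}")


@dataclass
class R0Estimate:
    """One estimator's value for one item.

    ``value`` is None when the estimate could not be computed, in which
    case ``reason`` says why ("fit_failed", "negative_r0",
    "core_prevalence_one", ...).  ``flags`` carry non-fatal notes such
    as "subcritical" when AoA exceeds LE.
    """

    item_id: str
    method: str  # {"aoa", "prevalence", "growth"}
    value: float | None
    moe: float | None = None
    reason: str | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return self.value is not None


def r0_from_aoa(norms: ItemNorms, demo: Demography) -> R0Estimate:
    """R0 from age of acquisition: ``LE / AoA``.

    Items acquired later than the life expectancy would imply R0 < 1;
    the estimate is kept but flagged "subcritical".
    """
    value = demo.le / norms.aoa_mean
    flags = ("subcritical",) if norms.aoa_mean >= demo.le else ()
    return R0Estimate(norms.item_id, "aoa", value, flags=flags)


def r0_from_prevalence(norms: ItemNorms) -> R0Estimate:
    """R0 from equilibrium prevalence: ``1 / (1 - p_U)``.

    A core-lexicon item with ``p_U = 1`` has an infinite estimate and is
    returned as not computable.
    """
    if norms.p_u >= 1.0:
        return R0Estimate(norms.item_id, "prevalence", None,
                          reason="core_prevalence_one")
    return R0Estimate(norms.item_id, "prevalence", 1.0 / (1.0 - norms.p_u))


def r0_from_growth(fit, norms: ItemNorms, demo: Demography) -> R0Estimate:
    """R0 from logistic growth: ``1 + r * (LE - AoA)``.

    Requires a converged fit and AoA below LE.  When ``1 + r*L`` is
    negative the estimate is conceptually invalid (R0 >= 0) and returned
    missing with reason "negative_r0", mirroring the exclusion applied
    in practice.
    """
    if fit is None or not getattr(fit, "converged", False):
        return R0Estimate(norms.item_id, "growth", None, reason="fit_failed")
    if norms.aoa_mean >= demo.le:
        return R0Estimate(norms.item_id, "growth", None, reason="aoa_exceeds_le")
    value = 1.0 + fit.r * (demo.le - norms.aoa_mean)
    if value < 0:
        return R0Estimate(norms.item_id, "growth", None, reason="negative_r0")
    return R0Estimate(norms.item_id, "growth", value)


def r0_from_network(transmissibility: float, mean_k: float, mean_k2: float) -> float:
    """R0 on a contact network: ``T * (<k^2> - <k>) / <k>``.

    ``T`` is the mean probability of transmission per contact event;
    ``mean_k`` and ``mean_k2`` are the mean degree and mean squared
    degree of the network.  Degree heterogeneity (variance
    ``<k^2> - <k>^2``) raises R0 above the homogeneous value.
    """
    if not 0.0 <= transmissibility <= 1.0:
        raise ValueError("transmissibility must lie in [0, 1]")
    if mean_k <= 0:
        raise ValueError("mean degree must be positive")
    if mean_k2 < mean_k**2 - 1e-12:
        raise ValueError(
            f"inconsistent moments: <k^2>={mean_k2} < <k>^2={mean_k**2}"
        )
    return transmissibility * (mean_k2 - mean_k) / mean_k


def contact_share(r0: float, network_size: float) -> float:
    """Fraction of a personal network an innovation is passed to.

    With a mean personal network of ~600 contacts over a lifetime, a
    word with R0 = 6 is successfully passed on to only ~1% of the
    contacts an individual ever has.
    """
    if network_size <= 0:
        raise ValueError("network_size must be positive")
    return r0 / network_size
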