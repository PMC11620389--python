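"""Prevalence-trajectory reconstruction and logistic growth fitting.

Diachronic corpora yield per-word occurrence-frequency trajectories
``f(t)``; surveys yield present-day prevalence ``p_U`` (the fraction of
speakers who know/use the word).  Treating the frequency trajectory as a
mirror of the prevalence trajectory, each word's user-fraction history is
reconstructed as

    U(t) = p_U * f(t) / max_t f(t)

A word counts as a *lexical innovation* when U(t) increased significantly
over the observation period (Spearman rank correlation of value with
time).  For innovations, a three-parameter logistic

    U_hat(t) = a / (1 + b * exp(-r * (t - t0)))

is fitted by nonlinear least squares; its growth rate ``r`` feeds the
growth-based R0 estimator, and the inflection point ``t0 + ln(b)/r``
dates the spurt.  Words whose recent dynamics are flat instead sit at
their endemic equilibrium; the stability coefficient ``S = 1 - |rho|``
(Spearman rho of value vs. time over a recent window, 1950-2000 by
default) quantifies how close to equilibrium a word rests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Trajectory",
    "LogisticFit",
    "StabilityScore",
    "ItemResult",
    "normalize_frequency",
    "prevalence_trajectory",
    "spearman_increase_test",
    "stability",
    "fit_logistic",
    "reconstruct_and_filter",
]


@dataclass(frozen=True)
class Trajectory:
    """A time-indexed series of frequencies or prevalences for one item.

    ``kind`` is ``"frequency"`` (nonnegative, arbitrary scale) or
    ``"prevalence"`` (fractions in [0, 1]).  Times are calendar years,
    strictly increasing, at least three points.
    """

    item_id: str
    times: np.ndarray
    values: np.ndarray
    kind: str = "frequency"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if times.size < 3:
            raise ValueError("a trajectory needs at least 3 time points")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("values must be finite and nonnegative")
        if self.kind not in ("frequency", "prevalence"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.kind == "prevalence" and np.any(values > 1.0 + 1e-12):
            raise ValueError("prevalence values must not exceed 1")


@dataclass(frozen=True)
class LogisticFit:
    """Result of the logistic growth fit.

    ``a`` is the carrying capacity (asymptotic prevalence), ``b`` the
    shape parameter, ``r`` the intrinsic growth rate per year, ``r2`` the
    coefficient of determination ``1 - SSE/SST`` (no floor; negative
    values indicate a fit worse than the mean), ``t_infl`` the inflection
    point in calendar years, ``t0`` the time origin used internally.
    """

    a: float
    b: float
    r: float
    r2: float
    t_infl: float
    t0: float
    converged: bool

    def predict(self, times) -> np.ndarray:
        tau = np.asarray(times, dtype=float) - self.t0
        return self.a / (1.0 + self.b * np.exp(-self.r * tau))


@dataclass(frozen=True)
class StabilityScore:
    """Contemporary stability ``S = 1 - |rho|`` over a recent window.

    ``S`` near 1 means the word's dynamics show no recent trend, i.e.
    rest at their population-dynamic equilibrium — the regime in which
    the prevalence- and acquisition-based R0 estimators are valid.
    """

    s: float
    rho_abs: float
    window: tuple[float, float]


@dataclass
class ItemResult:
    """Per-item outcome of :func:`reconstruct_and_filter`."""

    item_id: str
    included: bool
    reason: str | None = None  # exclusion reason when not included
    prevalence: Trajectory | None = None
    fit: LogisticFit | None = None
    stability: StabilityScore | None = None
    significant_increase: bool | None = None
    spearman_rho: float = float("nan")
    spearman_p: float = float("nan")


def normalize_frequency(traj: Trajectory) -> Trajectory:
    """Scale a frequency trajectory by its maximum so that max = 1."""
    peak = float(np.max(traj.values))
    if peak <= 0:
        raise ValueError(f"cannot normalize all-zero trajectory {traj.item_id!r}")
    return replace(traj, values=traj.values / peak)


def prevalence_trajectory(traj: Trajectory, p_u: float) -> Trajectory:
    """Reconstruct ``U(t) = p_u * f~(t)`` from a frequency trajectory.

    The input is max-normalized first if needed, so the reconstructed
    prevalence peaks exactly at the present-day survey prevalence
    ``p_u``.
    """
    if not 0.0 < p_u < 1.0:
        raise ValueError(f"p_u must lie strictly in (0, 1), got {p_u}")
    norm = normalize_frequency(traj)
    return replace(norm, values=p_u * norm.values, kind="prevalence")


def spearman_increase_test(
    traj: Trajectory, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Spearman rank-correlation trend test of value against time.

    Returns ``(rho, p_value, is_significant_increase)`` where the last
    flag requires both ``p < alpha`` (two-sided) and ``rho > 0``.  A
    constant series has undefined rho and maps to ``(0, 1, False)``.
    """
    if traj.times.size < 4:
        raise ValueError("trend test needs at least 4 time points")
    if np.ptp(traj.values) == 0:
        return 0.0, 1.0, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.spearmanr(traj.times, traj.values)
    rho = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(rho):
        return 0.0, 1.0, False
    return rho, p, bool(p < alpha and rho > 0)


def stability(
    traj: Trajectory, window: tuple[float, float] = (1950.0, 2000.0)
) -> StabilityScore:
    """Stability coefficient ``S = 1 - |rho|`` on points inside ``window``.

    The window is inclusive at both ends.  A constant series in the
    window has undefined rho, treated as 0 (maximal stability).  Raises
    if fewer than 3 points fall inside the window.
    """
    lo, hi = window
    mask = (traj.times >= lo) & (traj.times <= hi)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"only {int(mask.sum())} points in window [{lo}, {hi}] for "
            f"{traj.item_id!r}; need at least 3"
        )
    t, v = traj.times[mask], traj.values[mask]
    if np.ptp(v) == 0:
        rho_abs = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = float(stats.spearmanr(t, v).statistic)
        rho_abs = abs(rho) if np.isfinite(rho) else 0.0
    return StabilityScore(s=1.0 - rho_abs, rho_abs=rho_abs, window=(lo, hi))


# --- logistic fitting ------------------------------------------------------

_A_MIN = 1e-6


def _logistic(tau: np.ndarray, a: float, b: float, r: float) -> np.ndarray:
    return a / (1.0 + b * np.exp(-r * tau))


def _logistic_jac(tau: np.ndarray, a: float, b: float, r: float) -> np.ndarray:
    e = np.exp(-r * tau)
    denom = 1.0 + b * e
    da = 1.0 / denom
    db = -a * e / denom**2
    dr = a * b * tau * e / denom**2
    return np.column_stack([da, db, dr])


def _initial_guess(tau: np.ndarray, u: np.ndarray) -> tuple[float, float, float]:
    """Heuristic start values: a from the observed peak, r and b from a
    logit regression of the interior points.

    The regression ``logit(u/a0) ~ tau`` gives the growth-rate guess
    from its slope and the shape guess from its intercept
    (``b0 = exp(-intercept)``), which stays sane even when the first
    observations are zero.  Falls back to the first positive value for
    b0 when too few interior points exist.
    """
    a0 = min(1.0, 1.05 * float(np.max(u)))
    inner = (u > 0) & (u < a0)
    r0, b0 = 0.01, None
    if int(inner.sum()) >= 2:
        z = np.log(u[inner] / (a0 - u[inner]))
        slope, intercept = np.polyfit(tau[inner], z, 1)
        if np.isfinite(slope) and slope != 0:
            r0 = float(slope)
        if np.isfinite(intercept):
            b0 = float(np.exp(np.clip(-intercept, -30.0, 30.0)))
    if b0 is None:
        u_first = float(u[u > 0][0]) if np.any(u > 0) else a0 / 2
        b0 = float(np.clip(a0 / u_first - 1.0, 1e-6, 1e6))
    return a0, b0, r0


def fit_logistic(traj: Trajectory, tol: float = 1e-10) -> LogisticFit:
    """Fit ``U(t) = a/(1 + b e^{-r(t - t0)})`` by nonlinear least squares.

    ``t0`` is the first observation year; times are passed to the
    optimizer relative to it for conditioning.  Bounds: ``a`` in
    (0, 1], ``b > 0``, ``r`` unconstrained in sign (declining fits are
    allowed; the downstream growth estimator handles negative rates).
    Starts from data-driven initial values with a multi-start over the
    growth-rate guess on failure.  A degenerate (constant) input or a
    fit that never converges is returned with ``converged=False``.

    ``tol`` is passed to the optimizer (xtol/ftol/gtol).  The default is
    tight enough that noiseless logistic data is recovered to ~1e-9;
    bootstrap refits use a looser setting for speed.  Note that
    trajectories still in their near-exponential phase at the last
    observation leave the parameters only weakly identified (a long,
    flat residual valley trading a and b against r) — a limitation of
    growth-based estimation itself, not of the optimizer.
    """
    if traj.times.size < 5:
        raise ValueError("logistic fit needs at least 5 time points")
    if np.any(traj.values > 1.0 + 1e-12):
        raise ValueError("logistic fit expects prevalence values in [0, 1]")
    u = traj.values
    t0 = float(traj.times[0])
    tau = traj.times - t0

    failed = LogisticFit(
        a=float("nan"), b=float("nan"), r=float("nan"),
        r2=float("nan"), t_infl=float("nan"), t0=t0, converged=False,
    )
    if np.ptp(u) == 0:  # constant series: (a, b) not identifiable at r=0
        return failed

    a0, b0, r0 = _initial_guess(tau, u)
    lower = np.array([_A_MIN, 1e-12, -np.inf])
    upper = np.array([1.0, np.inf, np.inf])

    # first start from the data-driven guess; multi-start over the
    # growth-rate guess only when that fails
    popt = None
    for scale in (1.0, 0.5, 2.0):
        p0 = np.clip([a0, b0, r0 * scale], lower, upper)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    _logistic, tau, u, p0=p0, jac=_logistic_jac,
                    bounds=(lower, upper), maxfev=20000,
                    xtol=tol, ftol=tol, gtol=tol,
                )
            break
        except (RuntimeError, ValueError):
            continue
    if popt is None:
        return failed

    a, b, r = popt
    sse = float(np.sum((u - _logistic(tau, *popt)) ** 2))
    sst = float(np.sum((u - u.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    t_infl = t0 + np.log(b) / r if r != 0 else float("nan")
    return LogisticFit(
        a=float(a), b=float(b), r=float(r), r2=r2,
        t_infl=float(t_infl), t0=t0, converged=True,
    )


# --- filtering pipeline ----------------------------------------------------

def _item_prevalence(norm) -> float:
    return float(norm.p_u) if hasattr(norm, "p_u") else float(norm)


def reconstruct_and_filter(
    freq_table: Mapping[str, Trajectory],
    norms: Mapping[str, object],
    alpha: float = 0.05,
    prevalence_cap: float = 0.95,
    stability_window: tuple[float, float] = (1950.0, 2000.0),
    stability_on: str = "frequency",
) -> dict[str, ItemResult]:
    """Reconstruct prevalence trajectories and apply the inclusion filters.

    Filters are applied in order per item: present-day prevalence below
    the core-lexicon cap (strict, default 0.95); a trajectory exists;
    max-normalization and prevalence scaling; reconstructed U(t) <= 1
    everywhere; significant increase (Spearman, two-sided at ``alpha``
    with rho > 0); logistic fit convergence.  Every input item appears in
    the output exactly once with a machine-readable status; the stability
    coefficient is recorded whenever computable, regardless of inclusion.

    ``norms`` maps item id to either a bare prevalence or any object with
    a ``p_u`` attribute.  ``stability_on`` selects whether S is computed
    on the raw frequency trajectory (default, the conventional choice) or
    on the reconstructed prevalence trajectory ("prevalence").
    """
    if stability_on not in ("frequency", "prevalence"):
        raise ValueError("stability_on must be 'frequency' or 'prevalence'")
    out: dict[str, ItemResult] = {}
    for item_id, norm in norms.items():
        res = ItemResult(item_id=item_id, included=False)
        out[item_id] = res
        p_u = _item_prevalence(norm)

        traj = freq_table.get(item_id)
        if traj is not None:
            stab_traj = traj
            try:
                res.stability = stability(stab_traj, stability_window)
            except ValueError:
                res.stability = None

        if not p_u < prevalence_cap:
            res.reason = "core_lexicon"
            continue
        if traj is None:
            res.reason = "no_trajectory"
            continue
        if not 0.0 < p_u < 1.0:
            res.reason = "invalid_prevalence"
            continue

        try:
            prev = prevalence_trajectory(traj, p_u)
        except ValueError:
            res.reason = "degenerate_trajectory"
            continue
        if stability_on == "prevalence":
            try:
                res.stability = stability(prev, stability_window)
            except ValueError:
                res.stability = None
        if np.any(prev.values > 1.0 + 1e-12):
            res.reason = "prevalence_exceeds_one"
            continue

        rho, p_val, significant = spearman_increase_test(prev, alpha=alpha)
        res.spearman_rho, res.spearman_p = rho, p_val
        res.significant_increase = significant
        res.prevalence = prev
        if not significant:
            res.reason = "no_significant_increase"
            continue

        fit = fit_logistic(prev)
        res.fit = fit
        if not fit.converged:
            res.reason = "fit_failed"
            continue

        res.included = True
    return out
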