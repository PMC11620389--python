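"""Synthetic lexica with known ground truth.

Real analyses of this kind combine crowd-sourced age-of-acquisition
norms, survey prevalence, and diachronic corpus frequencies — datasets
that are large, external, and noisy in ways that cannot be inverted to a
known answer.  This module generates lexica whose norm tables and
frequency trajectories have the statistical structure the estimators
assume, with every item's true basic reproductive ratio recorded, so
that the whole pipeline is testable end to end.

Per item, a true ratio R0* is drawn (log-normal, median 6, log-sd 0.5 by
default); the equilibrium identities then fix the survey-side truth:
prevalence ``U* = 1 - 1/R0*`` and age of acquisition ``AoA = LE/R0*``.
*Stable* items sit at their equilibrium throughout; *growing* items
(lexical innovations) follow a logistic prevalence curve whose midpoint
falls uniformly in 1880-1980 and whose rate is the one the growth
estimator inverts, ``r = (R0* - 1)/(LE - AoA)``.  (The strict
compartment-model rate ``beta - gamma - mu`` is also recorded as
``r_model``; the two differ because ``1 + r*(LE - AoA)`` approximates
the prolific period by LE - AoA rather than by one generation.)

Observation noise mirrors the real instruments: survey prevalence is a
binomial proportion over ``n_p`` respondents; AoA is the mean of
``n_aoa`` per-rater ratings with per-item rating sd, truncated to
(0, LE); corpus frequency is the prevalence curve times an arbitrary
per-item scale (log-uniform over [1e-6, 1e-3], exercising normalization
invariance) with optional multiplicative log-normal noise.  All noise
channels can be switched off to obtain exactly invertible data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .model_core import logistic_solution
from .trajectories import Trajectory

__all__ = ["GeneratorConfig", "SyntheticLexicon", "generate_lexicon", "make_worked_example"]

_R0_MIN = 1.05  # rejection bound: equilibrium identities need R0 > 1


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of a synthetic lexicon.

    Defaults emulate a large-survey regime: 300 survey respondents, 30
    AoA raters per item, decade-gridded trajectories 1820-2000, life
    expectancy 75 years, no abandonment (gamma = 0; forgetting of
    established words is negligible).
    """

    n_items: int = 100
    frac_growing: float = 0.5
    r0_median: float = 6.0
    r0_log_sd: float = 0.5
    r0_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None
    le: float = 75.0
    gamma: float = 0.0
    n_p: int = 300
    n_aoa: int = 30
    aoa_sd_range: tuple[float, float] = (1.5, 3.5)
    aoa_sd_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None
    time_start: float = 1820.0
    time_stop: float = 2000.0
    time_step: float = 10.0
    midpoint_range: tuple[float, float] = (1880.0, 1980.0)
    scale_range: tuple[float, float] = (1e-6, 1e-3)
    freq_noise_sd: float = 0.05
    survey_noise: bool = True
    rating_noise: bool = True
    prevalence_from_raters: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if not 0.0 <= self.frac_growing <= 1.0:
            raise ValueError("frac_growing must lie in [0, 1]")
        if self.n_p < 1 or self.n_aoa < 1:
            raise ValueError("counts must be >= 1")
        if self.le <= 0 or self.gamma < 0:
            raise ValueError("le must be > 0 and gamma >= 0")

    def noise_free(self) -> "GeneratorConfig":
        """Copy with every noise channel off (exactly invertible data)."""
        return replace(self, freq_noise_sd=0.0, survey_noise=False,
                       rating_noise=False, prevalence_from_raters=False)

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.time_start, self.time_stop + self.time_step / 2,
                         self.time_step)


@dataclass
class SyntheticLexicon:
    """Generated norms, trajectories, and the ground truth behind them."""

    norms: pd.DataFrame        # item_id, aoa_mean, aoa_sd, n_aoa, prevalence, n_p
    trajectories: dict[str, Trajectory]
    truth: pd.DataFrame        # item_id, r0_true, r_true, r_model, u_star, ...
    config: GeneratorConfig | None = None

    def trajectory_frame(self) -> pd.DataFrame:
        """Long-form (item_id, year, frequency) table of all trajectories."""
        rows = [
            pd.DataFrame({"item_id": t.item_id, "year": t.times, "frequency": t.values})
            for t in self.trajectories.values()
        ]
        return pd.concat(rows, ignore_index=True)

    def write_csvs(self, out_dir) -> dict[str, Path]:
        """Write norms, long trajectories, and truth tables as CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "norms": out / "norms.csv",
            "trajectories": out / "trajectories.csv",
            "truth": out / "truth.csv",
        }
        self.norms.to_csv(paths["norms"], index=False)
        self.trajectory_frame().to_csv(paths["trajectories"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _draw_r0(cfg: GeneratorConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    sampler = cfg.r0_sampler
    if sampler is None:
        def sampler(r, size):  # noqa: ANN001 - local default law
            return r.lognormal(np.log(cfg.r0_median), cfg.r0_log_sd, size)
    r0 = np.asarray(sampler(rng, n), dtype=float)
    bad = r0 <= _R0_MIN
    tries = 0
    while np.any(bad):
        if tries == 0:
            warnings.warn(
                f"{int(bad.sum())} R0 draws at or below {_R0_MIN}; resampling "
                "(equilibrium identities require supercritical items)",
                stacklevel=3,
            )
        r0[bad] = np.asarray(sampler(rng, int(bad.sum())), dtype=float)
        bad = r0 <= _R0_MIN
        tries += 1
        if tries > 1000:
            raise ValueError("r0_law places too much mass below criticality")
    return r0


def _truncated_ratings(
    rng: np.random.Generator, mean: float, sd: float, n: int, upper: float
) -> np.ndarray:
    """Normal ratings truncated to (0, upper) by resampling."""
    x = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = (x <= 0) | (x >= upper)
        if not np.any(bad):
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(x, 1e-3, upper - 1e-3)


def generate_lexicon(cfg: GeneratorConfig) -> SyntheticLexicon:
    """Generate a synthetic lexicon under ``cfg``; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_items
    times = cfg.time_grid
    t_final = times[-1]

    r0 = _draw_r0(cfg, rng, n)
    u_star = 1.0 - 1.0 / r0
    aoa_true = cfg.le / r0
    mu = 1.0 / cfg.le
    beta = r0 * (cfg.gamma + mu)
    r_model = beta - cfg.gamma - mu
    # rate the growth estimator inverts exactly: 1 + r*(LE - AoA) = R0*
    r_growth = (r0 - 1.0) / (cfg.le - aoa_true)

    n_grow = int(round(cfg.frac_growing * n))
    is_growing = np.zeros(n, dtype=bool)
    is_growing[rng.permutation(n)[:n_grow]] = True
    midpoint = np.where(
        is_growing, rng.uniform(*cfg.midpoint_range, n), np.nan
    )

    if cfg.aoa_sd_sampler is not None:
        aoa_sd_true = np.asarray(cfg.aoa_sd_sampler(rng, n), dtype=float)
    else:
        aoa_sd_true = rng.uniform(*cfg.aoa_sd_range, n)

    lo, hi = np.log(cfg.scale_range[0]), np.log(cfg.scale_range[1])
    scales = np.exp(rng.uniform(lo, hi, n))

    width = int(np.ceil(np.log10(max(n, 2))))
    ids = [f"item{idx:0{width}d}" for idx in range(n)]

    trajectories: dict[str, Trajectory] = {}
    norm_rows, truth_rows = [], []
    for i, item_id in enumerate(ids):
        if is_growing[i]:
            u_t = u_star[i] / (1.0 + np.exp(-r_growth[i] * (times - midpoint[i])))
            r_true = float(r_growth[i])
        else:
            u_t = np.full_like(times, u_star[i])
            r_true = 0.0
        u_final = float(u_t[-1])

        freq = scales[i] * u_t
        if cfg.freq_noise_sd > 0:
            freq = freq * rng.lognormal(0.0, cfg.freq_noise_sd, times.size)
        trajectories[item_id] = Trajectory(item_id, times, freq, kind="frequency")

        n_aoa_eff = cfg.n_aoa
        if cfg.prevalence_from_raters:
            # prevalence observed as the fraction of raters able to rate
            n_respond = int(rng.binomial(cfg.n_p, u_final))
            p_obs = n_respond / cfg.n_p
            n_aoa_eff = max(1, min(cfg.n_aoa, n_respond))
        elif cfg.survey_noise:
            p_obs = rng.binomial(cfg.n_p, u_final) / cfg.n_p
        else:
            p_obs = u_final

        if cfg.rating_noise:
            ratings = _truncated_ratings(
                rng, aoa_true[i], aoa_sd_true[i], n_aoa_eff, cfg.le
            )
            aoa_obs = float(ratings.mean())
            aoa_sd_obs = float(ratings.std(ddof=1)) if n_aoa_eff > 1 else 0.0
        else:
            aoa_obs = float(aoa_true[i])
            aoa_sd_obs = float(aoa_sd_true[i])

        norm_rows.append(
            dict(item_id=item_id, aoa_mean=aoa_obs, aoa_sd=aoa_sd_obs,
                 n_aoa=n_aoa_eff, prevalence=p_obs, n_p=cfg.n_p)
        )
        truth_rows.append(
            dict(item_id=item_id, r0_true=float(r0[i]), r_true=r_true,
                 r_model=float(r_model[i]), beta=float(beta[i]),
                 u_star=float(u_star[i]), aoa_true=float(aoa_true[i]),
                 u_final=u_final, is_growing=bool(is_growing[i]),
                 midpoint=float(midpoint[i]))
        )

    return SyntheticLexicon(
        norms=pd.DataFrame(norm_rows),
        trajectories=trajectories,
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )


def make_worked_example() -> SyntheticLexicon:
    """A fixed 4-item fixture used in the documentation and tests.

    The "growing" item follows the closed-form logistic with U(0)=0.25,
    carrying capacity 0.75 and intrinsic rate 3 in the fixture's own
    time unit (so one unit spans most of the S-curve); "declining" falls
    from near capacity; "stable" is flat at its equilibrium; "core" has
    survey prevalence 0.97 and is caught by the periphery filter.
    Trajectories are noise-free frequencies on times 0..4.
    """
    times = np.linspace(0.0, 4.0, 17)
    u_grow = logistic_solution(0.25, 0.75, 3.0, times)
    u_decl = logistic_solution(0.70, 0.05, 2.0, times)  # falls toward 0.05
    u_stab = np.full_like(times, 0.6)
    u_core = np.full_like(times, 0.97)

    trajectories = {
        "growing": Trajectory("growing", times, 2e-4 * u_grow),
        "declining": Trajectory("declining", times, 5e-5 * u_decl),
        "stable": Trajectory("stable", times, 1e-4 * u_stab),
        "core": Trajectory("core", times, 8e-4 * u_core),
    }
    norms = pd.DataFrame(
        [
            dict(item_id="growing", aoa_mean=12.5, aoa_sd=2.0, n_aoa=30,
                 prevalence=float(u_grow[-1]), n_p=300),
            dict(item_id="declining", aoa_mean=30.0, aoa_sd=3.0, n_aoa=30,
                 prevalence=float(u_decl[-1]), n_p=300),
            dict(item_id="stable", aoa_mean=18.75, aoa_sd=2.5, n_aoa=30,
                 prevalence=0.6, n_p=300),
            dict(item_id="core", aoa_mean=5.0, aoa_sd=1.0, n_aoa=30,
                 prevalence=0.97, n_p=300),
        ]
    )
    truth = pd.DataFrame(
        [
            dict(item_id="growing", r0_true=4.0, r_true=3.0, u_star=0.75,
                 is_growing=True),
            dict(item_id="declining", r0_true=np.nan, r_true=-2.0,
                 u_star=0.05, is_growing=False),
            dict(item_id="stable", r0_true=2.5, r_true=0.0, u_star=0.6,
                 is_growing=False),
            dict(item_id="core", r0_true=np.nan, r_true=0.0, u_star=0.97,
                 is_growing=False),
        ]
    )
    return SyntheticLexicon(norms=norms, trajectories=trajectories, truth=truth)
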