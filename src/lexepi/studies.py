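"""Reference simulation studies.

Self-contained, seeded experiments that exercise the whole pipeline
against generator ground truth: estimator recovery on a synthetic
lexicon, and frequentist coverage of the bootstrap margin for the
logistic growth rate.  These are the package's standing answer to "does
the machinery, run end to end, give back what was put in?" and they back
both the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline_io import RunConfig, run_pipeline
from .synthetic_data import GeneratorConfig, generate_lexicon
from .trajectories import Trajectory, fit_logistic
from .uncertainty import bootstrap_delta_r, item_rng

__all__ = ["RecoveryResult", "CoverageResult", "recovery_study", "coverage_study"]


@dataclass(frozen=True)
class RecoveryResult:
    """Per-method medians against the generating truth."""

    median_est: dict[str, float]     # method -> median estimate
    median_truth: dict[str, float]   # method -> median true R0 of same items
    ratio: dict[str, float]          # method -> median_est / median_truth
    method_gap: float                # |median R0_growth - median R0_prev|
    gap_relative: float              # ... relative to the median true R0
    n_items: int


@dataclass(frozen=True)
class CoverageResult:
    coverage: float
    n_items: int
    n_p: int
    n_boot: int


def recovery_study(n_items: int = 500, seed: int = 0) -> RecoveryResult:
    """Run the full pipeline on a default-noise lexicon and compare each
    estimator's median with the median true R0 of the items it covered.

    The growth estimator only exists for lexical innovations (growing
    items), so each method is judged against the truth of its own item
    set; the cross-method gap compares the growth and prevalence
    medians on the scale of the overall true median.
    """
    lex = generate_lexicon(GeneratorConfig(n_items=n_items, seed=seed))
    report = run_pipeline(lex.norms, lex.trajectories, RunConfig(n_boot=0, seed=seed))
    truth = lex.truth.set_index("item_id")["r0_true"]

    ok = report.estimates[report.estimates.status == "ok"]
    wide = ok.pivot(index="item_id", columns="method", values="value")
    median_est, median_truth, ratio = {}, {}, {}
    for method in ("aoa", "prevalence", "growth"):
        s = wide[method].dropna()
        median_est[method] = float(s.median())
        median_truth[method] = float(truth.loc[s.index].median())
        ratio[method] = median_est[method] / median_truth[method]

    gap = abs(median_est["growth"] - median_est["prevalence"])
    return RecoveryResult(
        median_est=median_est,
        median_truth=median_truth,
        ratio=ratio,
        method_gap=gap,
        gap_relative=gap / float(truth.median()),
        n_items=n_items,
    )


def coverage_study(
    n_items: int = 200, n_p: int = 300, n_boot: int = 100, seed: int = 0
) -> CoverageResult:
    """Frequentist coverage of the bootstrap growth-rate margin.

    Draws growing items with known rates, observes each trajectory as
    binomial survey proportions ``B(n_p, U(t))/n_p`` — the noise process
    the bootstrap itself models — fits the logistic, and checks how
    often ``r_hat +/- delta_r`` contains the generating rate.  Nominal
    coverage is 95%.
    """
    cfg = GeneratorConfig(n_items=n_items, frac_growing=1.0, seed=seed).noise_free()
    lex = generate_lexicon(cfg)
    truth = lex.truth.set_index("item_id")
    hits = 0
    total = 0
    for item_id, traj in lex.trajectories.items():
        r_true = float(truth.loc[item_id, "r_true"])
        u_star = float(truth.loc[item_id, "u_star"])
        mid = float(truth.loc[item_id, "midpoint"])
        u_true = u_star / (1.0 + np.exp(-r_true * (traj.times - mid)))
        rng = item_rng(seed, f"coverage-{item_id}")
        u_obs = rng.binomial(n_p, u_true) / n_p
        prev = Trajectory(item_id, traj.times, u_obs, kind="prevalence")
        fit = fit_logistic(prev)
        if not fit.converged:
            continue
        delta_r, _ = bootstrap_delta_r(prev, n_p, n_boot=n_boot, seed=seed)
        if not np.isfinite(delta_r):
            continue
        total += 1
        hits += bool(fit.r - delta_r <= r_true <= fit.r + delta_r)
    return CoverageResult(
        coverage=hits / total, n_items=total, n_p=n_p, n_boot=n_boot
    )
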