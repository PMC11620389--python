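"""End-to-end pipeline: ingestion, validation, estimation, reporting.

Reads a per-item norm table (age-of-acquisition summary, survey
prevalence, sample sizes) and per-item frequency trajectories, runs the
filtering and estimation stages in order, and produces a report with
per-method estimates and margins, exclusion bookkeeping, paired
comparisons, correlations, and the stability-interaction regressions.

Input schemas
-------------
norms CSV
    ``item_id, aoa_mean, aoa_sd, n_aoa, prevalence, n_p``
trajectory CSV, long form
    ``item_id, year, frequency``
trajectory CSV, wide form
    ``item_id`` plus one column per year (numeric headers); the dialect
    is auto-detected from the header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import association, estimators, trajectories, uncertainty
from .estimators import Demography, ItemNorms, R0Estimate
from .synthetic_data import SyntheticLexicon
from .trajectories import ItemResult, Trajectory

logger = logging.getLogger("lexepi")

__all__ = [
    "RunConfig",
    "RunReport",
    "ValidationIssue",
    "read_norms",
    "read_trajectories",
    "validate_inputs",
    "run_pipeline",
    "run_pipeline_from_files",
]

NORM_COLUMNS = ("item_id", "aoa_mean", "aoa_sd", "n_aoa", "prevalence", "n_p")
METHODS = ("aoa", "prevalence", "growth")


@dataclass(frozen=True)
class RunConfig:
    """Settings of one pipeline run (one language/dataset)."""

    demography: Demography = field(default_factory=Demography)
    prevalence_cap: float = 0.95
    stability_window: tuple[float, float] = (1950.0, 2000.0)
    stability_on: str = "frequency"
    alpha: float = 0.05
    n_boot: int = 300  # 0 disables the bootstrap stage
    seed: int = 0
    es_norm: str = "sqrt"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_cap <= 1.0:
            raise ValueError("prevalence_cap must lie in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")


@dataclass(frozen=True)
class ValidationIssue:
    file: str
    row: object  # row index or None for file-level issues
    column: str | None
    message: str


@dataclass
class RunReport:
    """Everything one run computed, plus the exclusion ledger."""

    estimates: pd.DataFrame       # item_id, method, value, moe, status, reason
    item_status: pd.DataFrame     # item_id, included, reason, stability, fit columns
    counts: pd.DataFrame          # per-method computed / missing counts
    summaries: pd.DataFrame       # per-method median, IQR of value and moe
    comparisons: list[association.PairedComparison]
    correlations: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame] | None
    models: dict[str, association.InteractionModelFit]
    bootstrap: pd.DataFrame | None  # item_id, delta_r, n_failed
    n_items: int

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(out / "estimates.csv", index=False)
        self.item_status.to_csv(out / "item_status.csv", index=False)
        self.counts.to_csv(out / "counts.csv", index=False)
        self.summaries.to_csv(out / "summaries.csv", index=False)
        if self.bootstrap is not None:
            self.bootstrap.to_csv(out / "bootstrap.csv", index=False)
        if self.correlations is not None:
            self.correlations[0].to_csv(out / "correlations_r.csv")
            self.correlations[1].to_csv(out / "correlations_p.csv")
        if self.models:
            frames = []
            for name, fit in self.models.items():
                frame = fit.to_frame().reset_index(names="coefficient")
                frame.insert(0, "model", name)
                frames.append(frame)
            pd.concat(frames, ignore_index=True).to_csv(
                out / "models.csv", index=False
            )
        (out / "summary.md").write_text(self.to_markdown())

    def to_markdown(self) -> str:
        lines = ["# Run summary", "", f"Items: {self.n_items}", ""]
        lines += ["## Estimates per method", "", self.summaries.to_markdown(index=False), ""]
        lines += ["## Counts", "", self.counts.to_markdown(index=False), ""]
        if self.comparisons:
            lines.append("## Paired comparisons (Wilcoxon signed-rank)")
            lines.append("")
            for c in self.comparisons:
                lines.append(
                    f"- {c.methods[0]} vs {c.methods[1]}: n={c.n}, "
                    f"medians {c.median_a:.3g}/{c.median_b:.3g}, "
                    f"ES={c.effect_size:.3f}, p={c.p_value:.3g}"
                )
            lines.append("")
        if self.correlations is not None:
            lines += ["## Pearson correlations", "",
                      self.correlations[0].to_markdown(), ""]
        return "\n".join(lines)


# --- ingestion -------------------------------------------------------------

def read_norms(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in NORM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing norm columns {missing}")
    return df


def read_trajectories(path) -> dict[str, Trajectory]:
    """Read a trajectory CSV in long or wide form (auto-detected)."""
    df = pd.read_csv(path)
    if {"item_id", "year", "frequency"}.issubset(df.columns):
        out = {}
        for item_id, grp in df.groupby("item_id", sort=False):
            grp = grp.sort_values("year")
            out[str(item_id)] = Trajectory(
                str(item_id),
                grp["year"].to_numpy(float),
                grp["frequency"].to_numpy(float),
            )
        return out
    if "item_id" in df.columns:
        year_cols = [c for c in df.columns if c != "item_id"]
        try:
            years = np.array([float(c) for c in year_cols])
        except ValueError as exc:
            raise ValueError(
                f"{path}: wide-form headers must be numeric years"
            ) from exc
        order = np.argsort(years)
        out = {}
        for _, row in df.iterrows():
            vals = row[year_cols].to_numpy(float)[order]
            out[str(row["item_id"])] = Trajectory(
                str(row["item_id"]), years[order], vals
            )
        return out
    raise ValueError(f"{path}: unrecognized trajectory schema")


def validate_inputs(norms_path, trajectories_path=None) -> list[ValidationIssue]:
    """Schema and range checks with file/row/column diagnostics."""
    issues: list[ValidationIssue] = []
    name = str(norms_path)
    try:
        norms = pd.read_csv(norms_path)
    except Exception as exc:  # unreadable file is a single file-level issue
        return [ValidationIssue(name, None, None, f"unreadable: {exc}")]
    if norms.empty:
        issues.append(ValidationIssue(name, None, None, "no rows"))
    for col in NORM_COLUMNS:
        if col not in norms.columns:
            issues.append(ValidationIssue(name, None, col, "missing column"))
    if issues:
        return issues

    dup = norms["item_id"][norms["item_id"].duplicated()]
    for idx, val in dup.items():
        issues.append(ValidationIssue(name, idx, "item_id", f"duplicate id {val!r}"))
    checks = [
        ("aoa_mean", lambda v: v > 0, "must be > 0"),
        ("aoa_sd", lambda v: v >= 0, "must be >= 0"),
        ("n_aoa", lambda v: v >= 1, "must be >= 1"),
        ("prevalence", lambda v: 0 <= v <= 1, "must lie in [0, 1]"),
        ("n_p", lambda v: v >= 1, "must be >= 1"),
    ]
    for col, ok, msg in checks:
        vals = pd.to_numeric(norms[col], errors="coerce")
        for idx in norms.index[vals.isna() | ~vals.map(ok).fillna(False)]:
            issues.append(ValidationIssue(name, idx, col, msg))

    if trajectories_path is not None:
        tname = str(trajectories_path)
        try:
            trajs = read_trajectories(trajectories_path)
        except Exception as exc:
            issues.append(ValidationIssue(tname, None, None, str(exc)))
            return issues
        ids = set(norms["item_id"].astype(str))
        orphans = set(trajs) - ids
        for item in sorted(orphans):
            issues.append(
                ValidationIssue(tname, None, "item_id",
                                f"trajectory {item!r} has no norm row")
            )
    return issues


def _norms_records(norms: pd.DataFrame) -> dict[str, ItemNorms]:
    out = {}
    for _, row in norms.iterrows():
        out[str(row["item_id"])] = ItemNorms(
            item_id=str(row["item_id"]),
            aoa_mean=float(row["aoa_mean"]),
            aoa_sd=float(row["aoa_sd"]),
            n_aoa=int(row["n_aoa"]),
            p_u=float(row["prevalence"]),
            n_p=int(row["n_p"]),
        )
    return out


# --- pipeline --------------------------------------------------------------

def _estimate_frame(ests: list[R0Estimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                item_id=e.item_id, method=e.method,
                value=np.nan if e.value is None else e.value,
                moe=np.nan if e.moe is None else e.moe,
                status="ok" if e.ok else "missing",
                reason=e.reason or "",
                flags=";".join(e.flags),
            )
            for e in ests
        ]
    )


def run_pipeline(
    norms: pd.DataFrame,
    trajs: Mapping[str, Trajectory],
    cfg: RunConfig = RunConfig(),
) -> RunReport:
    """Run filtering, estimation, margins and comparisons on in-memory data."""
    if norms.empty:
        raise ValueError("empty norm table")
    records = _norms_records(norms)
    demo = cfg.demography
    n_items = len(records)
    logger.info("pipeline start: %d items, %d trajectories", n_items, len(trajs))

    results: dict[str, ItemResult] = trajectories.reconstruct_and_filter(
        trajs, records, alpha=cfg.alpha,
        prevalence_cap=cfg.prevalence_cap,
        stability_window=cfg.stability_window,
        stability_on=cfg.stability_on,
    )
    logger.info("trajectory filter: %d included",
                sum(r.included for r in results.values()))

    periphery = {
        i: rec for i, rec in records.items()
        if rec.p_u < cfg.prevalence_cap
    }

    ests: list[R0Estimate] = []
    boot_rows = []
    for item_id, rec in records.items():
        res = results[item_id]
        if item_id not in periphery:
            for method in METHODS:
                ests.append(R0Estimate(item_id, method, None, reason="core_lexicon"))
            continue

        delta_aoa = uncertainty.moe_aoa_ratings(rec.aoa_sd, rec.n_aoa)
        delta_p = uncertainty.moe_prevalence(rec.p_u, rec.n_p)

        e_aoa = estimators.r0_from_aoa(rec, demo)
        e_aoa.moe = uncertainty.moe_r0_aoa(demo, rec.aoa_mean, delta_aoa)
        ests.append(e_aoa)

        e_prev = estimators.r0_from_prevalence(rec)
        if e_prev.ok:
            e_prev.moe = uncertainty.moe_r0_prevalence(rec.p_u, delta_p)
        ests.append(e_prev)

        if not res.included:
            ests.append(R0Estimate(item_id, "growth", None, reason=res.reason))
            continue
        e_growth = estimators.r0_from_growth(res.fit, rec, demo)
        if e_growth.ok and cfg.n_boot > 0:
            delta_r, n_failed = uncertainty.bootstrap_delta_r(
                res.prevalence, rec.n_p, n_boot=cfg.n_boot, seed=cfg.seed
            )
            boot_rows.append(dict(item_id=item_id, delta_r=delta_r, n_failed=n_failed))
            if np.isfinite(delta_r):
                e_growth.moe = uncertainty.moe_r0_growth(
                    res.fit.r, delta_r, demo, rec.aoa_mean, delta_aoa
                )
        ests.append(e_growth)

    est_df = _estimate_frame(ests)

    # --- report tables ---
    status_rows = []
    for item_id, res in results.items():
        stab = res.stability
        fit = res.fit
        status_rows.append(
            dict(
                item_id=item_id,
                included=res.included,
                reason=res.reason or "",
                stability=np.nan if stab is None else stab.s,
                spearman_rho=res.spearman_rho,
                spearman_p=res.spearman_p,
                fit_a=np.nan if fit is None else fit.a,
                fit_r=np.nan if fit is None else fit.r,
                fit_r2=np.nan if fit is None else fit.r2,
                fit_t_infl=np.nan if fit is None else fit.t_infl,
            )
        )
    status_df = pd.DataFrame(status_rows)

    counts = (
        est_df.assign(n=1)
        .groupby(["method", "status"], sort=False)["n"].sum()
        .unstack(fill_value=0)
        .reindex(METHODS)
        .reset_index()
    )
    for col in ("ok", "missing"):
        if col not in counts:
            counts[col] = 0
    counts["total"] = counts["ok"] + counts["missing"]
    assert (counts["total"] == n_items).all(), "count reconciliation failed"

    def _q(series, q):
        return float(series.quantile(q)) if series.notna().any() else np.nan

    summaries = []
    for method in METHODS:
        sub = est_df[(est_df.method == method) & (est_df.status == "ok")]
        summaries.append(
            dict(
                method=method,
                n=len(sub),
                median=_q(sub.value, 0.5),
                q1=_q(sub.value, 0.25),
                q3=_q(sub.value, 0.75),
                median_moe=_q(sub.moe, 0.5),
            )
        )
    summaries_df = pd.DataFrame(summaries)

    # --- comparisons ---
    wide = est_df[est_df.status == "ok"].pivot(
        index="item_id", columns="method", values="value"
    )
    comparisons = []
    for a, b in (("aoa", "prevalence"), ("aoa", "growth"), ("prevalence", "growth")):
        if a in wide and b in wide:
            pair = wide[[a, b]].dropna()
            nz = (pair[a] - pair[b]) != 0
            if len(pair) >= 5 and int(nz.sum()) >= 5:
                comparisons.append(
                    association.paired_wilcoxon(
                        pair[a], pair[b], labels=(a, b), es_norm=cfg.es_norm
                    )
                )

    series = {m: wide[m].dropna() for m in METHODS if m in wide}
    correlations = association.pairwise_correlations(series) if len(series) >= 2 else None

    models: dict[str, association.InteractionModelFit] = {}
    stab_series = status_df.set_index("item_id")["stability"]
    r2_series = status_df.set_index("item_id")["fit_r2"]

    def _try_model(name, out_m, pred_m, weighted):
        if out_m not in wide or pred_m not in wide:
            return
        df = pd.DataFrame({"y": wide[out_m], "x": wide[pred_m],
                           "s": stab_series, "w": r2_series}).dropna(
            subset=["y", "x", "s"] + (["w"] if weighted else [])
        )
        if len(df) < 10:
            return
        try:
            models[name] = association.fit_interaction_model(
                df["y"], df["x"], df["s"],
                weights=df["w"] if weighted else None,
                outcome_label=out_m, predictor_label=pred_m,
            )
        except ValueError as exc:
            logger.warning("model %s not fitted: %s", name, exc)

    _try_model("aoa~prevalence", "aoa", "prevalence", weighted=False)
    _try_model("growth~prevalence", "growth", "prevalence", weighted=True)
    _try_model("growth~aoa", "growth", "aoa", weighted=True)

    boot_df = pd.DataFrame(boot_rows) if boot_rows else None
    return RunReport(
        estimates=est_df,
        item_status=status_df,
        counts=counts,
        summaries=summaries_df,
        comparisons=comparisons,
        correlations=correlations,
        models=models,
        bootstrap=boot_df,
        n_items=n_items,
    )


def run_pipeline_from_files(
    norms_path, trajectories_path, cfg: RunConfig = RunConfig()
) -> RunReport:
    """File-based entry point: validate, ingest, run."""
    issues = validate_inputs(norms_path, trajectories_path)
    fatal = [i for i in issues if "no norm row" not in i.message]
    if fatal:
        detail = "; ".join(
            f"{i.file}:{i.row}:{i.column}: {i.message}" for i in fatal[:10]
        )
        raise ValueError(f"input validation failed ({len(fatal)} issues): {detail}")
    norms = read_norms(norms_path)
    trajs = read_trajectories(trajectories_path)
    return run_pipeline(norms, trajs, cfg)


def run_on_lexicon(lexicon: SyntheticLexicon, cfg: RunConfig = RunConfig()) -> RunReport:
    """Convenience wrapper: run the pipeline on a synthetic lexicon."""
    return run_pipeline(lexicon.norms, lexicon.trajectories, cfg)
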