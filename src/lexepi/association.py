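"""Cross-estimator comparison statistics.

The three R0 estimators measure the same latent quantity from different
data, so their agreement is itself evidence.  This module provides the
comparison toolkit: paired Wilcoxon signed-rank tests with a
standardized effect size, pairwise Pearson correlations over the items
where both estimates exist, and weighted Gaussian interaction models

    y = b0 + b_x * x + b_xS * x*S + eps

that let the slope between two estimators vary with the stability
coefficient S.  Because the prevalence- and acquisition-based estimators
assume equilibrium dynamics, their agreement with the growth-based
estimator is expected to strengthen as S approaches 1 — the interaction
term tests exactly that.  Models involving the growth estimator weight
items by the goodness of fit (R^2) of their fitted trajectories to
demote unreliable growth rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PairedComparison",
    "InteractionModelFit",
    "paired_wilcoxon",
    "pairwise_correlations",
    "fit_interaction_model",
]


@dataclass(frozen=True)
class PairedComparison:
    """Wilcoxon signed-rank comparison of two paired estimator samples."""

    methods: tuple[str, str]
    n: int
    median_a: float
    median_b: float
    effect_size: float
    z: float
    p_value: float


@dataclass(frozen=True)
class InteractionModelFit:
    """Coefficients of the stability-interaction regression."""

    outcome: str
    predictor: str
    params: pd.Series  # index: const, x, x:S
    se: pd.Series
    p: pd.Series
    weights_used: bool
    nobs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.se, "p": self.p})


def paired_wilcoxon(
    values_a,
    values_b,
    labels: tuple[str, str] = ("a", "b"),
    es_norm: str = "sqrt",
) -> PairedComparison:
    """Wilcoxon signed-rank test on paired samples with effect size.

    Zero differences are dropped before ranking.  The p-value is exact
    for small tie-free samples and uses the normal approximation (with
    tie correction) otherwise.  The effect size is the standardized
    statistic ``Z/sqrt(N)`` by default (``es_norm="sqrt"``), where N is
    the number of nonzero pairs; ``es_norm="linear"`` gives the literal
    ``Z/N``.  Its sign follows the direction of the differences a - b.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d arrays")
    if es_norm not in ("sqrt", "linear"):
        raise ValueError("es_norm must be 'sqrt' or 'linear'")

    d = a - b
    nz = d[d != 0]
    n = nz.size
    median_a, median_b = float(np.median(a)), float(np.median(b))
    if n == 0:  # all differences zero
        return PairedComparison(labels, a.size, median_a, median_b, 0.0, 0.0, 1.0)
    if n < 5:
        raise ValueError("need at least 5 nonzero paired differences")

    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    mean_w = n * (n + 1) / 4.0
    # tie correction of the normal-approximation variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    z = (w_plus - mean_w) / np.sqrt(var_w) if var_w > 0 else 0.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.wilcoxon(nz, method="auto").pvalue)

    es = z / np.sqrt(n) if es_norm == "sqrt" else z / n
    return PairedComparison(labels, n, median_a, median_b, float(es), float(z), p)


def pairwise_correlations(
    estimates: Mapping[str, pd.Series], min_overlap: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations among estimators over shared items.

    ``estimates`` maps method name to a Series indexed by item id.
    Returns (r, p, n) DataFrames; cells with fewer than ``min_overlap``
    complete pairs are NaN with the count still reported.
    """
    methods = list(estimates)
    r = pd.DataFrame(np.nan, index=methods, columns=methods)
    p = pd.DataFrame(np.nan, index=methods, columns=methods)
    n = pd.DataFrame(0, index=methods, columns=methods)
    for i, mi in enumerate(methods):
        for mj in methods[i:]:
            joined = pd.concat(
                [estimates[mi].rename("x"), estimates[mj].rename("y")],
                axis=1, join="inner",
            ).dropna()
            n.loc[mi, mj] = n.loc[mj, mi] = len(joined)
            if len(joined) < min_overlap:
                continue
            if mi == mj:
                r.loc[mi, mj] = 1.0
                p.loc[mi, mj] = 0.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant inputs give NaN r
                res = stats.pearsonr(joined["x"], joined["y"])
            r.loc[mi, mj] = r.loc[mj, mi] = float(res.statistic)
            p.loc[mi, mj] = p.loc[mj, mi] = float(res.pvalue)
    return r, p, n


def fit_interaction_model(
    outcome,
    predictor,
    stability,
    weights=None,
    outcome_label: str = "y",
    predictor_label: str = "x",
) -> InteractionModelFit:
    """Fit ``outcome ~ predictor + predictor:S`` by (weighted) least squares.

    There is deliberately no main effect of S: stability only modulates
    the slope between the two estimators.  Weights, when given, are
    floored at 0 (trajectory R^2 can be negative) and passed to WLS;
    ``weights=None`` fits by OLS.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    s = np.asarray(stability, dtype=float)
    if not (y.shape == x.shape == s.shape) or y.ndim != 1:
        raise ValueError("outcome, predictor and stability must be equal-length 1-d")
    if y.size < 10:
        raise ValueError("need at least 10 complete cases")

    names = ["const", predictor_label, f"{predictor_label}:S"]
    X = pd.DataFrame({names[0]: 1.0, names[1]: x, names[2]: x * s})

    if weights is not None:
        w = np.maximum(np.asarray(weights, dtype=float), 0.0)
        if w.shape != y.shape:
            raise ValueError("weights must match the sample length")
        if not np.any(w > 0):
            raise ValueError("at least one weight must be positive")
    else:
        w = np.ones_like(y)

    active = w > 0
    Xw = X.values[active] * np.sqrt(w[active])[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        # identify which added column is collinear for a useful message
        culprit = names[2]
        if np.linalg.matrix_rank(Xw[:, :2]) < 2:
            culprit = names[1]
        raise ValueError(f"design matrix is rank deficient: term {culprit!r}")

    model = sm.WLS(y, X, weights=w)
    res = model.fit()
    return InteractionModelFit(
        outcome=outcome_label,
        predictor=predictor_label,
        params=res.params,
        se=res.bse,
        p=res.pvalues,
        weights_used=weights is not None,
        nobs=int(res.nobs),
    )
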