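"""Cohort-level and brain-behavior statistics.

Non-parametric group comparisons (Kruskal-Wallis omnibus, Dunn's pairwise
post-hoc tests with Benjamini-Hochberg adjustment, Cohen's d effect sizes),
Spearman rank correlations, and the mode-wise ordinary-least-squares model
linking modal weights to clinical scores.  Normality (Shapiro-Wilk) and
variance-homogeneity (Levene) checks are available as advisory diagnostics;
group inference always proceeds non-parametrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTestReport",
    "kruskal_wallis",
    "dunn_posthoc_bh",
    "cohens_d",
    "spearman_correlation",
    "modewise_glm",
    "group_test_report",
    "distribution_diagnostics",
]

CDR_STAGES = (0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass
class GroupTestReport:
    """Omnibus + pairwise group comparison of one variable."""

    variable: str
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj, cohens_d


def _as_groups(values_by_group: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for label, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=np.float64).ravel()
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        out[str(label)] = arr
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def kruskal_wallis(values_by_group: dict[str, np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-identical data returns (0, 1) rather than an error.
    """
    groups = _as_groups(values_by_group)
    samples = list(groups.values())
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def dunn_posthoc_bh(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled tie-corrected ranks, BH-adjusted.

    For each unordered pair (a, b):
    ``z = (R̄_a − R̄_b) / sqrt((N(N+1)/12 − T) (1/n_a + 1/n_b))`` where
    ``T = Σ(t³ − t) / (12 (N − 1))`` corrects for ties.  Two-sided normal
    p-values are adjusted with the Benjamini-Hochberg step-up across all
    pairs.  Columns: group_a, group_b, z, p_raw, p_adj.
    """
    groups = _as_groups(values_by_group)
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in labels:
        n = len(groups[g])
        mean_rank[g] = float(ranks[start : start + n].mean())
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            se = np.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 1.0
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    return table


def cohens_d(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Standardized mean difference (mean_a − mean_b) / pooled sd."""
    a = np.asarray(sample_a, float).ravel()
    b = np.asarray(sample_b, float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation; d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def group_test_report(variable: str, values_by_group: dict[str, np.ndarray]) -> GroupTestReport:
    """Kruskal-Wallis omnibus plus Dunn/BH pairwise table with Cohen's d."""
    groups = _as_groups(values_by_group)
    h, p = kruskal_wallis(groups)
    pairwise = dunn_posthoc_bh(groups)
    pairwise["cohens_d"] = [
        cohens_d(groups[r.group_a], groups[r.group_b])
        if groups[r.group_a].var(ddof=1) + groups[r.group_b].var(ddof=1) > 0
        else 0.0
        for r in pairwise.itertuples()
    ]
    return GroupTestReport(variable=variable, h_statistic=h, p_value=p, pairwise=pairwise)


def spearman_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman ρ and two-sided p; incomplete pairs are dropped with a log."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    complete = np.isfinite(x) & np.isfinite(y)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("spearman_correlation: dropped %d incomplete pairs", dropped)
    x, y = x[complete], y[complete]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector; Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def modewise_glm(
    outcome: np.ndarray,
    predictors: pd.DataFrame,
    condition_threshold: float = 1e8,
) -> pd.DataFrame:
    """OLS regression of a clinical outcome on modal-weight predictors.

    Fits ``outcome ~ 1 + predictors`` on complete cases and returns one row
    per predictor with columns ``predictor, coef, t, p`` (two-sided, on
    n − p − 1 residual df).  Raises on collinear designs, naming the columns
    with the largest variance inflation.
    """
    y = np.asarray(outcome, float).ravel()
    X = predictors.copy()
    if len(y) != len(X):
        raise ValueError("outcome and predictors must have equal length")
    complete = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("modewise_glm: dropped %d incomplete cases", dropped)
    y, X = y[complete], X.loc[complete]
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} complete cases for {p} predictors, got {n}")

    std = X.to_numpy(float)
    scale = std.std(axis=0, ddof=0)
    if np.any(scale == 0):
        bad = [c for c, s in zip(X.columns, scale) if s == 0]
        raise ValueError(f"constant predictor column(s): {bad}")
    std = (std - std.mean(axis=0)) / scale
    cond = np.linalg.cond(std)
    if cond > condition_threshold:
        design = sm.add_constant(std)
        with np.errstate(divide="ignore"):
            vifs = [variance_inflation_factor(design, i + 1) for i in range(p)]
        worst = [c for c, v in sorted(zip(X.columns, vifs), key=lambda t: -t[1])[:2]]
        raise ValueError(
            f"collinear predictors (condition number {cond:.3g}); "
            f"most inflated columns: {worst}"
        )

    model = sm.OLS(y, sm.add_constant(X.to_numpy(float))).fit()
    return pd.DataFrame(
        {
            "predictor": list(X.columns),
            "coef": model.params[1:],
            "t": model.tvalues[1:],
            "p": model.pvalues[1:],
        }
    )


def distribution_diagnostics(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Advisory Shapiro-Wilk (per group) and Levene (across groups) checks."""
    groups = _as_groups(values_by_group)
    rows = []
    for g, vals in groups.items():
        if len(vals) >= 3 and vals.var() > 0:
            w, p = stats.shapiro(vals)
        else:
            w, p = np.nan, np.nan
        rows.append({"test": "shapiro", "group": g, "statistic": w, "p": p})
    try:
        w, p = stats.levene(*groups.values())
    except ValueError:
        w, p = np.nan, np.nan
    rows.append({"test": "levene", "group": "all", "statistic": w, "p": p})
    return pd.DataFrame(rows)
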