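"""Correlation structure of deviation z-scores, network thresholding, and
group comparison with false-discovery-rate control.

Deviation z-scores (subjects x (roi, metric, statistic) columns) are
correlated pairwise-complete (Pearson).  Positive correlations at or above a
threshold define undirected network edges; connected components expose
"networks of variation".  Group comparisons use Welch's t-test (unequal
variances; the cohorts compared here are 44 vs 316) with Benjamini-Hochberg
step-up FDR control within each (metric, statistic) family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("qmrinorm")


@dataclass
class ComparisonResult:
    roi: str
    metric: str
    statistic: str
    t: float
    dof: float
    p_raw: float
    p_adjusted: float = np.nan
    significant: bool = False
    mean_a: float = np.nan
    mean_b: float = np.nan
    n_a: int = 0
    n_b: int = 0


def pivot_deviations(scores: pd.DataFrame, value_col: str = "z") -> pd.DataFrame:
    """Pivot long-format deviation scores to subjects x (roi, metric, statistic)."""
    idx = ["subject_id"] + (["hemisphere"] if "hemisphere" in scores.columns else [])
    return scores.pivot_table(
        index=idx, columns=["roi", "metric", "statistic"], values=value_col, aggfunc="mean"
    )


def corr_matrix(dev: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pearson correlation across columns, pairwise-complete observations.

    Cells with fewer than ``min_periods`` complete pairs, or involving a
    zero-variance column, are NaN (logged).  Diagonal is 1 where defined.
    """
    variances = dev.var(ddof=0)
    flat = variances[variances == 0].index.tolist()
    if flat:
        logger.warning("corr_matrix: zero-variance column(s) set to NaN: %s", flat)
    corr = dev.corr(method="pearson", min_periods=min_periods)
    np.fill_diagonal(corr.values, 1.0)
    for col in flat:
        corr.loc[col, :] = np.nan
        corr.loc[:, col] = np.nan
    return corr


def threshold_network(corr: pd.DataFrame, threshold: float):
    """Edges where r >= threshold (positive correlations only) + connected components.

    Returns ``(edges, components)``: edges as (node_a, node_b, r) tuples and
    components as lists of node labels sorted by decreasing size (ties by
    first node).
    """
    mat = corr.to_numpy()
    if mat.shape[0] != mat.shape[1] or not np.allclose(
        np.nan_to_num(mat), np.nan_to_num(mat.T), atol=1e-10
    ):
        raise ValueError("correlation matrix must be square and symmetric")
    nodes = list(corr.index)
    parent = {n: n for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    edges = []
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            r = mat[i, j]
            if np.isfinite(r) and r >= threshold:
                edges.append((a, nodes[j], float(r)))
                parent[find(a)] = find(nodes[j])
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), []).append(n)
    components = sorted(groups.values(), key=lambda g: (-len(g), str(g[0])))
    return edges, components


def welch_ttest(group_a, group_b):
    """Welch's two-sample t-test: (t, Welch-Satterthwaite dof, two-sided p).

    Zero variance in both groups with equal means returns (0, n-2, 1) by
    convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p, reject flags) in original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def compare_groups(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    value_col: str = "z",
    q: float = 0.05,
    pool_hemispheres: bool = True,
) -> pd.DataFrame:
    """Per-(roi, metric, statistic) Welch tests between two cohorts' scores, BH-corrected.

    Hemisphere rows are pooled per subject (mean) by default.  The FDR family
    is all ROIs within one (metric, statistic).
    """
    def collapse(df):
        if pool_hemispheres:
            return df.groupby(["roi", "metric", "statistic", "subject_id"])[value_col].mean()
        return df.set_index(["roi", "metric", "statistic", "subject_id"])[value_col]

    ga, gb = collapse(scores_a).sort_index(), collapse(scores_b).sort_index()
    records = []
    keys = sorted(
        set(ga.index.droplevel("subject_id").unique())
        & set(gb.index.droplevel("subject_id").unique())
    )
    for roi, metric, statistic in keys:
        va = ga.loc[(roi, metric, statistic)].to_numpy()
        vb = gb.loc[(roi, metric, statistic)].to_numpy()
        t, dof, p = welch_ttest(va, vb)
        records.append(
            ComparisonResult(
                roi, metric, statistic, t, dof, p,
                mean_a=float(np.mean(va)), mean_b=float(np.mean(vb)),
                n_a=len(va), n_b=len(vb),
            )
        )
    df = pd.DataFrame([vars(r) for r in records])
    df["p_adjusted"] = np.nan
    df["significant"] = False
    for _, idx in df.groupby(["metric", "statistic"]).groups.items():
        p_adj, rej = bh_fdr(df.loc[idx, "p_raw"].to_numpy(), q=q)
        df.loc[idx, "p_adjusted"] = p_adj
        df.loc[idx, "significant"] = rej
    return df
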