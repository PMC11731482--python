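"""Univariate statistical toolkit used across the pipeline.

Pearson chi-square (no continuity correction), Kruskal-Wallis, Bonferroni
adjustment, Epanechnikov kernel density, two-sample Kolmogorov-Smirnov and
Pearson correlation matrices, plus cohort-comparison report builders.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "chi_square_test", "kruskal_wallis", "bonferroni_adjust",
    "epanechnikov_density", "silverman_bandwidth", "ks_two_sample",
    "pearson_corr_matrix", "cohort_table", "group_association_table",
]


def chi_square_test(table):
    """Pearson chi-square test of independence on an r x c count table.

    No Yates continuity correction.  Rows/columns with a zero marginal are
    dropped with a warning.  Returns (statistic, df, p).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-marginal rows/columns from contingency table")
        t = t[np.ix_(keep_r, keep_c)]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns with positive marginals")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def kruskal_wallis(groups):
    """Rank-based Kruskal-Wallis H with tie correction; returns (H, df, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if all(np.array_equal(groups[0], g) for g in groups[1:]):
        return 0.0, len(groups) - 1, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def bonferroni_adjust(p_values, m=None):
    """Elementwise min(1, m * p); m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def silverman_bandwidth(values) -> float:
    """Silverman rule-of-thumb bandwidth, 0.9 * min(sd, IQR/1.349) * n^(-1/5)."""
    x = np.asarray(values, dtype=float)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    m = min(x.std(ddof=1), iqr / 1.349) if iqr > 0 else x.std(ddof=1)
    if m <= 0:
        raise ValueError("degenerate sample: zero spread")
    return 0.9 * m * len(x) ** (-0.2)


def epanechnikov_density(values, grid, bandwidth=None):
    """Epanechnikov kernel density estimate on ``grid``.

    f(x) = (1/nh) sum K((x - x_i)/h), K(u) = 0.75 (1 - u^2) on |u| <= 1.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(grid, dtype=float)
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    u = (g[:, None] - x[None, :]) / h
    k = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)
    return k.sum(axis=1) / (len(x) * h)


def ks_two_sample(a, b):
    """Two-sample Kolmogorov-Smirnov: D = sup|ECDF_a - ECDF_b|, asymptotic P."""
    res = sps.ks_2samp(np.asarray(a, float), np.asarray(b, float), method="asymp")
    return float(res.statistic), float(res.pvalue)


def pearson_corr_matrix(columns: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the columns of a DataFrame."""
    df = pd.DataFrame(columns)
    corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=df.columns, columns=df.columns)


def cohort_table(subjects: pd.DataFrame, case_col: str, variables) -> pd.DataFrame:
    """Table-1-style case/control comparison of categorical variables.

    One row per variable level with case/control counts and percentages, plus
    the variable-level chi-square P (uncorrected Pearson).
    """
    rows = []
    is_case = subjects[case_col].astype(bool)
    for var in variables:
        counts = pd.crosstab(subjects[var], is_case)
        counts = counts.reindex(columns=[True, False], fill_value=0)
        try:
            _, _, p = chi_square_test(counts.to_numpy())
        except ValueError:
            p = np.nan
        for level, row in counts.iterrows():
            rows.append({
                "variable": var, "level": level,
                "cases": int(row[True]), "controls": int(row[False]),
                "cases_pct": 100 * row[True] / max(is_case.sum(), 1),
                "controls_pct": 100 * row[False] / max((~is_case).sum(), 1),
                "p_value": p,
            })
    return pd.DataFrame(rows)


def group_association_table(subjects: pd.DataFrame, case_col: str,
                            grouping_cols, alpha=0.05) -> pd.DataFrame:
    """Case/control chi-square per grouping with Bonferroni-adjusted flags.

    Mirrors the reporting pattern used for trajectory-group and VIM-quintile
    case-count comparisons: one r x 2 table per grouping column, with the
    family-wise adjustment over the set of groupings tested.
    """
    rows = []
    is_case = subjects[case_col].astype(bool)
    for col in grouping_cols:
        counts = pd.crosstab(subjects[col], is_case).reindex(columns=[True, False], fill_value=0)
        stat, df, p = chi_square_test(counts.to_numpy())
        rows.append({"grouping": col, "chi2": stat, "df": df, "p_value": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni_adjust(out["p_value"].to_numpy(), len(out))
    out["significant"] = out["p_bonferroni"] < alpha
    return out
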