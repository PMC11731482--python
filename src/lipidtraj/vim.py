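"""Variability independent of the mean (VIM).

A subject's across-visit SD rescaled by a fitted power of the subject mean so
that the resulting variability measure is uncorrelated with mean level:

    x = OLS slope of ln(SD_i) on ln(mean_i)
    VIM_i = k * SD_i / mean_i^x,   k = (grand mean of subject means)^x

so VIM carries the units of the SD.  Quintile 1 = least variability.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VimResult", "subject_summaries", "fit_vim_exponent",
           "compute_vim", "assign_quintiles", "vim_table"]


@dataclass
class VimResult:
    """Per-subject VIM with the cohort-level exponent and scale."""
    table: pd.DataFrame          # subject_id, n, mean, sd, vim, quintile
    exponent: float
    scale: float                 # k = grand_mean ** exponent

    def to_csv(self, path, **kw):
        self.table.to_csv(path, index=False, **kw)


def subject_summaries(measurements: pd.DataFrame, value_col="value",
                      subject_col="subject_id") -> pd.DataFrame:
    """n / mean / SD (ddof=1) per subject from a long measurement table."""
    g = measurements.groupby(subject_col)[value_col]
    out = g.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    return out


def fit_vim_exponent(summ: pd.DataFrame) -> float:
    """Fitted exponent x: OLS slope of ln(SD_i) on ln(mean_i), SD_i > 0 only."""
    s = summ[(summ["sd"] > 0) & (summ["mean"] > 0)]
    if len(s) < 2:
        raise ValueError("need >=2 subjects with positive SD and mean")
    lx = np.log(s["mean"].to_numpy())
    ly = np.log(s["sd"].to_numpy())
    if np.ptp(lx) == 0:
        warnings.warn("all subject means equal; VIM exponent set to 0")
        return 0.0
    slope = np.polyfit(lx, ly, 1)[0]
    return float(slope)


def compute_vim(summ: pd.DataFrame, x: float) -> VimResult:
    """VIM_i = k * SD_i / mean_i^x with k = (grand mean of subject means)^x."""
    if not np.isfinite(x):
        raise ValueError("exponent must be finite")
    grand = summ["mean"].mean()
    k = grand ** x
    vim = np.where(summ["sd"] > 0, k * summ["sd"] / summ["mean"] ** x, 0.0)
    table = summ.copy()
    table["vim"] = vim
    return VimResult(table=table, exponent=x, scale=float(k))


def assign_quintiles(values, ids=None) -> np.ndarray:
    """Quintile labels 1-5 (1 = least variability) cutting at the sample
    20/40/60/80 percentiles; ties resolved by rank with stable id order, so
    label counts differ by at most one.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if np.unique(v).size < 5:
        raise ValueError("need at least 5 distinct values to form quintiles")
    if ids is not None:
        order = np.lexsort((np.asarray(ids), v))
    else:
        order = np.argsort(v, kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) * 5 // n + 1
    return labels


def vim_table(measurements: pd.DataFrame, lipids, value_col="value",
              lipid_col="lipid", subject_col="subject_id") -> pd.DataFrame:
    """VIM + quintiles per lipid type from a long measurement table.

    Returns one row per subject x lipid with n, mean, sd, vim, quintile and the
    fitted exponent for that lipid.
    """
    frames = []
    for lipid in lipids:
        m = measurements[measurements[lipid_col] == lipid]
        summ = subject_summaries(m, value_col=value_col, subject_col=subject_col)
        summ = summ[summ["n"] >= 3]
        x = fit_vim_exponent(summ)
        res = compute_vim(summ, x)
        t = res.table
        t["quintile"] = assign_quintiles(t["vim"].to_numpy(), t[subject_col].to_numpy())
        t["lipid"] = lipid
        t["exponent"] = x
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
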