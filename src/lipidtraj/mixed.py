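"""Multilevel mixed-effects models for longitudinal correlates of lipid levels.

One model per lipid: fixed-effect candidates (demographics, medication use,
comorbidities, interactions, genotypes, standardized polygenic scores, genetic
principal components) with a subject-level random intercept and random slope on
age, unstructured 2x2 covariance, maximum-likelihood estimation, and AIC
backward selection via :mod:`lipidtraj.selection`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams

from .selection import aic_backward_select, SelectionResult

__all__ = ["MixedModelFit", "fit_mixed_model", "backward_select_mixed"]


@dataclass
class MixedModelFit:
    """Coefficient table plus variance components for one mixed model."""
    response: str
    terms: list
    table: pd.DataFrame            # term, beta, ci_low, ci_high, p
    llf: float
    aic: float
    n_params: int
    var_intercept: float
    var_slope: float
    re_correlation: float
    resid_var: float
    diagonal_fallback: bool = False
    result: object = field(default=None, repr=False)


def _formula(response, terms):
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def fit_mixed_model(data: pd.DataFrame, response: str, terms,
                    group_col="subject_id", slope_col="age",
                    diagonal_fallback=True) -> MixedModelFit:
    """ML fit with random intercept + random slope on ``slope_col``.

    The 2x2 random-effects covariance is unstructured; if it comes back
    singular the model is refit with a diagonal structure and flagged.
    Wald confidence intervals.  AIC counts fixed effects, the random-effects
    covariance parameters and the residual variance.
    """
    terms = list(terms)
    data = data.dropna(subset=[response, group_col, slope_col]).copy()
    model = smf.mixedlm(_formula(response, terms), data,
                        groups=data[group_col], re_formula=f"~{slope_col}")
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method=["lbfgs", "powell"])
        cov_re = np.asarray(res.cov_re)
        if np.linalg.eigvalsh(cov_re).min() < 1e-10:
            if diagonal_fallback:
                fallback = True
                free = MixedLMParams.from_components(
                    fe_params=np.ones(len(res.fe_params)), cov_re=np.eye(2))
                res = model.fit(reml=False, free=free, method=["lbfgs", "powell"])
                cov_re = np.asarray(res.cov_re)
    n_fe = len(res.fe_params)
    n_recov = 2 if fallback else 3
    k = n_fe + n_recov + 1
    aic = -2 * res.llf + 2 * k
    ci = res.conf_int().iloc[:n_fe]
    table = pd.DataFrame({
        "term": res.fe_params.index,
        "beta": res.fe_params.to_numpy(),
        "ci_low": ci.iloc[:, 0].to_numpy(),
        "ci_high": ci.iloc[:, 1].to_numpy(),
        "p": res.pvalues.iloc[:n_fe].to_numpy(),
    })
    v_int = float(cov_re[0, 0])        # cov_re is already on the data scale
    v_slope = float(cov_re[1, 1])
    denom = np.sqrt(cov_re[0, 0] * cov_re[1, 1])
    corr = float(cov_re[0, 1] / denom) if denom > 0 else 0.0
    return MixedModelFit(
        response=response, terms=terms, table=table, llf=float(res.llf),
        aic=float(aic), n_params=k, var_intercept=v_int, var_slope=v_slope,
        re_correlation=corr, resid_var=float(res.scale),
        diagonal_fallback=fallback, result=res,
    )


def backward_select_mixed(data: pd.DataFrame, response: str, candidates,
                          locked=(), group_col="subject_id",
                          slope_col="age") -> SelectionResult:
    """AIC backward selection over fixed-effect candidate terms.

    Locked terms (e.g. the ten genetic principal components) are never
    dropped.  Returns the selection result with the full elimination trace.
    """
    def fit_fn(terms):
        return fit_mixed_model(data, response, terms,
                               group_col=group_col, slope_col=slope_col)
    return aic_backward_select(fit_fn, list(candidates), locked=list(locked))
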