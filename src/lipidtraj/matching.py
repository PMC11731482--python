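"""Propensity-score matching of controls to cases with exact strata.

Cases are matched at index age: exact strata on coarse variables (sex, age
group, BMI group, medication use), greedy nearest-neighbour on the propensity
logit within each stratum for the continuous/nearest variables (race, APOE
allele counts, education), variable control:case ratio without replacement.
Controls in a matched set share a total weight of 1 (ATT convention); cases
have weight 1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["AGE_GROUP_CUTS", "BMI_GROUP_CUTS", "MatchSpec", "MatchedCohort",
           "estimate_propensity", "match", "age_group", "bmi_group",
           "standardized_mean_differences"]

#: Exact-matching cutpoints for age at index year.
AGE_GROUP_CUTS = (50, 60, 65, 73, 78, 82, 86, 99)
AGE_GROUP_LABELS = ("50-59", "60-64", "65-72", "73-77", "78-81", "82-85", "86-98")

#: Exact-matching BMI (kg/m^2) bands.
BMI_GROUP_CUTS = (0, 18.5, 25, 30, 35, 40, np.inf)
BMI_GROUP_LABELS = ("<18.5", "18.5-24.9", "25-29.9", "30-34.9", "35-40", ">40")


def age_group(age) -> pd.Categorical:
    return pd.cut(age, bins=AGE_GROUP_CUTS, labels=AGE_GROUP_LABELS, right=False)


def bmi_group(bmi) -> pd.Categorical:
    return pd.cut(bmi, bins=BMI_GROUP_CUTS, labels=BMI_GROUP_LABELS, right=False)


@dataclass
class MatchSpec:
    exact: tuple = ("sex", "age_group", "bmi_group", "on_med_at_index")
    nearest: tuple = ("race", "apoe_e2", "apoe_e4", "education")
    ratio: int = 4                      # max controls per case
    caliper: float | None = None        # on the PS logit; None = no caliper

    def validate(self):
        if set(self.exact) & set(self.nearest):
            raise ValueError("exact and nearest variable lists must be disjoint")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")


@dataclass
class MatchedCohort:
    table: pd.DataFrame                  # subject_id, set_id, case, ps, weight
    balance: pd.DataFrame                # variable, smd_pre, smd_post
    unmatched_cases: list = field(default_factory=list)
    ps_flagged: bool = False             # penalized fallback used

    @property
    def n_sets(self):
        return self.table["set_id"].nunique()


def estimate_propensity(subjects: pd.DataFrame, covariates, case_col="case"):
    """Case-vs-control logistic propensity scores in (0, 1).

    Categorical covariates are dummy-coded.  Perfect separation triggers a
    flagged fallback to an L2-penalized fit.
    """
    X = pd.get_dummies(subjects[list(covariates)], drop_first=True).astype(float)
    X = sm.add_constant(X, has_constant="add")
    y = subjects[case_col].astype(float).to_numpy()
    flagged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        ps = np.asarray(res.predict(X))
        if not np.all((ps > 0) & (ps < 1)) or not np.all(np.isfinite(res.params)):
            raise ValueError("separation")
    except Exception:
        from sklearn.linear_model import LogisticRegression
        flagged = True
        warnings.warn("propensity fit flagged (separation/non-convergence); "
                      "using penalized logistic fallback")
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(X.to_numpy(), y)
        ps = clf.predict_proba(X.to_numpy())[:, 1]
    ps = np.clip(ps, 1e-12, 1 - 1e-12)
    return pd.Series(ps, index=subjects.index, name="ps"), flagged


def standardized_mean_differences(subjects, variables, case_col="case",
                                  weights=None) -> pd.Series:
    """Absolute standardized mean difference per variable (dummy-coded).

    Denominator is the pooled (unweighted) SD; weights, if given, apply to the
    group means (matching weights for post-match balance).
    """
    X = pd.get_dummies(subjects[list(variables)], drop_first=True).astype(float)
    case = subjects[case_col].astype(bool).to_numpy()
    w = np.ones(len(subjects)) if weights is None else np.asarray(weights, float)
    out = {}
    for col in X.columns:
        x = X[col].to_numpy()
        sd = np.sqrt((x[case].var(ddof=1) + x[~case].var(ddof=1)) / 2)
        m1 = np.average(x[case], weights=w[case])
        m0 = np.average(x[~case], weights=w[~case])
        out[col] = abs(m1 - m0) / sd if sd > 0 else 0.0
    return pd.Series(out, name="smd")


def match(subjects: pd.DataFrame, spec: MatchSpec, case_col="case",
          ps=None) -> MatchedCohort:
    """Greedy nearest-PS matching within exact strata, without replacement.

    Cases are processed in descending propensity order; each takes up to
    ``spec.ratio`` nearest unmatched controls on the PS logit (within the
    caliper, if set).  Cases whose stratum has no available control are
    reported unmatched; unmatched controls are dropped.
    """
    spec.validate()
    df = subjects.copy()
    flagged = False
    if ps is None:
        ps, flagged = estimate_propensity(df, spec.nearest, case_col=case_col)
    df["ps"] = np.asarray(ps, dtype=float)
    df["_logit_ps"] = np.log(df["ps"] / (1 - df["ps"]))
    case_mask = df[case_col].astype(bool)

    strata = df.groupby(list(spec.exact), observed=True, sort=False)
    set_rows, unmatched = [], []
    set_id = 0
    for _, stratum in strata:
        cases = stratum[stratum[case_col].astype(bool)].sort_values("ps", ascending=False)
        controls = stratum[~stratum[case_col].astype(bool)]
        avail = controls["_logit_ps"].copy()
        for cix, crow in cases.iterrows():
            if avail.empty:
                unmatched.append(df.loc[cix, "subject_id"] if "subject_id" in df else cix)
                continue
            dist = (avail - crow["_logit_ps"]).abs().sort_values(kind="stable")
            if spec.caliper is not None:
                dist = dist[dist <= spec.caliper]
            take = dist.index[:spec.ratio]
            if len(take) == 0:
                unmatched.append(df.loc[cix, "subject_id"] if "subject_id" in df else cix)
                continue
            set_id += 1
            set_rows.append((cix, set_id, 1.0))
            for t in take:
                set_rows.append((t, set_id, 1.0 / len(take)))
            avail = avail.drop(take)
    if unmatched:
        warnings.warn(f"{len(unmatched)} case(s) left unmatched (empty stratum)")

    cols = ["set_id", "weight", "ps", case_col]
    if "subject_id" in df:
        cols = ["subject_id"] + cols
    bal_vars = [v for v in (*spec.exact, *spec.nearest)]
    pre = standardized_mean_differences(df, bal_vars, case_col=case_col)
    if not set_rows:
        table = pd.DataFrame(columns=cols)
        post = pd.Series(np.nan, index=pre.index, name="smd")
        balance = pd.DataFrame({"smd_pre": pre, "smd_post": post}) \
            .rename_axis("variable").reset_index()
        return MatchedCohort(table=table, balance=balance,
                             unmatched_cases=unmatched, ps_flagged=flagged)

    assigned = pd.DataFrame(set_rows, columns=["_ix", "set_id", "weight"]).set_index("_ix")
    out = df.loc[assigned.index].copy()
    out["set_id"] = assigned["set_id"]
    out["weight"] = assigned["weight"]
    table = out[cols].sort_values(["set_id", case_col], ascending=[True, False]).reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        post = standardized_mean_differences(out, bal_vars, case_col=case_col,
                                             weights=out["weight"].to_numpy())
    balance = pd.DataFrame({"smd_pre": pre, "smd_post": post}).rename_axis("variable").reset_index()
    return MatchedCohort(table=table, balance=balance,
                         unmatched_cases=unmatched, ps_flagged=flagged)
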