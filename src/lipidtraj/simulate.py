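"""Synthetic case/control cohorts with the longitudinal structure the
downstream analysis assumes.

Each subject gets an 11-year observation window on a relative-year axis
(-10..0, 0 = index year), a per-year Bernoulli visit schedule resampled until
at least three distinct measured years, latent lipid-trajectory groups with
polynomial mean curves and a medication effect, subject-level residual SDs
scaled as a power of the subject mean (so the VIM machinery has a true
exponent to recover), a medication-order event table driven by the same
order-state semantics the derivations module infers from, and case status
drawn from a configurable logistic outcome model on trajectory group, true VIM
quintile, age, education, comorbidity and genetic-score terms.

The group mean curves are illustrative: levels are styled on the three roughly
level per-lipid groups the trajectory models are meant to recover, not
extracted estimates from any cohort.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import derive
from .vim import assign_quintiles

__all__ = ["GroupSpec", "LipidSpec", "OutcomeModel", "CovariateConfig",
           "CohortConfig", "SyntheticCohort", "generate_cohort",
           "generate_case_status"]


@dataclass
class GroupSpec:
    """One latent trajectory group: mixing share, polynomial mean coefficients
    on the t/10 basis (t = relative year, so coefs[0] is the year-0 mean), and
    an additive on-medication shift in the lipid's units."""
    share: float
    coefs: tuple
    med_effect: float = 0.0


@dataclass
class LipidSpec:
    groups: list
    resid_sd: float               # visit-level residual SD at the grand mean
    subject_sd: float             # between-subject intercept SD
    vim_exponent: float = 0.8     # true x: SD_i proportional to mean_i^x
    sd_spread: float = 0.3        # lognormal sigma of the subject SD multiplier
    log_scale: bool = False       # simulate on the ln scale (triglycerides)
    score_effect: float = 0.0     # shift (lipid units per SD) from prs_<name>

    def validate(self, name=""):
        shares = np.array([g.share for g in self.groups])
        if not np.isclose(shares.sum(), 1.0, atol=1e-8) or np.any(shares <= 0):
            raise ValueError(f"{name}: group shares must be positive and sum to 1")
        if self.resid_sd <= 0:
            raise ValueError(f"{name}: resid_sd must be positive")


def _default_lipids():
    return {
        "hdl": LipidSpec(
            groups=[GroupSpec(0.44, (42.0, -2.0), 1.0),
                    GroupSpec(0.41, (56.0, -2.0), 1.5),
                    GroupSpec(0.15, (85.0, 0.0), 2.0)],
            resid_sd=5.0, subject_sd=4.0, vim_exponent=0.8, score_effect=2.5),
        "tc": LipidSpec(
            groups=[GroupSpec(0.50, (175.0, -8.0), -18.0),
                    GroupSpec(0.35, (205.0, -8.0), -18.0),
                    GroupSpec(0.15, (245.0, -10.0), -20.0)],
            resid_sd=16.0, subject_sd=12.0, vim_exponent=0.8, score_effect=8.0),
        "tg": LipidSpec(
            groups=[GroupSpec(1.0, (4.75, 0.1), -0.08)],
            resid_sd=0.22, subject_sd=0.3, vim_exponent=0.0, log_scale=True,
            score_effect=0.08),
    }


@dataclass
class OutcomeModel:
    """Log-odds coefficients of the case-status logistic model.

    Keys of ``coefficients`` name numeric columns of the subject table; the
    intercept is calibrated once so the default covariate mix yields a roughly
    30% marginal prevalence (a case-control cohort, not a population rate).
    """
    intercept: float = -2.0
    coefficients: dict = field(default_factory=lambda: {
        "hdl_group1": 1.0,      # lowest HDL-C trajectory, relative to group 3
        "hdl_group2": 1.3,
        "tc_vim_q1": 0.9,       # least TC variability, relative to quintiles 2-5
        "age_c": 0.05,          # per year, centered at 75
        "educ_gt12": -0.5,
        "cerebrovascular": 0.4,
        "prs_ad": 0.8,
        "prs_tc": 0.25,
    })


@dataclass
class CovariateConfig:
    p_female: float = 0.5
    age_mean: float = 77.0
    age_sd: float = 7.0
    age_range: tuple = (52.0, 97.0)
    bmi_mean: float = 26.5
    bmi_sd: float = 4.2
    bmi_range: tuple = (16.0, 45.0)
    education_probs: dict = field(default_factory=lambda: {
        "<12": 0.025, "12": 0.15, "12-15": 0.17, ">=16": 0.655})
    race_probs: dict = field(default_factory=lambda: {
        "Caucasian": 0.92, "Black": 0.03, "Asian": 0.04, "Other": 0.01})
    p_smoking: float = 0.02
    p_alcohol: float = 0.11
    comorbidity_prevalence: dict = field(default_factory=lambda: {
        "hypertension": 0.75, "atherosclerosis": 0.06, "cerebrovascular": 0.18,
        "diabetes": 0.27, "ischemic_heart_disease": 0.33,
        "malignant_neoplasm": 0.42})
    apoe_e4_probs: tuple = (0.65, 0.29, 0.06)    # 0/1/2 allele counts
    apoe_e2_probs: tuple = (0.885, 0.11, 0.005)
    score_names: tuple = ("prs_ad", "prs_tc", "prs_hdl", "prs_nonhdl",
                          "prs_ldl", "prs_tg")
    n_pcs: int = 10


@dataclass
class CohortConfig:
    n_subjects: int = 800
    window_years: int = 11
    visit_prob: float = 0.6
    min_visits: int = 3
    max_visits: int = 11
    lipids: dict = field(default_factory=_default_lipids)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    med_user_frac: float = 0.76
    med_discontinue_frac: float = 0.15
    med_replace_frac: float = 0.5
    ldl_recorded_frac: float = 0.25
    seed: int = 0

    def validate(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.window_years < 3:
            raise ValueError("window_years must be >= 3")
        if self.min_visits < 3:
            raise ValueError("min_visits must be >= 3")
        if self.min_visits > self.window_years:
            raise ValueError("infeasible schedule: min visits exceed the window")
        if not 0 < self.visit_prob <= 1:
            raise ValueError("visit_prob must be in (0, 1]")
        for p in self.covariates.comorbidity_prevalence.values():
            if not 0 <= p <= 1:
                raise ValueError("prevalences must lie in [0, 1]")
        for name, spec in self.lipids.items():
            spec.validate(name)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain(asdict(self)), fh, sort_keys=False)


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def vim_validation_config(n_subjects=500, exponent=0.8, seed=0) -> CohortConfig:
    """Cohort whose measured values follow the pure VIM generating law.

    One flat total-cholesterol trajectory, no medication use and a full annual
    visit schedule, so a subject's visit-to-visit SD is exactly
    c * mean^exponent * lognormal noise -- the heteroscedastic condition the
    variability-independent-of-the-mean machinery is meant to neutralize.
    Between-subject spread is wide (SD 55 mg/dl around 200) so the SD-vs-mean
    relation is detectable at n around 500.
    """
    return CohortConfig(
        n_subjects=n_subjects, visit_prob=1.0, med_user_frac=0.0,
        ldl_recorded_frac=0.0, seed=seed,
        lipids={"tc": LipidSpec(groups=[GroupSpec(1.0, (200.0,), 0.0)],
                                resid_sd=20.0, subject_sd=55.0,
                                vim_exponent=exponent, sd_spread=0.2)},
        outcome=OutcomeModel(intercept=-1.0, coefficients={"age_c": 0.0}),
    )


@dataclass
class SyntheticCohort:
    subjects: pd.DataFrame
    measurements: pd.DataFrame
    orders: pd.DataFrame
    config: CohortConfig
    prevalence: float

    def write(self, outdir):
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.measurements.to_csv(out / "measurements.csv", index=False)
        self.orders.to_csv(out / "orders.csv", index=False)
        self.config.to_yaml(out / "cohort_config.yaml")
        with open(out / "metadata.json", "w") as fh:
            json.dump({"seed": self.config.seed,
                       "n_subjects": int(len(self.subjects)),
                       "prevalence": self.prevalence}, fh, indent=2)


def generate_case_status(subjects: pd.DataFrame, outcome: OutcomeModel,
                         rng: np.random.Generator):
    """Draw binary case status from the configured logistic model.

    Returns (case vector, marginal prevalence).  A coefficient naming a column
    absent from the subject table raises an error naming it.
    """
    lp = np.full(len(subjects), outcome.intercept, dtype=float)
    for col, coef in outcome.coefficients.items():
        if col not in subjects.columns:
            raise ValueError(f"missing covariate column {col!r} in subject table")
        lp += coef * subjects[col].to_numpy(dtype=float)
    p = expit(lp)
    case = (rng.random(len(subjects)) < p).astype(int)
    return case, float(p.mean())


def _visit_schedule(rng, n, window, prob, min_visits):
    """Per-year Bernoulli inclusion, rows resampled until >= min_visits years."""
    sched = rng.random((n, window)) < prob
    bad = sched.sum(axis=1) < min_visits
    while bad.any():
        sched[bad] = rng.random((bad.sum(), window)) < prob
        bad = sched.sum(axis=1) < min_visits
    return sched


def _medication_orders(rng, cfg, subject_ids):
    rows = []
    n = len(subject_ids)
    user = rng.random(n) < cfg.med_user_frac
    start = rng.integers(-10, 1, n)
    disc = rng.random(n) < cfg.med_discontinue_frac
    replace = rng.random(n) < cfg.med_replace_frac
    meds = rng.integers(0, len(derive.CHOLESTEROL_MEDICATIONS), (n, 2))
    statuses = np.array(["Sent", "Dispensed", "Verified"])
    first_status = statuses[rng.integers(0, 3, n)]
    disc_gap = rng.integers(1, 6, n)
    repl_gap = rng.integers(0, 3, n)
    for i, sid in enumerate(subject_ids):
        if not user[i]:
            continue
        med1 = derive.CHOLESTEROL_MEDICATIONS[meds[i, 0]]
        rows.append((sid, med1, first_status[i], int(start[i])))
        if disc[i] and start[i] < 0:
            d_year = int(min(start[i] + disc_gap[i], 0))
            rows.append((sid, med1, "Discontinued", d_year))
            if replace[i]:
                med2 = derive.CHOLESTEROL_MEDICATIONS[meds[i, 1]]
                r_year = int(min(d_year + repl_gap[i], 0))
                rows.append((sid, med2, first_status[i], r_year))
    return pd.DataFrame(rows, columns=["subject_id", "medication", "status", "year"])


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a reproducible synthetic case/control cohort."""
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    cov = cfg.covariates
    years = np.arange(-(cfg.window_years - 1), 1)
    subject_ids = np.array([f"S{i:05d}" for i in range(n)])

    sched = _visit_schedule(rng, n, cfg.window_years, cfg.visit_prob, cfg.min_visits)
    orders = _medication_orders(rng, cfg, subject_ids)
    orders_by_subj = {sid: grp.to_dict("records")
                      for sid, grp in orders.groupby("subject_id")}
    on_med = np.zeros((n, cfg.window_years), dtype=bool)
    for i, sid in enumerate(subject_ids):
        recs = orders_by_subj.get(sid)
        if recs:
            on_med[i] = [derive.infer_medication_use(recs, int(y)) for y in years]

    subj = {"subject_id": subject_ids}
    subj["index_year"] = rng.integers(2013, 2024, n)
    subj["female"] = (rng.random(n) < cov.p_female).astype(int)
    subj["age"] = np.clip(rng.normal(cov.age_mean, cov.age_sd, n), *cov.age_range)
    subj["bmi"] = np.clip(rng.normal(cov.bmi_mean, cov.bmi_sd, n), *cov.bmi_range)
    edu_levels = list(cov.education_probs)
    subj["education"] = rng.choice(edu_levels, n, p=list(cov.education_probs.values()))
    subj["race"] = rng.choice(list(cov.race_probs), n, p=list(cov.race_probs.values()))
    subj["smoking"] = (rng.random(n) < cov.p_smoking).astype(int)
    subj["alcohol"] = (rng.random(n) < cov.p_alcohol).astype(int)
    for cond, prev in cov.comorbidity_prevalence.items():
        subj[cond] = (rng.random(n) < prev).astype(int)
    subj["apoe_e4"] = rng.choice([0, 1, 2], n, p=cov.apoe_e4_probs)
    subj["apoe_e2"] = rng.choice([0, 1, 2], n, p=cov.apoe_e2_probs)
    for s in cov.score_names:
        subj[s] = rng.normal(0.0, 1.0, n)
    for j in range(cov.n_pcs):
        subj[f"pc{j+1}"] = rng.normal(0.0, 1.0, n)
    subjects = pd.DataFrame(subj)
    subjects["age_c"] = subjects["age"] - 75.0
    subjects["educ_gt12"] = subjects["education"].isin(["12-15", ">=16"]).astype(int)
    subjects["on_med_at_index"] = on_med[:, -1].astype(int)

    meas_rows = []
    t_scaled = years / 10.0
    for lipid, spec in cfg.lipids.items():
        shares = [g.share for g in spec.groups]
        glabels = rng.choice(len(spec.groups), n, p=shares)
        subjects[f"{lipid}_group"] = glabels + 1
        b_i = rng.normal(0.0, spec.subject_sd, n)
        score_col = f"prs_{lipid}"
        if spec.score_effect and score_col in subjects.columns:
            b_i = b_i + spec.score_effect * subjects[score_col].to_numpy()
        # subject-level residual SD proportional to (subject mean)^x
        curves = np.array([np.polynomial.polynomial.polyval(t_scaled, g.coefs)
                           for g in spec.groups])               # (G, window)
        mu = curves[glabels] + b_i[:, None]                     # (n, window)
        mu = mu + np.array([g.med_effect for g in spec.groups])[glabels][:, None] * on_med
        m_i = mu.mean(axis=1)
        grand = float(np.mean(m_i))
        ratio = np.maximum(m_i / grand, 1e-3)
        sd_i = spec.resid_sd * ratio ** spec.vim_exponent \
            * np.exp(rng.normal(0.0, spec.sd_spread, n))
        vals = mu + rng.normal(0.0, 1.0, mu.shape) * sd_i[:, None]
        if spec.log_scale:
            vals = np.exp(vals)
        else:
            vals = np.maximum(vals, 1.0)
        # true VIM quintile from the generating SD and mean
        true_ratio = sd_i / np.maximum(np.abs(m_i), 1e-6) ** spec.vim_exponent
        q = assign_quintiles(true_ratio, subject_ids)
        subjects[f"{lipid}_vim_q1"] = (q == 1).astype(int)
        ii, jj = np.nonzero(sched)
        meas_rows.append(pd.DataFrame({
            "subject_id": subject_ids[ii],
            "rel_year": years[jj],
            "lipid": lipid,
            "value": vals[ii, jj],
            "on_med": on_med[ii, jj].astype(int),
        }))
    measurements = pd.concat(meas_rows, ignore_index=True)

    # occasionally-recorded LDL rows so the Friedewald precedence is exercised
    if cfg.ldl_recorded_frac > 0 and {"tc", "hdl", "tg"} <= set(cfg.lipids):
        wide = measurements.pivot_table(index=["subject_id", "rel_year"],
                                        columns="lipid", values="value")
        ok = wide[["tc", "hdl", "tg"]].notna().all(axis=1)
        pick = rng.random(ok.sum()) < cfg.ldl_recorded_frac
        chosen = wide[ok][pick]
        if len(chosen):
            ldl = (chosen["tc"] - chosen["hdl"] - chosen["tg"] / 5.0
                   + rng.normal(0, 3.0, len(chosen)))
            ldl_rows = chosen.reset_index()[["subject_id", "rel_year"]]
            ldl_rows["lipid"] = "ldl"
            ldl_rows["value"] = np.maximum(ldl.to_numpy(), 1.0)
            med_map = measurements.drop_duplicates(["subject_id", "rel_year"])\
                .set_index(["subject_id", "rel_year"])["on_med"]
            ldl_rows["on_med"] = [med_map.get((s, y), 0) for s, y in
                                  zip(ldl_rows["subject_id"], ldl_rows["rel_year"])]
            measurements = pd.concat([measurements, ldl_rows], ignore_index=True)

    # outcome model indicator columns
    for lipid, spec in cfg.lipids.items():
        G = len(spec.groups)
        for g in range(1, G):
            subjects[f"{lipid}_group{g}"] = (subjects[f"{lipid}_group"] == g).astype(int)
    case, prevalence = generate_case_status(subjects, cfg.outcome, rng)
    subjects["case"] = case

    measurements = measurements.sort_values(
        ["subject_id", "rel_year", "lipid"]).reset_index(drop=True)
    return SyntheticCohort(subjects=subjects, measurements=measurements,
                           orders=orders, config=cfg, prevalence=prevalence)
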