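"""Configuration-driven orchestration of the full analysis.

Stage order: simulate -> derive -> match -> trajectories -> vim ->
associations -> mixed -> risk -> report.  Every stage writes CSV artifacts to
the output directory and appends to a JSON run manifest (seed, row counts,
timings, status).  Stages are pure functions of (inputs, config, seed); a
rerun with the same config and seed reproduces identical numbers.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import derive, matching, mixed, risk, stats, trajectories, vim
from .simulate import CohortConfig, generate_cohort

log = logging.getLogger("lipidtraj")

STAGES = ("simulate", "derive", "match", "trajectories", "vim",
          "associations", "mixed", "risk", "report")


@dataclass
class PipelineConfig:
    outdir: str = "lipidtraj_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_name: str = "AD"
    trajectory_lipids: tuple = ("hdl",)
    vim_lipids: tuple = ("tc", "hdl", "ldl", "non_hdl", "ln_tg")
    sweep_groups: tuple = (1, 2, 3, 4)
    sweep_orders: tuple = (0, 1, 2)
    n_starts: int = 6
    match_ratio: int = 4
    mixed_response: str = "hdl"
    mixed_candidates: tuple = ("female", "on_med", "bmi", "prs_hdl_std")
    mixed_locked: tuple = ("age",)
    risk_margin_grid: tuple = (-2.0, -1.0, 0.0, 1.0, 2.0)
    # With variable-ratio matched sets the ATT weight identifies cases
    # in-sample; keep it out of the AUROC-compared covariate sets by default.
    include_weight_covariate: bool = False
    make_plots: bool = True

    def validate(self):
        self.cohort.validate()

    @classmethod
    def from_yaml(cls, path):
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if cohort_raw:
            cfg.cohort = _cohort_from_dict(cohort_raw)
        return cfg


def _cohort_from_dict(d: dict) -> CohortConfig:
    from .simulate import GroupSpec, LipidSpec, OutcomeModel, CovariateConfig
    d = dict(d)
    if "lipids" in d:
        lip = {}
        for name, spec in d["lipids"].items():
            groups = [GroupSpec(**g) if isinstance(g, dict) else GroupSpec(*g)
                      for g in spec.pop("groups")]
            lip[name] = LipidSpec(groups=groups, **spec)
        d["lipids"] = lip
    if "outcome" in d:
        d["outcome"] = OutcomeModel(**d["outcome"])
    if "covariates" in d:
        d["covariates"] = CovariateConfig(**d["covariates"])
    return CohortConfig(**d)


class _Context(dict):
    """Stage artifact cache with lazy CSV reload from the output directory."""

    def __init__(self, outdir: Path):
        super().__init__()
        self.outdir = outdir

    def load(self, key, fname, **kw):
        if key not in self:
            path = self.outdir / fname
            if not path.exists():
                raise FileNotFoundError(
                    f"stage artifact {fname} not found; run earlier stages first")
            self[key] = pd.read_csv(path, **kw)
        return self[key]


def _stage_simulate(cfg, ctx):
    cohort_cfg = cfg.cohort
    cohort_cfg.seed = cfg.seed
    cohort = generate_cohort(cohort_cfg)
    cohort.write(ctx.outdir)
    ctx["subjects"] = cohort.subjects
    ctx["measurements"] = cohort.measurements
    ctx["orders"] = cohort.orders
    return {"n_subjects": len(cohort.subjects),
            "n_measurements": len(cohort.measurements),
            "prevalence": cohort.prevalence}


def _stage_derive(cfg, ctx):
    meas = ctx.load("measurements", "measurements.csv")
    subjects = ctx.load("subjects", "subjects.csv")
    orders = ctx.load("orders", "orders.csv")
    eligible = derive.apply_inclusion_filter(meas)
    n_before = subjects["subject_id"].nunique()
    subjects = subjects[subjects["subject_id"].isin(eligible)].reset_index(drop=True)
    on_med = derive.medication_use_by_year(orders)
    annual = derive.aggregate_annual(meas, on_med=on_med)
    annual = annual[annual["subject_id"].isin(eligible)]
    for col in [c for c in subjects.columns if c.startswith("prs_")]:
        subjects[f"{col}_std"] = derive.standardize_scores(subjects[col])
    subjects["age_group"] = matching.age_group(subjects["age"]).astype(str)
    subjects["bmi_group"] = matching.bmi_group(subjects["bmi"]).astype(str)
    annual.to_csv(ctx.outdir / "annual_records.csv", index=False)
    subjects.to_csv(ctx.outdir / "subjects_derived.csv", index=False)
    ctx["annual"] = annual
    ctx["subjects_derived"] = subjects
    return {"n_subjects_in": n_before, "n_excluded_lt3_years": n_before - len(subjects),
            "n_subjects_eligible": len(subjects), "n_annual_records": len(annual)}


def _stage_match(cfg, ctx):
    subjects = ctx.load("subjects_derived", "subjects_derived.csv")
    spec = matching.MatchSpec(
        exact=("female", "age_group", "bmi_group", "on_med_at_index"),
        nearest=("race", "apoe_e2", "apoe_e4", "education"),
        ratio=cfg.match_ratio)
    cohort = matching.match(subjects, spec)
    cohort.table.to_csv(ctx.outdir / "matched.csv", index=False)
    cohort.balance.to_csv(ctx.outdir / "balance.csv", index=False)
    ctx["matched"] = cohort.table
    return {"n_sets": cohort.n_sets, "n_matched": len(cohort.table),
            "n_unmatched_cases": len(cohort.unmatched_cases),
            "ps_flagged": cohort.ps_flagged}


def _trajectory_data(ctx, lipid):
    annual = ctx.load("annual", "annual_records.csv")
    matched = ctx.load("matched", "matched.csv")
    d = annual[annual["subject_id"].isin(matched["subject_id"])]
    d = d[["subject_id", "rel_year", lipid, "on_med"]].dropna()
    d = d.rename(columns={lipid: "value"})
    counts = d.groupby("subject_id")["rel_year"].nunique()
    return d[d["subject_id"].isin(counts.index[counts >= 3])]


def _stage_trajectories(cfg, ctx):
    info = {}
    assignments = {}
    for lipid in cfg.trajectory_lipids:
        d = _trajectory_data(ctx, lipid)
        sweep = trajectories.sweep_and_select(
            d, groups=cfg.sweep_groups, orders=cfg.sweep_orders,
            n_starts=cfg.n_starts, seed=cfg.seed)
        sweep.report.to_csv(ctx.outdir / f"trajectory_sweep_{lipid}.csv", index=False)
        if sweep.status != "ok":
            info[lipid] = {"status": sweep.status}
            continue
        fit = sweep.chosen
        fit.fitted_curves().to_csv(ctx.outdir / f"trajectory_curves_{lipid}.csv", index=False)
        assignments[lipid] = fit.assignments
        pd.DataFrame({"subject_id": fit.assignments.index,
                      "group": fit.assignments.to_numpy()}).to_csv(
            ctx.outdir / f"trajectory_groups_{lipid}.csv", index=False)
        info[lipid] = {"status": "ok", "n_groups": int(len(fit.pi)),
                       "bic": fit.bic, "min_app": float(np.nanmin(fit.app)),
                       "shares": fit.shares.tolist()}
    ctx["trajectory_assignments"] = assignments
    return info


def _stage_vim(cfg, ctx):
    annual = ctx.load("annual", "annual_records.csv")
    matched = ctx.load("matched", "matched.csv")
    d = annual[annual["subject_id"].isin(matched["subject_id"])]
    long = d.melt(id_vars=["subject_id", "rel_year"],
                  value_vars=[l for l in cfg.vim_lipids if l in d.columns],
                  var_name="lipid", value_name="value").dropna()
    table = vim.vim_table(long, [l for l in cfg.vim_lipids if l in d.columns])
    table.to_csv(ctx.outdir / "vim.csv", index=False)
    ctx["vim"] = table
    return {lipid: {"exponent": float(table[table["lipid"] == lipid]["exponent"].iloc[0]),
                    "n": int((table["lipid"] == lipid).sum())}
            for lipid in table["lipid"].unique()}


def _analysis_frame(cfg, ctx):
    """Matched subjects merged with fitted trajectory groups and VIM quintiles."""
    subjects = ctx.load("subjects_derived", "subjects_derived.csv")
    matched = ctx.load("matched", "matched.csv")
    df = subjects.merge(matched[["subject_id", "set_id", "weight"]], on="subject_id")
    assignments = ctx.get("trajectory_assignments", {})
    for lipid in cfg.trajectory_lipids:
        path = ctx.outdir / f"trajectory_groups_{lipid}.csv"
        if lipid in assignments:
            ser = assignments[lipid]
            df[f"{lipid}_group_fit"] = df["subject_id"].map(ser)
        elif path.exists():
            g = pd.read_csv(path)
            df[f"{lipid}_group_fit"] = df["subject_id"].map(
                g.set_index("subject_id")["group"])
    if "vim" in ctx or (ctx.outdir / "vim.csv").exists():
        vt = ctx.load("vim", "vim.csv")
        for lipid in vt["lipid"].unique():
            sub = vt[vt["lipid"] == lipid].set_index("subject_id")
            df[f"{lipid}_vim_q1_fit"] = (
                df["subject_id"].map(sub["quintile"]) == 1).astype(float)
    return df


def _stage_associations(cfg, ctx):
    df = _analysis_frame(cfg, ctx)
    cat_vars = [c for c in ("female", "education", "race", "apoe_e4",
                            "hypertension", "cerebrovascular", "diabetes")
                if c in df.columns]
    t1 = stats.cohort_table(df, "case", cat_vars)
    t1.to_csv(ctx.outdir / "cohort_table.csv", index=False)
    group_cols = [c for c in df.columns
                  if c.endswith("_group_fit") or c.endswith("_vim_q1_fit")]
    group_cols = [c for c in group_cols if df[c].notna().all() and df[c].nunique() > 1]
    if group_cols:
        assoc = stats.group_association_table(df, "case", group_cols)
        assoc.to_csv(ctx.outdir / "group_associations.csv", index=False)
    return {"n_variables": len(cat_vars), "n_groupings": len(group_cols)}


def _stage_mixed(cfg, ctx):
    annual = ctx.load("annual", "annual_records.csv")
    subjects = ctx.load("subjects_derived", "subjects_derived.csv")
    d = annual.merge(subjects, on="subject_id", suffixes=("", "_subj"))
    d["age"] = d["age"] + d["rel_year"]          # age at measurement year
    d["on_med"] = d["on_med"].astype(float)
    resp = cfg.mixed_response
    candidates = [c for c in cfg.mixed_candidates
                  if c in d.columns or not c.isidentifier()]
    sel = mixed.backward_select_mixed(d.dropna(subset=[resp]), resp,
                                      candidates, locked=list(cfg.mixed_locked))
    sel.fit.table.to_csv(ctx.outdir / f"mixed_{resp}.csv", index=False)
    trace = pd.DataFrame(sel.trace, columns=["dropped", "aic"])
    trace.to_csv(ctx.outdir / f"mixed_{resp}_trace.csv", index=False)
    return {"response": resp, "final_terms": sel.terms, "aic": sel.aic}


def _stage_risk(cfg, ctx):
    df = _analysis_frame(cfg, ctx)
    df = df.dropna(axis=1, how="all")
    base_cols = ["age_c", "female", "educ_gt12"]
    if cfg.include_weight_covariate:
        base_cols.append("weight")
    base = [t for t in base_cols if t in df.columns]
    lipid_terms = []
    for lipid in cfg.trajectory_lipids:
        col = f"{lipid}_group_fit"
        if col in df.columns and df[col].notna().all() and df[col].nunique() > 1:
            ref = int(df[col].max())            # highest-level group as reference
            lipid_terms.append(f"C({col}, Treatment(reference={ref}))")
    for col in [c for c in df.columns if c.endswith("_vim_q1_fit")][:1]:
        if df[col].nunique() > 1:
            lipid_terms.append(col)
    gen_terms = [t for t in ("prs_ad_std", "prs_tc_std", "apoe_e4") if t in df.columns]
    sets = {"base": base,
            "base_lipids": base + lipid_terms,
            "base_genetics": base + gen_terms,
            "base_lipids_genetics": base + lipid_terms + gen_terms}
    fits, info = {}, {}
    for name, terms in sets.items():
        fit = risk.fit_logistic_cluster(df, "case", terms, cluster="set_id")
        fits[name] = fit
        hl = risk.hosmer_lemeshow(fit.y, fit.fitted)
        lt = risk.link_test(fit)
        fit.table.to_csv(ctx.outdir / f"risk_{name}.csv", index=False)
        info[name] = {"auroc": fit.auroc, "aic": fit.aic,
                      "pseudo_r2": fit.pseudo_r2,
                      "hosmer_lemeshow_p": hl[2], "link_test_ok": lt.ok}
    comp = risk.compare_aurocs(fits["base"].y,
                               [fits[n].fitted for n in sets], labels=list(sets))
    comp["pairwise"].to_csv(ctx.outdir / "auroc_comparison.csv", index=False)
    info["auroc_equality_p"] = comp["p_equality"]
    full = fits["base_lipids_genetics"]
    if "prs_ad_std" in df.columns and "prs_ad_std" in full.formula:
        margins = risk.predictive_margins(
            full, {"prs_ad_std": list(cfg.risk_margin_grid)}, mode="at_means")
        margins.to_csv(ctx.outdir / "margins_prs_ad.csv", index=False)
    ctx["risk_fits"] = fits
    return info


def _stage_report(cfg, ctx):
    made = []
    if cfg.make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for lipid in cfg.trajectory_lipids:
            path = ctx.outdir / f"trajectory_curves_{lipid}.csv"
            if not path.exists():
                continue
            curves = pd.read_csv(path)
            fig, ax = plt.subplots(figsize=(6, 4))
            for g, sub in curves.groupby("group"):
                ax.plot(sub["rel_year"], sub["mean"], marker="o", label=f"group {g}")
                ax.fill_between(sub["rel_year"], sub["lo"], sub["hi"], alpha=0.2)
            ax.set_xlabel("years before index")
            ax.set_ylabel(f"{lipid} (mg/dl)")
            ax.legend()
            out = ctx.outdir / f"trajectories_{lipid}.svg"
            fig.savefig(out)
            plt.close(fig)
            made.append(out.name)
    return {"plots": made}


_STAGE_FNS = {
    "simulate": _stage_simulate, "derive": _stage_derive, "match": _stage_match,
    "trajectories": _stage_trajectories, "vim": _stage_vim,
    "associations": _stage_associations, "mixed": _stage_mixed,
    "risk": _stage_risk, "report": _stage_report,
}


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Execute the requested stages in order and write the run manifest.

    A stage failure is recorded in the manifest (partial completion) and
    re-raised after the manifest is written.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = _Context(outdir)
    manifest = {"seed": cfg.seed, "cohort_name": cfg.cohort_name,
                "stages": {}, "status": "ok"}
    from . import __version__
    manifest["version"] = __version__
    todo = [s for s in STAGES if stages is None or s in stages]
    failure = None
    for name in todo:
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            info = _STAGE_FNS[name](cfg, ctx)
            manifest["stages"][name] = {"status": "ok", "seconds": round(time.perf_counter() - t0, 3),
                                        "info": _jsonable(info)}
        except Exception as exc:                          # noqa: BLE001
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            manifest["status"] = "partial"
            failure = exc
            log.error("stage %s failed: %s", name, exc)
            break
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    if failure is not None:
        raise failure
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
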