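"""EHR-style derived variables.

Medication-use inference from order states, lipid algebra (Friedewald LDL-C,
non-HDL-C, log triglycerides), ICD-prefix comorbidity flags, the >=3-distinct-year
inclusion filter, annual aggregation of repeated same-year measurements, and
within-cohort score standardization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CHOLESTEROL_MEDICATIONS",
    "QUALIFYING_STATUSES",
    "ORDER_STATUSES",
    "MedicationOrder",
    "infer_medication_use",
    "medication_use_by_year",
    "derive_lipids",
    "load_icd_prefixes",
    "comorbidity_flags",
    "comorbidity_table",
    "apply_inclusion_filter",
    "aggregate_annual",
    "standardize_scores",
    "RELATIVE_YEARS",
]

#: Relative-year axis: 0 is the index year (first cognitive symptom in cases,
#: match age in controls); measurements span the decade before it.
RELATIVE_YEARS = tuple(range(-10, 1))

#: Cholesterol-lowering medications tracked in order tables.
CHOLESTEROL_MEDICATIONS = (
    "atorvastatin", "simvastatin", "rosuvastatin", "pravastatin",
    "lovastatin", "fluvastatin", "pitavastatin",
    "gemfibrozil", "fenofibrate", "clofibrate", "bempedoic acid",
    "ezetimibe", "cholestyramine", "colestipol", "colesevelam",
    "alirocumab", "evolocumab",
)

QUALIFYING_STATUSES = frozenset({"Sent", "Dispensed", "Verified"})
ORDER_STATUSES = QUALIFYING_STATUSES | {"Discontinued"}

#: Friedewald validity bound for triglycerides, mg/dl.
FRIEDEWALD_TG_MAX = 400.0


@dataclass(frozen=True)
class MedicationOrder:
    subject_id: object
    medication: str
    status: str
    year: int

    def __post_init__(self):
        if self.status not in ORDER_STATUSES:
            raise ValueError(
                f"unknown medication order status {self.status!r}; "
                f"expected one of {sorted(ORDER_STATUSES)}"
            )


def infer_medication_use(orders, year: int) -> bool:
    """True iff a cholesterol-lowering medication order is active at ``year``.

    An order is active if some qualifying order (Sent/Dispensed/Verified) was
    placed at or before ``year`` and it was not discontinued before ``year`` --
    a discontinuation being ignored when another qualifying order was placed at
    or after it (replacement).  Equivalently: the latest qualifying order at or
    before ``year`` must not precede the latest discontinuation strictly before
    ``year``.
    """
    q_years, d_years = [], []
    for o in orders:
        status = o.status if hasattr(o, "status") else o["status"]
        oyear = o.year if hasattr(o, "year") else o["year"]
        if status not in ORDER_STATUSES:
            raise ValueError(f"unknown medication order status {status!r}")
        if status == "Discontinued":
            if oyear < year:
                d_years.append(oyear)
        elif oyear <= year:
            q_years.append(oyear)
    if not q_years:
        return False
    return not d_years or max(q_years) >= max(d_years)


def medication_use_by_year(orders: pd.DataFrame, years=RELATIVE_YEARS) -> pd.DataFrame:
    """Per-subject on-medication flags over ``years`` from an order table.

    ``orders`` needs columns subject_id, status, year.  Returns a boolean frame
    indexed by subject_id with one column per year.
    """
    bad = set(orders["status"]) - ORDER_STATUSES
    if bad:
        raise ValueError(f"unknown medication order status(es): {sorted(bad)}")
    out = {}
    for sid, grp in orders.groupby("subject_id", sort=True):
        recs = grp.to_dict("records")
        out[sid] = [infer_medication_use(recs, y) for y in years]
    return pd.DataFrame.from_dict(out, orient="index", columns=list(years)).rename_axis("subject_id")


def derive_lipids(tc, hdl, tg, ldl_recorded=None):
    """Derive (ldl, non_hdl, ln_tg, valid) from TC/HDL-C/TG in mg/dl.

    non_hdl = tc - hdl.  LDL-C is the recorded value when present, otherwise
    Friedewald tc - hdl - tg/5, valid only for tg <= 400 (else NaN, flagged
    missing rather than raised).  ln_tg is the natural log.  ``valid`` is False
    when hdl >= tc.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tc <= 0) or np.any(hdl <= 0) or np.any(tg <= 0):
        raise ValueError("tc, hdl and tg must be positive (mg/dl)")
    non_hdl = tc - hdl
    ln_tg = np.log(tg)
    friedewald = np.where(tg <= FRIEDEWALD_TG_MAX, tc - hdl - tg / 5.0, np.nan)
    if ldl_recorded is None:
        ldl = friedewald
    else:
        rec = np.asarray(ldl_recorded, dtype=float)
        ldl = np.where(np.isnan(rec), friedewald, rec)
    valid = hdl < tc
    if np.ndim(tc) == 0:
        return float(ldl), float(non_hdl), float(ln_tg), bool(valid)
    return ldl, non_hdl, ln_tg, valid


def _expand_range(token: str):
    """Expand an inclusive prefix range like '401-403' or 'I10-I16'."""
    lo, hi = token.split("-")
    lo, hi = lo.strip(), hi.strip()
    if lo[0].isalpha():
        letter = lo[0]
        if hi[0] != letter:
            raise ValueError(f"cannot expand range {token!r}")
        width = len(lo) - 1
        return [f"{letter}{i:0{width}d}" for i in range(int(lo[1:]), int(hi[1:]) + 1)]
    width = len(lo)
    return [f"{i:0{width}d}" for i in range(int(lo), int(hi) + 1)]


def load_icd_prefixes() -> dict:
    """Load the versioned ICD prefix lists shipped with the package.

    Prefixes are dot-stripped and upper-cased; ranges are expanded.
    """
    text = resources.files("lipidtraj.data").joinpath("icd_codes.txt").read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, rest = line.partition(":")
        prefixes = []
        for token in rest.split(","):
            token = token.strip()
            if "-" in token:
                prefixes.extend(_expand_range(token))
            else:
                prefixes.append(token)
        table[name.strip()] = tuple(p.replace(".", "").upper() for p in prefixes)
    return table


_ICD_PREFIXES = None


def _icd_prefixes():
    global _ICD_PREFIXES
    if _ICD_PREFIXES is None:
        _ICD_PREFIXES = load_icd_prefixes()
    return _ICD_PREFIXES


def comorbidity_flags(icd_codes) -> dict:
    """Boolean flag per condition from a subject's list of ICD code strings.

    Matching is by string prefix after stripping dots; unmatched codes are
    ignored.  A code may flag several conditions (e.g. I25- appears in both the
    atherosclerosis and ischemic-heart-disease lists).
    """
    norm = [str(c).replace(".", "").upper() for c in icd_codes]
    out = {}
    for cond, prefixes in _icd_prefixes().items():
        out[cond] = any(code.startswith(p) for code in norm for p in prefixes)
    return out


def comorbidity_table(codes_by_subject: dict) -> pd.DataFrame:
    """Vectorized ``comorbidity_flags`` over a {subject_id: [codes]} mapping."""
    rows = {sid: comorbidity_flags(codes) for sid, codes in codes_by_subject.items()}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject_id")


def apply_inclusion_filter(measurements: pd.DataFrame,
                           subject_col="subject_id", year_col="rel_year"):
    """Subjects with >=3 distinct measured relative years within -10..0."""
    m = measurements[measurements[year_col].between(RELATIVE_YEARS[0], RELATIVE_YEARS[-1])]
    n_years = m.groupby(subject_col)[year_col].nunique()
    return pd.Index(n_years.index[n_years >= 3], name=subject_col)


def aggregate_annual(measurements: pd.DataFrame, on_med: pd.DataFrame | None = None) -> pd.DataFrame:
    """One annual lipid record per subject-year from a long measurement table.

    ``measurements`` columns: subject_id, rel_year, lipid (tc/hdl/tg/ldl),
    value.  Same-year duplicates are averaged on the raw scale *before* any
    transformation; LDL-C and non-HDL-C are then derived where TC/HDL/TG are
    all present (a recorded ldl row takes precedence over Friedewald).
    ``on_med`` is an optional frame from :func:`medication_use_by_year`.
    """
    wide = (measurements
            .groupby(["subject_id", "rel_year", "lipid"])["value"].mean()
            .unstack("lipid"))
    for col in ("tc", "hdl", "tg"):
        if col not in wide:
            wide[col] = np.nan
    rec_ldl = wide["ldl"] if "ldl" in wide else pd.Series(np.nan, index=wide.index)
    ok = wide[["tc", "hdl", "tg"]].notna().all(axis=1)
    out = wide.loc[ok, ["tc", "hdl", "tg"]].copy()
    ldl, non_hdl, ln_tg, valid = derive_lipids(
        out["tc"].to_numpy(), out["hdl"].to_numpy(), out["tg"].to_numpy(),
        rec_ldl[ok].to_numpy(),
    )
    out["ldl"] = ldl
    out["non_hdl"] = non_hdl
    out["ln_tg"] = ln_tg
    out["valid"] = valid
    out = out.reset_index()
    if on_med is not None:
        med_long = on_med.stack()
        out["on_med"] = [
            bool(med_long.get((s, y), False))
            for s, y in zip(out["subject_id"], out["rel_year"])
        ]
    return out


def standardize_scores(scores) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (within-cohort convention)."""
    x = np.asarray(scores, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant score vector")
    return (x - x.mean()) / sd
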