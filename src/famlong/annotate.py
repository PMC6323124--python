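"""Turn a person table into analysis rows.

For each analysis unit (index person, child, or spouse) this module resolves
the relevant relatives, converts their observed ages into birth-cohort
survival percentiles, and derives

* top-x exposure counts (parents exact 0/1/2; siblings and aunts/uncles
  capped at the 2+ category),
* mutually exclusive percentile groups g1..g6 defined by the most long-lived
  relative: (0,1], (1,5], (5,10], (10,15], (15,20], (20,100] — "belonging to
  percentile p" always means percentile <= p, so a relative at exactly the 1st
  percentile sits in g1,
* analytical weights w = k/S (qualifying siblings over classifiable sibship
  size) that stop large sibships from dominating extreme exposure categories,
* left-truncation entry ages (later of marriage and first child for IPs and
  spouses; 0 for children, who were not selected on anything).

Relatives with no known age are excluded from numerators and denominators
alike; exclusion ledgers account for every input unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetables import LifetableCollection, observed_percentile

__all__ = [
    "GROUP_BOUNDS",
    "assign_exclusive_group",
    "compute_analytical_weight",
    "count_top_x_relatives",
    "entry_age",
    "annotate_ips",
    "annotate_children",
    "annotate_spouses",
    "counts_at",
    "build_analysis_table",
]

GROUP_BOUNDS = (1.0, 5.0, 10.0, 15.0, 20.0)


def assign_exclusive_group(percentiles) -> int:
    """Group index 1..6 from the minimum (most long-lived) relative percentile.

    Raises ValueError when no classifiable relative is supplied.
    """
    pcts = [p for p in percentiles if p is not None and not math.isnan(p)]
    if not pcts:
        raise ValueError("no classifiable relative: group undefined")
    p_star = min(pcts)
    for g, bound in enumerate(GROUP_BOUNDS, start=1):
        if p_star <= bound:
            return g
    return 6


def compute_analytical_weight(k: int, s: int, reference_weight: str = "one") -> float:
    """w = k/S for units with k >= 1 qualifying siblings out of S classifiable.

    Units in the reference category (k = 0) carry weight 1 by default so the
    comparison group is retained at full size; ``reference_weight='inv_s'``
    gives them 1/S instead.
    """
    if s < 1:
        raise ValueError("weight undefined for sibships with no classifiable sibling")
    if k == 0:
        return 1.0 if reference_weight == "one" else 1.0 / s
    return k / s


def count_top_x_relatives(parent_pcts, sib_pcts, x: float) -> dict:
    """Exposure counts at threshold x: parents exact, siblings capped at 2+."""
    pp = [p for p in parent_pcts if not math.isnan(p)]
    sp = [p for p in sib_pcts if not math.isnan(p)]
    n_par = sum(p <= x for p in pp)
    k = sum(p <= x for p in sp)
    return {
        "n_top_parents": n_par,
        "n_top_sibs": min(k, 2),
        "k_sibs": k,
        "s_sibs": len(sp),
    }


def entry_age(marriage_age, first_child_age) -> float:
    """Later of the available marriage / first-child ages; NaN when neither."""
    vals = [v for v in (marriage_age, first_child_age) if v is not None and not _nan(v)]
    return max(vals) if vals else float("nan")


def _nan(v) -> bool:
    try:
        return math.isnan(float(v))
    except (TypeError, ValueError):
        return False


@dataclass
class ExclusionLedger:
    total_units: int = 0
    retained: int = 0
    reasons: dict = field(default_factory=dict)

    def exclude(self, reason: str, n: int = 1) -> None:
        self.reasons[reason] = self.reasons.get(reason, 0) + n

    def as_dict(self) -> dict:
        return {
            "total_units": self.total_units,
            "retained": self.retained,
            "excluded": dict(self.reasons),
        }


def _sib_pct_by_family(sibs: pd.DataFrame, tables: LifetableCollection,
                       interpolate: bool) -> dict:
    """family_id -> sorted array of classifiable sibling percentiles."""
    acc: dict = {}
    for r in sibs.itertuples():
        p = observed_percentile(r.sex, r.birth_year, r.death_age, r.censor_age,
                                tables, interpolate)
        if not math.isnan(p):
            acc.setdefault(r.family_id, []).append(p)
    return {fid: np.sort(v) for fid, v in acc.items()}


def _person_lookup(table: pd.DataFrame) -> dict:
    """person_id -> (sex, birth_year, death_age, censor_age)."""
    return {
        r.person_id: (r.sex, r.birth_year, r.death_age, r.censor_age)
        for r in table.itertuples()
    }


def _with_covariates(units: pd.DataFrame, center_year: float = 1850.0) -> pd.DataFrame:
    """Numeric model covariates: encoded sex, centred birth year, SES score
    with the missing code mean-imputed, raw demographic columns mean-filled."""
    out = units.copy()
    out["female"] = (out["sex"] == "F").astype(float)
    out["birth_year_c"] = out["birth_year"].astype(float) - center_year
    ses = out["ses"].astype(float)
    out["ses_score"] = pd.Series(np.where(ses == 999, np.nan, ses), index=out.index)
    rel = out["religion"].astype(float) if "religion" in out else pd.Series(np.nan, index=out.index)
    out["religion"] = rel.where(rel >= 0)
    numeric = ["sibship_size", "mother_age_at_birth", "birth_order",
               "birth_interval", "twin", "ses_score", "religion"]
    for c in numeric:
        out[c] = pd.to_numeric(out[c], errors="coerce")
        fill = out[c].mean()
        out[c] = out[c].fillna(0.0 if np.isnan(fill) else fill)
    return out


def annotate_ips(
    table: pd.DataFrame, tables: LifetableCollection, interpolate: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Per-IP analysis frame with relative percentiles, entry/exit and covariates.

    Sibling and parent percentiles are attached as sorted arrays (columns
    ``sib_pcts`` / ``parent_pcts``) so any top-x threshold or grouping can be
    derived without re-walking the pedigree.
    """
    ledger = ExclusionLedger()
    ips = table[table["role"] == "ip"]
    ledger.total_units = len(ips)
    persons = _person_lookup(table)
    sibs = table[(table["generation"] == "F2") & (table["role"] == "sibling")]
    sib_arrays = _sib_pct_by_family(sibs, tables, interpolate)
    empty = np.array([])

    rows = []
    for ip in ips.itertuples():
        exit_age = ip.death_age
        if _nan(exit_age):
            ledger.exclude("ip_missing_death_age")
            continue
        ent = entry_age(ip.marriage_age, ip.first_child_age)
        if _nan(ent):
            ledger.exclude("ip_missing_entry_age")
            continue
        if not ent < exit_age:
            ledger.exclude("entry_not_before_exit")
            continue
        pp = []
        lineage = {}
        for label, pid in (("mother_pct", ip.mother_id), ("father_pct", ip.father_id)):
            pct = float("nan")
            if not _nan(pid) and pid in persons:
                sex, by, da, ca = persons[pid]
                pct = observed_percentile(sex, by, da, ca, tables, interpolate)
            lineage[label] = pct
            if not math.isnan(pct):
                pp.append(pct)
        pp = np.sort(pp)
        sp = sib_arrays.get(ip.family_id, empty)
        rows.append({
            "unit_id": ip.person_id, "family_id": ip.family_id,
            "entry_age": float(ent), "exit_age": float(exit_age), "event": 1,
            "parent_pcts": pp, "sib_pcts": sp,
            "mother_pct": lineage["mother_pct"], "father_pct": lineage["father_pct"],
            "sex": ip.sex, "birth_year": ip.birth_year,
            "sibship_size": ip.sibship_size, "ses": ip.ses,
            "religion": getattr(ip, "religion", np.nan),
            "mother_age_at_birth": ip.mother_age_at_birth,
            "birth_order": ip.birth_order, "birth_interval": ip.birth_interval,
            "twin": ip.twin,
        })
    df = pd.DataFrame(rows)
    ledger.retained = len(df)
    if len(df):
        df = _with_covariates(df.reset_index(drop=True))
    return df, ledger.as_dict()


def counts_at(ann: pd.DataFrame, x: float, reference_weight: str = "one") -> pd.DataFrame:
    """Top-x exposure counts and cumulative-analysis weights for annotated units.

    Counts are non-decreasing in x by construction (nesting of top-x sets).
    """
    n_par = np.fromiter(
        (np.searchsorted(p, x, side="right") for p in ann["parent_pcts"]), int, len(ann))
    k = np.fromiter(
        (np.searchsorted(p, x, side="right") for p in ann["sib_pcts"]), int, len(ann))
    s = np.fromiter((len(p) for p in ann["sib_pcts"]), int, len(ann))
    w = np.where(k == 0,
                 1.0 if reference_weight == "one" else 1.0 / np.maximum(s, 1),
                 k / np.maximum(s, 1))
    out = ann.copy()
    out["n_top_parents"] = n_par
    out["n_top_sibs"] = np.minimum(k, 2)
    out["k_sibs"] = k
    out["s_sibs"] = s
    out["weight"] = w
    return out


def group_assignments(ann: pd.DataFrame, kind: str,
                      reference_weight: str = "one") -> pd.DataFrame:
    """Exclusive group g1..g6 (NaN when no classifiable relative of the kind)
    plus the exclusive-group analytical weight for sibling groupings."""
    col = "sib_pcts" if kind == "siblings" else "parent_pcts"
    groups, weights = [], []
    for p in ann[col]:
        if len(p) == 0:
            groups.append(np.nan)
            weights.append(np.nan)
            continue
        g = assign_exclusive_group(p)
        groups.append(g)
        if kind == "siblings":
            lo = 0.0 if g == 1 else GROUP_BOUNDS[g - 2] if g <= 5 else GROUP_BOUNDS[-1]
            hi = GROUP_BOUNDS[g - 1] if g <= 5 else 100.0
            k = int(np.sum((p > lo) & (p <= hi))) if g > 1 else int(np.sum(p <= hi))
            weights.append(compute_analytical_weight(k, len(p), reference_weight))
        else:
            weights.append(1.0)
    out = ann.copy()
    out["group"] = groups
    out["group_weight"] = weights
    return out


def annotate_children(
    table: pd.DataFrame, tables: LifetableCollection, interpolate: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Per-F3-child frame: top-10-style exposures come from the IP (a parent),
    the IP's spouse (the other parent) and the IP's siblings (aunts/uncles).
    Children enter the risk set at birth."""
    ledger = ExclusionLedger()
    kids = table[table["role"] == "child"]
    ledger.total_units = len(kids)
    sibs = table[(table["generation"] == "F2") & (table["role"] == "sibling")]
    sib_arrays = _sib_pct_by_family(sibs, tables, interpolate)
    empty = np.array([])
    ip_pct = {
        r.family_id: observed_percentile(r.sex, r.birth_year, r.death_age,
                                         r.censor_age, tables, interpolate)
        for r in table[table["role"] == "ip"].itertuples()
    }
    sp_pct = {
        r.family_id: observed_percentile(r.sex, r.birth_year, r.death_age,
                                         r.censor_age, tables, interpolate)
        for r in table[table["role"] == "spouse"].itertuples()
    }

    rows = []
    for kid in kids.itertuples():
        death, censor = kid.death_age, kid.censor_age
        if _nan(death) and _nan(censor):
            ledger.exclude("child_missing_age")
            continue
        exit_age = death if not _nan(death) else censor
        if not exit_age > 0:
            ledger.exclude("entry_not_before_exit")
            continue
        fid = kid.family_id
        if fid not in ip_pct:
            ledger.exclude("no_ip_in_family")
            continue
        au = sib_arrays.get(fid, empty)
        rows.append({
            "unit_id": kid.person_id, "family_id": fid,
            "entry_age": 0.0, "exit_age": float(exit_age),
            "event": int(not _nan(death)),
            "ip_pct": ip_pct[fid], "spouse_pct": sp_pct.get(fid, np.nan),
            "auntuncle_pcts": au,
            "sex": kid.sex, "birth_year": kid.birth_year,
            "sibship_size": kid.sibship_size, "ses": kid.ses,
            "religion": getattr(kid, "religion", np.nan),
            "mother_age_at_birth": kid.mother_age_at_birth,
            "birth_order": kid.birth_order, "birth_interval": kid.birth_interval,
            "twin": kid.twin,
        })
    df = pd.DataFrame(rows)
    ledger.retained = len(df)
    if len(df):
        df = _with_covariates(df.reset_index(drop=True))
    return df, ledger.as_dict()


def annotate_spouses(
    table: pd.DataFrame, tables: LifetableCollection, interpolate: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Per-spouse frame grouped by the IP's own survival percentile."""
    ledger = ExclusionLedger()
    spouses = table[table["role"] == "spouse"]
    ledger.total_units = len(spouses)
    ip_pct = {
        r.family_id: observed_percentile(r.sex, r.birth_year, r.death_age,
                                         r.censor_age, tables, interpolate)
        for r in table[table["role"] == "ip"].itertuples()
    }
    rows = []
    for sp in spouses.itertuples():
        death, censor = sp.death_age, sp.censor_age
        if _nan(death) and _nan(censor):
            ledger.exclude("spouse_missing_age")
            continue
        exit_age = death if not _nan(death) else censor
        ent = entry_age(sp.marriage_age, sp.first_child_age)
        if _nan(ent):
            ledger.exclude("spouse_missing_entry_age")
            continue
        if not ent < exit_age:
            ledger.exclude("entry_not_before_exit")
            continue
        fid = sp.family_id
        if fid not in ip_pct or math.isnan(ip_pct[fid]):
            ledger.exclude("ip_percentile_unknown")
            continue
        rows.append({
            "unit_id": sp.person_id, "family_id": fid,
            "entry_age": float(ent), "exit_age": float(exit_age),
            "event": int(not _nan(death)),
            "ip_pct": ip_pct[fid], "group": assign_exclusive_group([ip_pct[fid]]),
            "sex": sp.sex, "birth_year": sp.birth_year,
            "sibship_size": sp.sibship_size, "ses": sp.ses,
            "religion": getattr(sp, "religion", np.nan),
            "mother_age_at_birth": sp.mother_age_at_birth,
            "birth_order": sp.birth_order, "birth_interval": sp.birth_interval,
            "twin": sp.twin,
        })
    df = pd.DataFrame(rows)
    ledger.retained = len(df)
    if len(df):
        df = _with_covariates(df.reset_index(drop=True))
    return df, ledger.as_dict()


def build_analysis_table(
    table: pd.DataFrame,
    tables: LifetableCollection,
    target: str = "ip",
    x: float = 10.0,
    interpolate: bool = False,
    reference_weight: str = "one",
) -> tuple[pd.DataFrame, dict]:
    """One analysis row per unit of the requested target with top-x exposures,
    weights, entry/exit ages, event flag and covariates, plus an exclusion
    ledger whose totals reconcile with the input unit count."""
    if target == "ip":
        ann, ledger = annotate_ips(table, tables, interpolate)
        if len(ann):
            ann = counts_at(ann, x, reference_weight)
        return ann, ledger
    if target == "children":
        ann, ledger = annotate_children(table, tables, interpolate)
        if len(ann):
            ann["ip_top"] = (ann["ip_pct"] <= x).astype(int)
            sp = ann["spouse_pct"]
            ann["spouse_top"] = np.where(sp.isna(), 0, (sp <= x).astype(int))
            k = np.fromiter((np.searchsorted(p, x, side="right")
                             for p in ann["auntuncle_pcts"]), int, len(ann))
            ann["n_top_auntuncles"] = np.minimum(k, 2)
        return ann, ledger
    if target == "spouses":
        return annotate_spouses(table, tables, interpolate)
    raise ValueError(f"unknown target {target!r}")
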