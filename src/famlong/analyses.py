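"""The five family-longevity analyses and threshold detection.

1. *Cumulative percentile sweep* — for each x in 1..60, Cox regressions of IP
   survival on the number of top-x parents (unweighted) and, separately, the
   number of top-x siblings (analytically weighted), each cross-adjusted for
   the top-10% count of the other relative kind and the covariate list.
2. *Mutually exclusive groups* — IPs grouped g1..g6 by their most long-lived
   parent or sibling, g1..g5 compared against reference g6; the longevity
   threshold is the upper percentile bound of the highest-index group showing
   a significant survival advantage (non-significant more-extreme groups are
   treated as power gaps, not vetoes).
3. *Top-10% integrated design* — joint fit of parent and sibling top-10%
   counts, plus a companion fit restricted to IPs without top-10% parents.
4. *Children verification* — log-normal shared-frailty Cox of F3 survival on
   top-10% IP, spouse, and aunt/uncle exposures, random intercept per family.
5. *Spouse analysis* — spouses grouped by IP survival percentile, compared to
   group 6 and post-hoc over all 15 pairs with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import (
    GROUP_BOUNDS,
    annotate_children,
    annotate_ips,
    annotate_spouses,
    counts_at,
    group_assignments,
)
from .cox import (
    CoxModel,
    CoxResults,
    SharedFrailtyCoxModel,
    bonferroni_posthoc,
)
from .lifetables import LifetableCollection

__all__ = [
    "SweepResult",
    "ThresholdResult",
    "run_percentile_sweep",
    "max_effect",
    "run_exclusive_groups",
    "run_top10_integrated",
    "run_children_verification",
    "run_spouse_analysis",
    "run_sensitivity_variants",
    "run_all",
]

IP_COVARIATES = [
    "female", "birth_year_c", "sibship_size", "ses_score", "mother_age_at_birth",
    "birth_order", "birth_interval", "twin", "religion",
]


def _covs(df: pd.DataFrame, exclude: tuple[str, ...] = ()) -> list[str]:
    return [c for c in IP_COVARIATES
            if c in df.columns and c not in exclude and df[c].nunique() > 1]


def _dummies(df: pd.DataFrame, col: str, levels: dict[str, object]) -> tuple[pd.DataFrame, list[str]]:
    """Indicator columns for the given levels; all-zero levels are dropped."""
    out = df.copy()
    kept = []
    for name, lev in levels.items():
        v = (df[col] == lev).astype(float)
        if v.sum() > 0 and v.sum() < len(v):
            out[name] = v
            kept.append(name)
    return out, kept


@dataclass
class SweepResult:
    """Tidy per-(x, kind, level) hazard-ratio table for the cumulative sweep."""

    frame: pd.DataFrame
    x_values: list[int]
    cross_adjust_x: float | None

    def at(self, x: int, kind: str) -> pd.DataFrame:
        return self.frame[(self.frame["x"] == x) & (self.frame["kind"] == kind)]


@dataclass
class ThresholdResult:
    relative_kind: str
    threshold_percentile: float | None
    trail: pd.DataFrame = field(repr=False)


def run_percentile_sweep(
    table: pd.DataFrame,
    tables: LifetableCollection,
    x_values=range(1, 61),
    cross_adjust_x: float | None = 10.0,
    interpolate: bool = False,
    reference_weight: str = "one",
    ann: pd.DataFrame | None = None,
) -> SweepResult:
    """Fit the cumulative top-x exposure models over the percentile grid.

    Fits are independent per x (no smoothing).  Exposure levels with no
    occupants at some x are omitted and recorded with NaN rows.  A
    precomputed IP annotation frame may be passed to avoid re-walking the
    pedigree across analyses.
    """
    if ann is None:
        ann, _ = annotate_ips(table, tables, interpolate)
    recs = []
    for x in x_values:
        cx = counts_at(ann, x, reference_weight)
        if cross_adjust_x is not None:
            cross = counts_at(ann, cross_adjust_x, reference_weight)
            cx["x_parent_1"] = (cross["n_top_parents"] == 1).astype(float)
            cx["x_parent_2"] = (cross["n_top_parents"] == 2).astype(float)
            cx["x_sib_1"] = (cross["n_top_sibs"] == 1).astype(float)
            cx["x_sib_2"] = (cross["n_top_sibs"] == 2).astype(float)
        for kind in ("parents", "siblings"):
            if kind == "parents":
                d, expo = _dummies(cx, "n_top_parents", {"parent_1": 1, "parent_2": 2})
                cross_terms = [c for c in ("x_sib_1", "x_sib_2")
                               if c in d and d[c].nunique() > 1] if cross_adjust_x else []
                wcol = None
            else:
                d, expo = _dummies(cx, "n_top_sibs", {"sib_1": 1, "sib_2plus": 2})
                cross_terms = [c for c in ("x_parent_1", "x_parent_2")
                               if c in d and d[c].nunique() > 1] if cross_adjust_x else []
                wcol = "weight"
            if not expo:
                recs.append({"x": x, "kind": kind, "term": None, "hr": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "n_level": 0, "omitted": True})
                continue
            fit = CoxModel(
                d, exposures=expo, covariates=_covs(d) + cross_terms,
                weights_col=wcol,
            ).fit()
            for t in expo:
                row = fit.summary_frame.loc[t]
                recs.append({
                    "x": x, "kind": kind, "term": t,
                    "hr": row["hr"], "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"], "p": row["p"],
                    "n_level": int(d[t].sum()), "omitted": False,
                })
    return SweepResult(pd.DataFrame(recs), list(x_values), cross_adjust_x)


def max_effect(sweep: SweepResult) -> dict:
    """Per exposure level, the lowest significant hazard ratio and its x.

    A level with no x whose CI excludes 1 maps to None (explicit absence).
    """
    out = {}
    f = sweep.frame.dropna(subset=["hr"])
    for term, grp in f.groupby("term"):
        sig = grp[(grp["ci_high"] < 1.0) | (grp["ci_low"] > 1.0)]
        if len(sig) == 0:
            out[term] = None
        else:
            best = sig.loc[sig["hr"].idxmin()]
            out[term] = {"x": int(best["x"]), "hr": float(best["hr"]),
                         "ci": (float(best["ci_low"]), float(best["ci_high"]))}
    return out


def detect_threshold(fit: CoxResults, kind: str, alpha: float = 0.05) -> ThresholdResult:
    """Highest-index group among g1..g5 with a significant survival advantage;
    low-power gaps at more extreme groups do not veto the threshold."""
    rows = []
    best = None
    for g in range(1, 6):
        term = f"g{g}"
        if term not in fit.summary_frame.index:
            rows.append({"group": term, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "significant": False})
            continue
        r = fit.summary_frame.loc[term]
        sig = bool(r["p"] < alpha and r["hr"] < 1.0)
        rows.append({"group": term, "hr": r["hr"], "ci_low": r["ci_low"],
                     "ci_high": r["ci_high"], "p": r["p"], "significant": sig})
        if sig:
            best = g
    thr = GROUP_BOUNDS[best - 1] if best is not None else None
    return ThresholdResult(kind, thr, pd.DataFrame(rows))


def run_exclusive_groups(
    table: pd.DataFrame,
    tables: LifetableCollection,
    kind: str = "siblings",
    cross_adjust_x: float | None = 10.0,
    interpolate: bool = False,
    reference_weight: str = "one",
    ann: pd.DataFrame | None = None,
) -> tuple[CoxResults, ThresholdResult]:
    """Mutually exclusive percentile groups vs reference g6 and the detected
    longevity threshold for the requested relative kind."""
    if ann is None:
        ann, _ = annotate_ips(table, tables, interpolate)
    ga = group_assignments(ann, kind, reference_weight)
    ga = ga[ga["group"].notna()].copy()
    if (ga["group"] == 6).sum() == 0:
        raise ValueError("reference group g6 is empty")
    ga, expo = _dummies(ga, "group", {f"g{g}": g for g in range(1, 6)})
    covs = _covs(ga)
    if cross_adjust_x is not None:
        cross = counts_at(ga, cross_adjust_x, reference_weight)
        if kind == "siblings":
            ga["x_parent_1"] = (cross["n_top_parents"] == 1).astype(float)
            ga["x_parent_2"] = (cross["n_top_parents"] == 2).astype(float)
            covs += [c for c in ("x_parent_1", "x_parent_2") if ga[c].nunique() > 1]
        else:
            ga["x_sib_1"] = (cross["n_top_sibs"] == 1).astype(float)
            ga["x_sib_2"] = (cross["n_top_sibs"] == 2).astype(float)
            covs += [c for c in ("x_sib_1", "x_sib_2") if ga[c].nunique() > 1]
    wcol = "group_weight" if kind == "siblings" else None
    fit = CoxModel(ga, exposures=expo, covariates=covs, weights_col=wcol).fit()
    return fit, detect_threshold(fit, kind)


def run_top10_integrated(
    table: pd.DataFrame,
    tables: LifetableCollection,
    x: float = 10.0,
    interpolate: bool = False,
    reference_weight: str = "one",
    ann: pd.DataFrame | None = None,
) -> dict:
    """Joint top-x parent/sibling fit plus the zero-top-parent stratum fit."""
    if ann is None:
        ann, _ = annotate_ips(table, tables, interpolate)
    cx = counts_at(ann, x, reference_weight)
    d, expo_p = _dummies(cx, "n_top_parents", {"parent_1": 1, "parent_2": 2})
    d, expo_s = _dummies(d, "n_top_sibs", {"sib_1": 1, "sib_2plus": 2})
    joint = CoxModel(
        d, exposures=expo_p + expo_s, covariates=_covs(d), weights_col="weight"
    ).fit()
    stratum = d[d["n_top_parents"] == 0].copy()
    strat_fit = None
    s_expo = [t for t in ("sib_1", "sib_2plus") if t in stratum and stratum[t].nunique() > 1]
    if s_expo:
        strat_fit = CoxModel(
            stratum, exposures=s_expo, covariates=_covs(stratum),
            weights_col="weight",
        ).fit()
    return {"joint": joint, "no_top_parent_stratum": strat_fit}


def run_children_verification(
    table: pd.DataFrame,
    tables: LifetableCollection,
    x: float = 10.0,
    interpolate: bool = False,
    ann: pd.DataFrame | None = None,
) -> dict:
    """F3 verification: shared-frailty Cox of child survival on top-x IP,
    spouse, and aunt/uncle exposures, with a family random intercept, plus the
    non-longevous-parents stratum."""
    if ann is None:
        ann, _ = annotate_children(table, tables, interpolate)
    ann = ann.copy()
    ann["ip_top"] = (ann["ip_pct"] <= x).astype(float)
    sp = ann["spouse_pct"]
    ann["spouse_top"] = np.where(sp.isna(), 0.0, (sp <= x).astype(float))
    k = np.fromiter((np.searchsorted(p, x, side="right")
                     for p in ann["auntuncle_pcts"]), int, len(ann))
    ann["au_1"] = (np.minimum(k, 2) == 1).astype(float)
    ann["au_2plus"] = (np.minimum(k, 2) == 2).astype(float)
    expo = [t for t in ("ip_top", "spouse_top", "au_1", "au_2plus")
            if ann[t].nunique() > 1]
    full = SharedFrailtyCoxModel(
        ann, exposures=expo, covariates=_covs(ann), group_col="family_id",
    ).fit()
    stratum = ann[(ann["ip_top"] == 0) & (ann["spouse_top"] == 0)]
    strat_fit = None
    s_expo = [t for t in ("au_1", "au_2plus") if t in stratum and stratum[t].nunique() > 1]
    if len(stratum) and s_expo and stratum["event"].sum() > 0:
        strat_fit = SharedFrailtyCoxModel(
            stratum, exposures=s_expo, covariates=_covs(stratum),
            group_col="family_id",
        ).fit()
    return {"full": full, "no_longevous_parents_stratum": strat_fit}


def run_spouse_analysis(
    table: pd.DataFrame,
    tables: LifetableCollection,
    interpolate: bool = False,
    alpha: float = 0.05,
    ann: pd.DataFrame | None = None,
) -> dict:
    """Spouses grouped by IP survival percentile: groups 1-5 vs reference g6,
    then all 15 pairwise contrasts with Bonferroni correction."""
    if ann is None:
        ann, _ = annotate_spouses(table, tables, interpolate)
    ann, expo = _dummies(ann, "group", {f"g{g}": g for g in range(1, 6)})
    fit = CoxModel(ann, exposures=expo, covariates=_covs(ann)).fit()
    posthoc = bonferroni_posthoc(fit, [f"g{g}" for g in range(1, 6)], alpha=alpha)
    return {"fit": fit, "posthoc": posthoc,
            "bonferroni_threshold": posthoc.attrs["bonferroni_threshold"]}


def run_sensitivity_variants(
    table: pd.DataFrame,
    tables: LifetableCollection,
    x: float = 10.0,
    seed: int = 0,
    interpolate: bool = False,
) -> dict:
    """Lineage split, sex-interaction, and half-sample refits."""
    ann, _ = annotate_ips(table, tables, interpolate)
    cx = counts_at(ann, x)

    # (a) maternal / paternal split of the parent exposure
    cx["maternal_top"] = (cx["mother_pct"] <= x).astype(float)
    cx["paternal_top"] = (cx["father_pct"] <= x).astype(float)
    lineage = CoxModel(
        cx, exposures=["maternal_top", "paternal_top"], covariates=_covs(cx),
    ).fit()

    # (b) exposure x sex interaction
    cx["n_top_parents_f"] = cx["n_top_parents"].astype(float)
    cx["parent_x_female"] = cx["n_top_parents_f"] * cx["female"]
    interaction = CoxModel(
        cx, exposures=["n_top_parents_f", "parent_x_female"],
        covariates=_covs(cx),
    ).fit()

    # (c) half-sample refit of the integrated design
    rng = np.random.default_rng(seed)
    fams = cx["family_id"].unique()
    half = set(rng.choice(fams, size=len(fams) // 2, replace=False))
    sub_table = table[table["family_id"].isin(half)]
    full_fit = run_top10_integrated(table, tables, x, interpolate)["joint"]
    half_fit = run_top10_integrated(sub_table, tables, x, interpolate)["joint"]
    shared = [t for t in full_fit.summary_frame.index
              if t in half_fit.summary_frame.index
              and t in ("parent_1", "parent_2", "sib_1", "sib_2plus")]
    concordance = pd.DataFrame({
        "full_hr": full_fit.hazard_ratios[shared],
        "half_hr": half_fit.hazard_ratios[shared],
        "same_sign": np.sign(np.log(full_fit.hazard_ratios[shared]))
        == np.sign(np.log(half_fit.hazard_ratios[shared])),
        "ci_overlap": [
            max(full_fit.conf_int(t)[0], half_fit.conf_int(t)[0])
            <= min(full_fit.conf_int(t)[1], half_fit.conf_int(t)[1])
            for t in shared
        ],
    })
    return {"lineage": lineage, "sex_interaction": interaction,
            "half_sample": {"full": full_fit, "half": half_fit,
                            "concordance": concordance}}


def run_all(
    table: pd.DataFrame,
    tables: LifetableCollection,
    seed: int = 0,
    analyses: tuple[str, ...] = ("sweep", "groups", "top10", "children", "spouses"),
    x_values=range(1, 61),
    x: float = 10.0,
    interpolate: bool = False,
) -> dict:
    """Execute the requested analyses in study order and collect results."""
    out: dict = {}
    ann, ip_ledger = annotate_ips(table, tables, interpolate)
    out["exclusions"] = {"ips": ip_ledger}
    if "sweep" in analyses:
        sweep = run_percentile_sweep(table, tables, x_values, cross_adjust_x=x,
                                     interpolate=interpolate, ann=ann)
        out["sweep"] = sweep
        out["max_effect"] = max_effect(sweep)
    if "groups" in analyses:
        out["groups"] = {}
        for kind in ("parents", "siblings"):
            fit, thr = run_exclusive_groups(table, tables, kind,
                                            cross_adjust_x=x,
                                            interpolate=interpolate, ann=ann)
            out["groups"][kind] = {"fit": fit, "threshold": thr}
    if "top10" in analyses:
        out["top10"] = run_top10_integrated(table, tables, x, interpolate, ann=ann)
    if "children" in analyses:
        ann_ch, ch_ledger = annotate_children(table, tables, interpolate)
        out["exclusions"]["children"] = ch_ledger
        out["children"] = run_children_verification(table, tables, x, interpolate,
                                                    ann=ann_ch)
    if "spouses" in analyses:
        ann_sp, sp_ledger = annotate_spouses(table, tables, interpolate)
        out["exclusions"]["spouses"] = sp_ledger
        out["spouses"] = run_spouse_analysis(table, tables, interpolate=interpolate,
                                             ann=ann_sp)
    if "sensitivity" in analyses:
        out["sensitivity"] = run_sensitivity_variants(table, tables, x, seed, interpolate)
    return out
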