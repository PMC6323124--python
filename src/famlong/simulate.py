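"""Three-generation pedigree simulator with a transmitted longevity component.

Families consist of two F1 founders, an F2 sibship, one F2 member who marries
and has children (the index-person candidate), an unrelated (or assortatively
matched) F2 spouse, and F3 children of that couple.  Mortality follows a
Gompertz–Makeham baseline (or user-supplied lifetables) multiplied by
``exp(log_frailty + covariate effects)``.

The longevity component is an additive quantitative genetic trait on the
log-hazard scale: founders carry genetic values ``a ~ N(0, sigma_g2)``, each
child receives the mid-parent value plus Mendelian segregation noise
``N(0, sigma_g2 / 2)``, and the individual log-frailty adds environmental
noise ``N(0, sigma_e2)``.  The narrow-sense heritability of log-frailty is
``sigma_g2 / (sigma_g2 + sigma_e2)``; parent-offspring regression of
log-frailty has expected slope ``h2 / 2``.

Founders, index persons and spouses are sampled conditional on surviving to
the ages their family role implies (marriage, first child); everyone else is
sampled unconditionally, so infant and child mortality appear among siblings
and F3 children as in historical registries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lifetables import (
    FEMALE,
    MALE,
    GompertzMakehamParams,
    LifetableCollection,
    observed_percentile,
)

__all__ = [
    "SimConfig",
    "simulate_population",
    "select_index_persons",
    "apply_censoring",
    "simulate_study",
    "simulate_threshold_scenario",
    "PERSON_COLUMNS",
]

SES_MISSING = 999

PERSON_COLUMNS = [
    "person_id", "family_id", "generation", "role", "sex", "birth_year",
    "death_age", "censor_age", "mother_id", "father_id", "spouse_id",
    "marriage_age", "first_child_age", "sibship_size", "birth_order",
    "birth_interval", "twin", "ses", "religion", "mother_age_at_birth",
    "log_frailty",
]


@dataclass
class SimConfig:
    """Simulator parameters.

    Defaults emulate the historical study populations: sibships average ~6.3
    children, founders are born 1740-1845 so the middle generation falls in the
    1767-1902 range, administrative follow-up closes in 1940 producing roughly
    15-30% censoring among relatives, and adult mortality follows a 19th
    century Gompertz-Makeham regime (modal adult age at death in the 70s,
    top-10% threshold near age 80).
    """

    n_families: int = 1000
    sibship_mean: float = 6.3
    mortality: object = field(default_factory=GompertzMakehamParams)
    sigma_g2: float = 0.3
    sigma_e2: float = 0.3
    birth_year_range: tuple[int, int] = (1740, 1845)
    censor_year: int = 1940
    loss_rate: float = 0.001
    missing_age_rate: float = 0.01
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    marriage_age_mean: float = 25.0
    marriage_age_sd: float = 4.0
    interbirth_mean: float = 2.5
    twin_prob: float = 0.015
    assortative_corr: float = 0.0
    lineage_weights: tuple[float, float] = (0.5, 0.5)
    include_religion: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if self.sibship_mean <= 1.0:
            raise ValueError("sibship_mean must exceed 1 (zero-truncated Poisson)")
        if not (-1.0 <= self.assortative_corr <= 1.0):
            raise ValueError("assortative_corr must lie in [-1, 1]")
        if self.marriage_age_mean + 3 * self.marriage_age_sd > 110:
            raise ValueError("marriage-age distribution extends beyond the lifetime support")

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return 0.0 if tot == 0 else self.sigma_g2 / tot

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "mortality" in d and isinstance(d["mortality"], Mapping):
            d["mortality"] = GompertzMakehamParams(**d["mortality"])
        for key in ("birth_year_range", "lineage_weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _ztp_mu(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``mean``."""
    return brentq(lambda m: m / -np.expm1(-m) - mean, 1e-6, 50.0)


def _ztp_sample(mu: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated Poisson via rejection (fast for mu > 1)."""
    out = rng.poisson(mu, size)
    bad = out == 0
    while bad.any():
        out[bad] = rng.poisson(mu, int(bad.sum()))
        bad = out == 0
    return out


def _segmented_cumsum(values: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at each segment boundary."""
    cs = np.cumsum(values)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    offsets = np.where(starts > 0, cs[starts - 1], 0.0)
    return cs - np.repeat(offsets, sizes)


def _invert_cumhaz(mortality, sex: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Solve H0(t) = q per person for the baseline cumulative hazard."""
    t = np.empty_like(q)
    if isinstance(mortality, GompertzMakehamParams):
        lo = np.zeros_like(q)
        hi = np.full_like(q, 135.0)
        # the Gompertz term guarantees H(135) >> any practical q
        for _ in range(52):
            mid = 0.5 * (lo + hi)
            high = mortality.cumulative_hazard(mid) >= q
            hi = np.where(high, mid, hi)
            lo = np.where(high, lo, mid)
        return 0.5 * (lo + hi)
    if isinstance(mortality, LifetableCollection):
        for s in np.unique(sex):
            lt = mortality.lookup(s)
            m = sex == s
            H = lt.cum_hazard
            idx = np.clip(np.searchsorted(H, q[m], side="right") - 1, 0, lt.a_max)
            ts = idx + (q[m] - H[idx]) / lt.hazard[idx]
            beyond = q[m] > H[-1]
            ts[beyond] = lt.a_max + 1.0 + (q[m][beyond] - H[-1]) / lt.hazard[-1]
            t[m] = ts
        return t
    raise TypeError(f"unsupported mortality model {type(mortality).__name__}")


def _sample_deaths(mortality, sex, eta, rng, min_age=None) -> np.ndarray:
    """Inverse-transform lifetimes from hazard h0(t) * exp(eta).

    With ``min_age`` given, draws are conditional on surviving past it
    (founders and spouses are observed only because they reproduced).
    """
    u = rng.uniform(size=len(eta))
    m = np.exp(eta)
    q = -np.log(u) / m
    if min_age is not None:
        if isinstance(mortality, GompertzMakehamParams):
            q = q + mortality.cumulative_hazard(np.asarray(min_age, dtype=float))
        else:
            h0 = np.empty_like(q)
            for s in np.unique(sex):
                msk = sex == s
                h0[msk] = mortality.lookup(s).cumulative_hazard_at(
                    np.asarray(min_age, dtype=float)[msk]
                )
            q = q + h0
    return _invert_cumhaz(mortality, sex, q)


def _covariate_eta(cfg: SimConfig, cols: Mapping[str, np.ndarray]) -> np.ndarray:
    n = len(next(iter(cols.values())))
    eta = np.zeros(n)
    for name, beta in cfg.covariate_effects.items():
        if beta == 0.0 or name not in cols:
            continue
        v = np.asarray(cols[name], dtype=float)
        if name == "ses":
            v = np.where(v == SES_MISSING, 4.5, v)
        v = np.nan_to_num(v, nan=0.0)
        eta = eta + beta * v
    return eta


def simulate_population(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the uncensored three-generation person table.

    One F2 member per family (chosen uniformly among those alive at a drawn
    marriage age) marries and has children; index-person designation itself is
    done by :func:`select_index_persons`.  The returned table carries true
    death ages and the latent ``log_frailty`` truth column.
    """
    if rng is None:
        if config.seed is None:
            raise ValueError("SimConfig.seed is required when no Generator is supplied")
        rng = np.random.default_rng(config.seed)
    nf = config.n_families
    mu = _ztp_mu(config.sibship_mean)
    sg, se = config.sigma_g2, config.sigma_e2
    by_lo, by_hi = config.birth_year_range

    frames = []
    next_id = np.array([1])

    def take_ids(n: int) -> np.ndarray:
        ids = np.arange(next_id[0], next_id[0] + n)
        next_id[0] += n
        return ids

    fam = np.arange(1, nf + 1)

    # ---- F1 founders ------------------------------------------------------
    father_by = rng.integers(by_lo, by_hi + 1, nf)
    mother_by = father_by + rng.integers(-2, 6, nf)
    a_father = rng.normal(0.0, math.sqrt(sg), nf) if sg > 0 else np.zeros(nf)
    a_mother = rng.normal(0.0, math.sqrt(sg), nf) if sg > 0 else np.zeros(nf)
    lf_father = a_father + (rng.normal(0.0, math.sqrt(se), nf) if se > 0 else 0.0)
    lf_mother = a_mother + (rng.normal(0.0, math.sqrt(se), nf) if se > 0 else 0.0)
    ses_fam = rng.integers(0, 10, nf)
    ses_fam = np.where(rng.uniform(size=nf) < 0.05, SES_MISSING, ses_fam)
    religion_fam = rng.integers(0, 4, nf) if config.include_religion else np.full(nf, -1)

    mother_marr = np.clip(rng.normal(config.marriage_age_mean - 1.0, config.marriage_age_sd, nf), 17, 42)
    father_marr = np.clip(mother_marr + (father_by - mother_by) * -1.0 + rng.normal(1.0, 2.0, nf), 17, 50)

    # ---- F2 sibships ------------------------------------------------------
    base_sibs = _ztp_sample(mu, nf, rng)
    gaps = 1.0 + rng.exponential(config.interbirth_mean - 1.0, int(base_sibs.sum()))
    first_gap = 0.6 + rng.exponential(0.8, nf)
    fam_of_birth = np.repeat(np.arange(nf), base_sibs)
    order_in_fam = _segmented_cumsum(np.ones(int(base_sibs.sum())), base_sibs)
    rel_age = _segmented_cumsum(np.where(order_in_fam == 1, 0.0, gaps), base_sibs)
    mother_age_birth = mother_marr[fam_of_birth] + first_gap[fam_of_birth] + rel_age

    twin = rng.uniform(size=len(fam_of_birth)) < config.twin_prob
    if twin.any():
        # duplicate twin births: same mother age, same family
        fam_of_birth = np.concatenate([fam_of_birth, fam_of_birth[twin]])
        mother_age_birth = np.concatenate([mother_age_birth, mother_age_birth[twin]])
        twin_flag = np.concatenate([twin, np.ones(int(twin.sum()), dtype=bool)])
        srt = np.lexsort((mother_age_birth, fam_of_birth))
        fam_of_birth, mother_age_birth, twin_flag = (
            fam_of_birth[srt], mother_age_birth[srt], twin_flag[srt])
    else:
        twin_flag = twin

    n2 = len(fam_of_birth)
    sib_count = np.bincount(fam_of_birth, minlength=nf)
    birth_order = _segmented_cumsum(np.ones(n2), sib_count).astype(int)
    mab_sorted = mother_age_birth
    birth_interval = np.where(
        birth_order == 1, 0.0,
        mab_sorted - np.concatenate([[0.0], mab_sorted[:-1]]),
    )
    sex2 = np.where(rng.uniform(size=n2) < 0.5, FEMALE, MALE)
    by2 = mother_by[fam_of_birth] + np.floor(mother_age_birth).astype(int)
    w_pat, w_mat = config.lineage_weights
    mid_parent = w_pat * a_father[fam_of_birth] + w_mat * a_mother[fam_of_birth]
    a2 = mid_parent + (rng.normal(0.0, math.sqrt(sg / 2.0), n2) if sg > 0 else 0.0)
    lf2 = a2 + (rng.normal(0.0, math.sqrt(se), n2) if se > 0 else 0.0)

    cov2 = {
        "sex": (sex2 == FEMALE).astype(float),
        "ses": ses_fam[fam_of_birth].astype(float),
        "sibship_size": sib_count[fam_of_birth].astype(float),
        "birth_order": birth_order.astype(float),
        "birth_interval": birth_interval,
        "twin": twin_flag.astype(float),
        "mother_age_at_birth": mother_age_birth,
        "birth_year": by2.astype(float),
    }
    eta2 = lf2 + _covariate_eta(config, cov2)
    death2 = _sample_deaths(config.mortality, sex2, eta2, rng)

    # ---- F1 deaths (conditional on rearing the sibship) --------------------
    cov1f = {"sex": np.zeros(nf), "ses": ses_fam.astype(float), "birth_year": father_by.astype(float)}
    cov1m = {"sex": np.ones(nf), "ses": ses_fam.astype(float), "birth_year": mother_by.astype(float)}
    last_birth_age_m = np.zeros(nf)
    np.maximum.at(last_birth_age_m, fam_of_birth, mother_age_birth)
    death_f1f = _sample_deaths(
        config.mortality, np.full(nf, MALE), lf_father + _covariate_eta(config, cov1f),
        rng, min_age=father_marr)
    death_f1m = _sample_deaths(
        config.mortality, np.full(nf, FEMALE), lf_mother + _covariate_eta(config, cov1m),
        rng, min_age=last_birth_age_m)

    # ---- choose the marrying F2 member ------------------------------------
    cand_marr = np.clip(rng.normal(config.marriage_age_mean, config.marriage_age_sd, n2), 18, 45)
    cand_gap = 0.6 + rng.exponential(0.8, n2)
    eligible = (death2 > cand_marr + cand_gap) & (sib_count[fam_of_birth] >= 2)
    pick = np.full(nf, -1)
    u_pick = rng.uniform(size=n2)
    # uniform choice among eligible members per family via random keys
    key = np.where(eligible, u_pick, np.inf)
    order = np.lexsort((key, fam_of_birth))
    first_of_fam = np.searchsorted(fam_of_birth[order], np.arange(nf))
    best = order[np.clip(first_of_fam, 0, n2 - 1)] if n2 else np.array([], dtype=int)
    valid = (first_of_fam < n2) & (fam_of_birth[np.clip(best, 0, n2 - 1)] == np.arange(nf)) \
        & np.isfinite(key[np.clip(best, 0, n2 - 1)])
    pick[valid] = best[valid]

    ip_idx = pick[pick >= 0]                      # indices into F2 arrays
    ip_fam = np.flatnonzero(pick >= 0)
    n_ip = len(ip_idx)

    marr2 = np.full(n2, np.nan)
    fca2 = np.full(n2, np.nan)
    marr2[ip_idx] = cand_marr[ip_idx]
    fca2[ip_idx] = cand_marr[ip_idx] + cand_gap[ip_idx]

    # ---- spouses -----------------------------------------------------------
    rho = config.assortative_corr
    sp_sex = np.where(sex2[ip_idx] == FEMALE, MALE, FEMALE)
    sp_by = by2[ip_idx] + rng.integers(-4, 5, n_ip)
    a_sp = rho * a2[ip_idx] + (
        rng.normal(0.0, math.sqrt(max(sg * (1 - rho**2), 0.0)), n_ip) if sg > 0 else 0.0)
    lf_sp = a_sp + (rng.normal(0.0, math.sqrt(se), n_ip) if se > 0 else 0.0)
    child_birth_year = by2[ip_idx] + fca2[ip_idx]
    sp_fca = np.maximum(child_birth_year - sp_by, 15.0)
    sp_marr = np.maximum(sp_fca - (fca2[ip_idx] - marr2[ip_idx]), 14.0)
    sp_sibs = _ztp_sample(mu, n_ip, rng)
    sp_cov = {
        "sex": (sp_sex == FEMALE).astype(float),
        "ses": ses_fam[ip_fam].astype(float),
        "sibship_size": sp_sibs.astype(float),
        "birth_year": sp_by.astype(float),
    }
    death_sp = _sample_deaths(
        config.mortality, sp_sex, lf_sp + _covariate_eta(config, sp_cov), rng, min_age=sp_fca)

    # ---- F3 children -------------------------------------------------------
    n_kids = _ztp_sample(mu, n_ip, rng)
    nk = int(n_kids.sum())
    kid_fam = np.repeat(ip_fam, n_kids)
    kid_of_ip = np.repeat(np.arange(n_ip), n_kids)
    gaps3 = 1.0 + rng.exponential(config.interbirth_mean - 1.0, nk)
    order3 = _segmented_cumsum(np.ones(nk), n_kids)
    rel3 = _segmented_cumsum(np.where(order3 == 1, 0.0, gaps3), n_kids)
    mother_is_ip = sex2[ip_idx] == FEMALE
    mother_fca = np.where(mother_is_ip, fca2[ip_idx], sp_fca)
    mother_by3 = np.where(mother_is_ip, by2[ip_idx], sp_by)
    mab3 = mother_fca[kid_of_ip] + rel3
    twin3 = rng.uniform(size=nk) < config.twin_prob
    if twin3.any():
        kid_fam = np.concatenate([kid_fam, kid_fam[twin3]])
        kid_of_ip = np.concatenate([kid_of_ip, kid_of_ip[twin3]])
        mab3 = np.concatenate([mab3, mab3[twin3]])
        twin3 = np.concatenate([twin3, np.ones(int(twin3.sum()), dtype=bool)])
        srt = np.lexsort((mab3, kid_fam))
        kid_fam, kid_of_ip, mab3, twin3 = kid_fam[srt], kid_of_ip[srt], mab3[srt], twin3[srt]
    nk = len(kid_fam)
    kid_count = np.bincount(kid_of_ip, minlength=n_ip)
    order3 = _segmented_cumsum(np.ones(nk), kid_count).astype(int)
    interval3 = np.where(order3 == 1, 0.0, mab3 - np.concatenate([[0.0], mab3[:-1]]))
    sex3 = np.where(rng.uniform(size=nk) < 0.5, FEMALE, MALE)
    by3 = mother_by3[kid_of_ip] + np.floor(mab3).astype(int)
    a3 = 0.5 * (a2[ip_idx][kid_of_ip] + a_sp[kid_of_ip]) + (
        rng.normal(0.0, math.sqrt(sg / 2.0), nk) if sg > 0 else 0.0)
    lf3 = a3 + (rng.normal(0.0, math.sqrt(se), nk) if se > 0 else 0.0)
    cov3 = {
        "sex": (sex3 == FEMALE).astype(float),
        "ses": ses_fam[kid_fam].astype(float),
        "sibship_size": kid_count[kid_of_ip].astype(float),
        "birth_order": order3.astype(float),
        "birth_interval": interval3,
        "twin": twin3.astype(float),
        "mother_age_at_birth": mab3,
        "birth_year": by3.astype(float),
    }
    death3 = _sample_deaths(config.mortality, sex3, lf3 + _covariate_eta(config, cov3), rng)

    # ---- assemble ----------------------------------------------------------
    id_father = take_ids(nf)
    id_mother = take_ids(nf)
    id_f2 = take_ids(n2)
    id_sp = take_ids(n_ip)
    id_f3 = take_ids(nk)

    def frame(**cols):
        df = pd.DataFrame(cols)
        for c in PERSON_COLUMNS:
            if c not in df:
                df[c] = np.nan
        return df[PERSON_COLUMNS]

    nanf = np.full(nf, np.nan)
    frames.append(frame(
        person_id=id_father, family_id=fam, generation="F1", role="parent",
        sex=MALE, birth_year=father_by, death_age=death_f1f,
        spouse_id=id_mother.astype(float), marriage_age=father_marr,
        ses=ses_fam, religion=religion_fam, log_frailty=lf_father))
    frames.append(frame(
        person_id=id_mother, family_id=fam, generation="F1", role="parent",
        sex=FEMALE, birth_year=mother_by, death_age=death_f1m,
        spouse_id=id_father.astype(float), marriage_age=mother_marr,
        ses=ses_fam, religion=religion_fam, log_frailty=lf_mother))
    sp_of_f2 = np.full(n2, np.nan)
    sp_of_f2[ip_idx] = id_sp
    frames.append(frame(
        person_id=id_f2, family_id=fam[fam_of_birth], generation="F2", role="sibling",
        sex=sex2, birth_year=by2, death_age=death2,
        mother_id=id_mother[fam_of_birth].astype(float),
        father_id=id_father[fam_of_birth].astype(float),
        spouse_id=sp_of_f2, marriage_age=marr2, first_child_age=fca2,
        sibship_size=sib_count[fam_of_birth], birth_order=birth_order,
        birth_interval=birth_interval, twin=twin_flag.astype(int),
        ses=ses_fam[fam_of_birth], religion=religion_fam[fam_of_birth],
        mother_age_at_birth=mother_age_birth, log_frailty=lf2))
    frames.append(frame(
        person_id=id_sp, family_id=fam[ip_fam], generation="F2", role="spouse",
        sex=sp_sex, birth_year=sp_by, death_age=death_sp,
        spouse_id=id_f2[ip_idx].astype(float), marriage_age=sp_marr,
        first_child_age=sp_fca, sibship_size=sp_sibs,
        birth_order=rng.integers(1, sp_sibs + 1),
        birth_interval=np.where(rng.uniform(size=n_ip) < 1 / np.maximum(sp_sibs, 1), 0.0,
                                1.0 + rng.exponential(config.interbirth_mean - 1.0, n_ip)),
        twin=(rng.uniform(size=n_ip) < config.twin_prob).astype(int),
        ses=ses_fam[ip_fam], religion=religion_fam[ip_fam],
        mother_age_at_birth=np.clip(rng.normal(30, 6, n_ip), 16, 48),
        log_frailty=lf_sp))
    ip_is_mother = mother_is_ip[kid_of_ip]
    frames.append(frame(
        person_id=id_f3, family_id=fam[kid_fam], generation="F3", role="child",
        sex=sex3, birth_year=by3, death_age=death3,
        mother_id=np.where(ip_is_mother, id_f2[ip_idx][kid_of_ip], id_sp[kid_of_ip]).astype(float),
        father_id=np.where(ip_is_mother, id_sp[kid_of_ip], id_f2[ip_idx][kid_of_ip]).astype(float),
        sibship_size=kid_count[kid_of_ip], birth_order=order3,
        birth_interval=interval3, twin=twin3.astype(int),
        ses=ses_fam[kid_fam], religion=religion_fam[kid_fam],
        mother_age_at_birth=mab3, log_frailty=lf3))

    table = pd.concat(frames, ignore_index=True)
    table["birth_year"] = table["birth_year"].astype(int)
    table["family_id"] = table["family_id"].astype(int)
    table["person_id"] = table["person_id"].astype(int)
    return table


def select_index_persons(table: pd.DataFrame, seed: int | None = None) -> tuple[pd.DataFrame, int]:
    """Designate one index person per F2 sibship.

    Eligibility: known birth year and death age, known sex, at least one
    sibling, at least one spouse and at least one child.  The choice among
    eligible members is uniform at random.  Families without an eligible
    member are dropped; their count is returned alongside the table.
    """
    rng = np.random.default_rng(seed)
    t = table.copy()
    has_child = set(t["mother_id"].dropna()) | set(t["father_id"].dropna())
    f2 = t[t["generation"] == "F2"]
    members = f2[f2["role"].isin(["sibling", "ip"])]
    sib_counts = members.groupby("family_id")["person_id"].transform("count")
    eligible = (
        members["death_age"].notna()
        & members["birth_year"].notna()
        & members["sex"].notna()
        & members["spouse_id"].notna()
        & members["person_id"].isin(has_child)
        & (sib_counts >= 2)
    )
    chosen: list[int] = []
    dropped = 0
    for fid, grp in members[eligible].groupby("family_id"):
        chosen.append(int(grp["person_id"].iloc[rng.integers(len(grp))]))
    n_fam_total = members["family_id"].nunique()
    dropped = n_fam_total - len(chosen)
    keep_fams = set(members.loc[eligible, "family_id"].unique())
    t = t[t["family_id"].isin(keep_fams)].copy()
    t.loc[t["person_id"].isin(chosen), "role"] = "ip"
    return t.reset_index(drop=True), dropped


def apply_censoring(table: pd.DataFrame, config: SimConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Right-censor non-IP persons at the administrative cut-off year or a
    random loss-to-follow-up age, whichever comes first; IPs keep observed
    deaths (they are selected on having one).  A small fraction of non-IPs
    loses both ages entirely (missing vital records)."""
    if rng is None:
        rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    t = table.copy()
    non_ip = (t["role"] != "ip").to_numpy()
    n = len(t)
    admin_age = (config.censor_year - t["birth_year"]).to_numpy(dtype=float)
    loss_age = np.full(n, np.inf)
    if config.loss_rate > 0:
        loss_age = rng.exponential(1.0 / config.loss_rate, n)
    censor_at = np.minimum(admin_age, loss_age)
    death = t["death_age"].to_numpy(dtype=float)
    censored = non_ip & np.isfinite(censor_at) & (censor_at < death)
    t.loc[censored, "censor_age"] = np.maximum(censor_at[censored], 0.0)
    t.loc[censored, "death_age"] = np.nan
    if config.missing_age_rate > 0:
        gone = non_ip & (rng.uniform(size=n) < config.missing_age_rate)
        t.loc[gone, ["death_age", "censor_age"]] = np.nan
    return t


def simulate_study(config: SimConfig) -> pd.DataFrame:
    """Full pipeline: simulate, designate IPs, apply censoring."""
    if config.seed is None:
        raise ValueError("SimConfig.seed is required")
    rng = np.random.default_rng(config.seed)
    table = simulate_population(config, rng)
    table, _ = select_index_persons(table, seed=config.seed + 7)
    return apply_censoring(table, config, rng=np.random.default_rng(config.seed + 13))


def simulate_frailty_cohort(
    n_groups: int,
    theta: float,
    seed: int,
    mean_size: float = 6.3,
    mortality: GompertzMakehamParams | None = None,
    beta_female: float = -0.2,
    censor_prob: float = 0.15,
) -> pd.DataFrame:
    """Direct draw from the shared-frailty model: sibships with a common
    ``N(0, theta)`` log-frailty, a sex effect, and uninformative censoring.

    Used to study frailty-variance recovery in isolation from the pedigree
    machinery: returns entry/exit/event rows ready for
    :class:`famlong.cox.SharedFrailtyCoxModel`.
    """
    rng = np.random.default_rng(seed)
    mort = mortality or GompertzMakehamParams()
    sizes = _ztp_sample(_ztp_mu(mean_size), n_groups, rng)
    n = int(sizes.sum())
    fam = np.repeat(np.arange(n_groups), sizes)
    b = rng.normal(0.0, math.sqrt(theta), n_groups) if theta > 0 else np.zeros(n_groups)
    female = rng.uniform(size=n) < 0.5
    sex = np.where(female, FEMALE, MALE)
    eta = b[fam] + beta_female * female
    death = _sample_deaths(mort, sex, eta, rng)
    censor = rng.uniform(size=n) < censor_prob
    cage = rng.uniform(1.0, 90.0, n)
    exit_age = np.where(censor & (cage < death), cage, death)
    event = ~(censor & (cage < death))
    return pd.DataFrame({
        "family_id": fam, "entry_age": 0.0, "exit_age": exit_age,
        "event": event.astype(int), "female": female.astype(float),
    })


def simulate_threshold_scenario(
    config: SimConfig,
    tables: LifetableCollection,
    boundary: float = 10.0,
    hr: float = 0.65,
    kind: str = "siblings",
) -> pd.DataFrame:
    """Null population in which only families whose ``kind`` relatives reach
    below the given survival percentile confer an IP survival advantage.

    Used to check that threshold detection localises the generative boundary:
    IP lifetimes are redrawn with hazard multiplied by ``hr`` exactly when the
    family's best (lowest-percentile) relative of the requested kind lies at
    or below ``boundary``; all other structure stays null (sigma_g2 = 0).
    """
    cfg = replace(config, sigma_g2=0.0, loss_rate=0.0, missing_age_rate=0.0)
    table = simulate_study(cfg)
    rng = np.random.default_rng((cfg.seed or 0) + 101)

    ips = table[table["role"] == "ip"]
    qualifies: dict[int, bool] = {}
    for fid, grp in table.groupby("family_id"):
        ip = grp[grp["role"] == "ip"].iloc[0]
        if kind == "siblings":
            rel = grp[(grp["generation"] == "F2") & (grp["role"] == "sibling")]
        else:
            rel = grp[grp["person_id"].isin([ip["mother_id"], ip["father_id"]])]
        pcts = [
            observed_percentile(r.sex, r.birth_year, r.death_age, r.censor_age, tables)
            for r in rel.itertuples()
        ]
        pcts = [p for p in pcts if not math.isnan(p)]
        qualifies[fid] = bool(pcts) and min(pcts) <= boundary

    mask = ips["family_id"].map(qualifies).fillna(False).to_numpy(dtype=bool)
    idx = ips.index[mask]
    if len(idx):
        sub = table.loc[idx]
        eta = sub["log_frailty"].to_numpy() + math.log(hr)
        entry = np.maximum(sub["marriage_age"].to_numpy(), sub["first_child_age"].to_numpy())
        new_death = _sample_deaths(
            cfg.mortality, sub["sex"].to_numpy(), eta, rng, min_age=entry)
        table.loc[idx, "death_age"] = new_death
    return table
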