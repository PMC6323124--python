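"""Cohort lifetables and birth-cohort survival percentiles.

A cohort lifetable gives, for one sex and one birth year, the yearly hazard of
dying between exact ages x and x+1 (``h_x``).  Under the piecewise-constant
hazard convention the conditional cumulative hazard is ``H_{x+1} = H_x + h_x``
(``H_0 = 0``) and the survival function is ``S_x = exp(-H_x)``.  An
individual's *survival percentile* is ``100 * S(age)``: the expected share of
the person's sex-specific birth cohort still alive at that age.  Smaller
percentiles mean longer lives, and "top x%" means percentile <= x.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CohortLifetable",
    "GompertzMakehamParams",
    "LifetableCollection",
    "build_from_hazards",
    "read_hmd_cohort_table",
    "synthesize_lifetable",
    "write_simple_csv",
    "read_simple_csv",
]

FEMALE = "F"
MALE = "M"

_SEX_ALIASES = {
    "f": FEMALE, "female": FEMALE, "fltcoh": FEMALE,
    "m": MALE, "male": MALE, "mltcoh": MALE,
}


def normalize_sex(sex: str) -> str:
    try:
        return _SEX_ALIASES[str(sex).strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognised sex code {sex!r}; expected one of F/M/female/male")


class LifetableError(Exception):
    """Structural or validation problem in lifetable construction."""


class LifetableLookupError(KeyError):
    """No lifetable available for a requested (sex, birth_year)."""


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Gompertz–Makeham hazard h(t) = makeham + gompertz_a * exp(gompertz_b * t).

    ``makeham`` is the age-independent background hazard (accidents,
    infections), the Gompertz term captures the exponential rise of adult
    mortality; ``gompertz_b`` around 0.1/year doubles the hazard roughly every
    7 years, the canonical value for human populations.
    """

    makeham: float = 0.01
    gompertz_a: float = 5e-5
    gompertz_b: float = 0.1

    def __post_init__(self) -> None:
        for name in ("makeham", "gompertz_a", "gompertz_b"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.makeham < 0:
            raise ValueError("makeham baseline hazard must be >= 0")
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValueError("gompertz_a and gompertz_b must be strictly positive")

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        return self.makeham + self.gompertz_a * np.exp(self.gompertz_b * t)

    def cumulative_hazard(self, t):
        """Closed-form H(t) = makeham*t + (a/b)(exp(b t) - 1)."""
        t = np.asarray(t, dtype=float)
        a, b = self.gompertz_a, self.gompertz_b
        return self.makeham * t + (a / b) * np.expm1(b * t)


@dataclass
class CohortLifetable:
    """Sex- and birth-year-specific lifetable on integer ages 0..a_max.

    ``hazard[x]`` is h_x for the interval [x, x+1); ``cum_hazard[x]`` is H_x at
    exact age x (length a_max+2 so the closing value H_{a_max+1} is available);
    ``survival[x] = exp(-H_x)``.  Ages beyond the table carry the last hazard
    forward.
    """

    sex: str
    birth_year: int | None
    hazard: np.ndarray
    cum_hazard: np.ndarray = field(init=False)
    survival: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sex = normalize_sex(self.sex)
        h = np.asarray(self.hazard, dtype=float)
        if h.ndim != 1 or h.size == 0:
            raise LifetableError("hazard must be a non-empty 1-d array")
        if np.any(~np.isfinite(h)) or np.any(h < 0):
            bad = int(np.flatnonzero(~np.isfinite(h) | (h < 0))[0])
            raise LifetableError(f"negative or non-finite hazard at age {bad}")
        self.hazard = h
        self.cum_hazard = np.concatenate([[0.0], np.cumsum(h)])
        self.survival = np.exp(-self.cum_hazard)

    @property
    def a_max(self) -> int:
        return self.hazard.size - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.hazard.size)

    # -- survival evaluation -------------------------------------------------

    def cumulative_hazard_at(self, age, interpolate: bool = True):
        """H(age) for scalar or array age; past a_max the last hazard extends."""
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be non-negative")
        H = self.cum_hazard
        h_last = self.hazard[-1]
        top = float(H[-1])
        if interpolate:
            inside = np.clip(age, 0.0, self.a_max + 1.0)
            lo = np.floor(inside).astype(int)
            frac = inside - lo
            out = H[np.minimum(lo, self.a_max)] + frac * self.hazard[np.minimum(lo, self.a_max)]
            out = np.where(inside >= self.a_max + 1.0, top, out)
            out = out + np.maximum(age - (self.a_max + 1.0), 0.0) * h_last
        else:
            idx = np.floor(age).astype(int)
            out = np.where(
                idx <= self.a_max + 1,
                H[np.minimum(idx, self.a_max + 1)],
                top + (idx - (self.a_max + 1)) * h_last,
            )
        return out if out.shape else float(out)

    def survival_at(self, age, interpolate: bool = True):
        return np.exp(-np.asarray(self.cumulative_hazard_at(age, interpolate)))

    def survival_percentile(self, age, interpolate: bool = False):
        """100 * S(age); smaller = longer-lived.  Integer-age lookup by default."""
        out = 100.0 * self.survival_at(age, interpolate=interpolate)
        return out if np.ndim(out) else float(out)

    def age_at_percentile(self, p: float) -> int:
        """Smallest integer age a with 100*S(a) <= p.

        If even the closing survival value stays above p/100 the table cannot
        resolve the percentile; a_max is returned and
        :meth:`percentile_out_of_range` reports the condition.
        """
        if not (0 < p <= 100):
            raise ValueError(f"percentile must be in (0, 100], got {p}")
        pct = 100.0 * self.survival
        idx = np.flatnonzero(pct <= p)
        if idx.size == 0:
            return self.a_max  # beyond table support; see percentile_out_of_range
        return int(idx[0])

    def percentile_out_of_range(self, p: float) -> bool:
        return 100.0 * self.survival[-1] > p

    def sample_ages(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-transform draws from this table's own survival curve.

        Continuous ages under the piecewise-constant hazard convention; the
        final hazard is carried beyond a_max so the distribution is proper.
        """
        u = rng.uniform(size=n)
        q = -np.log(u)  # target cumulative hazard
        H = self.cum_hazard
        idx = np.searchsorted(H, q, side="right") - 1
        idx = np.clip(idx, 0, self.a_max)
        t = idx + (q - H[idx]) / self.hazard[idx]
        beyond = q > H[-1]
        if np.any(beyond):
            t[beyond] = (self.a_max + 1.0) + (q[beyond] - H[-1]) / self.hazard[-1]
        return t


class LifetableCollection:
    """Lifetables keyed by (sex, birth_year); ``birth_year=None`` is a wildcard
    used by synthetic time-invariant mortality regimes."""

    def __init__(self, tables: Iterable[CohortLifetable] = ()):  # noqa: D401
        self._tables: dict[tuple[str, int | None], CohortLifetable] = {}
        for t in tables:
            self.add(t)

    def add(self, table: CohortLifetable) -> None:
        self._tables[(table.sex, table.birth_year)] = table

    def __len__(self) -> int:
        return len(self._tables)

    def __iter__(self):
        return iter(self._tables.values())

    def keys(self):
        return self._tables.keys()

    def lookup(self, sex: str, birth_year: int | None = None) -> CohortLifetable:
        sex = normalize_sex(sex)
        if birth_year is not None and (sex, int(birth_year)) in self._tables:
            return self._tables[(sex, int(birth_year))]
        if (sex, None) in self._tables:
            return self._tables[(sex, None)]
        avail = sorted(
            (s, y) for (s, y) in self._tables if s == sex and y is not None
        )
        raise LifetableLookupError(
            f"no lifetable for sex={sex!r}, birth_year={birth_year}; "
            f"available cohorts for {sex!r}: {[y for _, y in avail]}"
        )

    def survival_percentile(self, sex, birth_year, age, interpolate=False) -> float:
        return self.lookup(sex, birth_year).survival_percentile(age, interpolate)


def build_from_hazards(rows: Iterable[tuple]) -> LifetableCollection:
    """Build lifetables from (sex, birth_year, age, hazard) rows.

    For every (sex, birth_year) the ages must form a contiguous run starting
    at 0.  H and S follow the piecewise-constant-hazard convention.
    """
    groups: dict[tuple[str, int | None], dict[int, float]] = {}
    for sex, birth_year, age, hazard in rows:
        key = (normalize_sex(sex), None if birth_year is None else int(birth_year))
        groups.setdefault(key, {})[int(age)] = float(hazard)
    coll = LifetableCollection()
    for (sex, by), amap in groups.items():
        ages = sorted(amap)
        expected = list(range(len(ages)))
        if ages != expected:
            missing = sorted(set(expected) - set(ages))
            label = missing[0] if missing else ages[0]
            raise LifetableError(
                f"ages for (sex={sex}, birth_year={by}) are not a contiguous run "
                f"from 0: first missing age {label}"
            )
        coll.add(CohortLifetable(sex, by, np.array([amap[a] for a in ages])))
    return coll


def synthesize_lifetable(
    params: GompertzMakehamParams,
    sex: str,
    birth_year: int | None = None,
    a_max: int = 109,
) -> CohortLifetable:
    """Discretize a Gompertz–Makeham hazard into a yearly cohort lifetable.

    Each yearly hazard is the continuous hazard evaluated at the interval
    midpoint x + 0.5, a second-order-accurate discretization.
    """
    if a_max < 99:
        raise ValueError("a_max must be at least 99")
    x = np.arange(a_max + 1) + 0.5
    return CohortLifetable(sex, birth_year, params.hazard(x))


def synthesize_collection(
    params: GompertzMakehamParams, a_max: int = 109
) -> LifetableCollection:
    """Wildcard-year tables for both sexes under one mortality regime."""
    return LifetableCollection(
        [synthesize_lifetable(params, s, None, a_max) for s in (FEMALE, MALE)]
    )


# ---------------------------------------------------------------------------
# top-x classification

TOP = "top"
NOT_TOP = "not_top"
UNKNOWN = "unknown"


def classify_top_x(
    sex,
    birth_year,
    death_age,
    censor_age,
    tables: LifetableCollection,
    x: float,
    interpolate: bool = False,
) -> str:
    """Classify a person as top-x (percentile <= x) of their birth cohort.

    Deceased people are classified at their death age.  Censored people count
    as top only when their censoring age already exceeds the threshold age —
    they have outlived it — and as not_top otherwise (a conservative rule that
    never imputes a death age).  People with neither age are ``unknown``.
    """
    lt = tables.lookup(sex, birth_year)
    age = death_age if death_age is not None and not _isnan(death_age) else None
    if age is None:
        age = censor_age if censor_age is not None and not _isnan(censor_age) else None
        if age is None:
            return UNKNOWN
        return TOP if lt.survival_percentile(age, interpolate) <= x else NOT_TOP
    return TOP if lt.survival_percentile(age, interpolate) <= x else NOT_TOP


def observed_percentile(
    sex, birth_year, death_age, censor_age, tables, interpolate: bool = False
):
    """Survival percentile at the last observed age (death or censoring);
    NaN when no age is known.  For a censored person this is an upper bound on
    the death percentile (they can only become longer-lived)."""
    age = death_age if death_age is not None and not _isnan(death_age) else None
    if age is None:
        age = censor_age if censor_age is not None and not _isnan(censor_age) else None
    if age is None:
        return float("nan")
    return tables.lookup(sex, birth_year).survival_percentile(age, interpolate)


def _isnan(v) -> bool:
    try:
        return math.isnan(float(v))
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# HMD cohort-lifetable dialect

_HMD_COLUMNS = ["Year", "Age", "mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex"]


@dataclass
class ParseReport:
    imputed: list[tuple[int, str, int]] = field(default_factory=list)  # (year, sex, age)

    def flag(self, year: int, sex: str, age: int) -> None:
        self.imputed.append((year, sex, age))


def read_hmd_cohort_table(
    stream, sex: str | None = None, report: ParseReport | None = None
) -> LifetableCollection:
    """Read a whitespace-delimited HMD cohort-lifetable file.

    The central death rate ``mx`` is used directly as the yearly hazard h_x.
    The open age group ``110+`` is kept as the closing interval and missing
    values (``.``) are imputed by the last observed hazard, with each
    imputation flagged in the parse report.  Sex is taken from ``sex=`` or
    inferred from HMD file naming (fltcoh/mltcoh) appearing in the header.
    """
    if isinstance(stream, (str, bytes)):
        stream = io.StringIO(stream.decode() if isinstance(stream, bytes) else stream)
    lines = stream.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.split()[:2] == ["Year", "Age"]:
            cols = line.split()
            if cols != _HMD_COLUMNS:
                raise LifetableError(
                    f"malformed HMD header: expected {' '.join(_HMD_COLUMNS)}, got {line!r}"
                )
            header_idx = i
            break
        if sex is None:
            m = re.search(r"\b([fm])ltcoh\b", line, flags=re.IGNORECASE)
            if m:
                sex = FEMALE if m.group(1).lower() == "f" else MALE
    if header_idx is None:
        raise LifetableError("malformed HMD file: no 'Year Age mx ...' header found")
    if sex is None:
        raise LifetableError(
            "sex not determinable: pass sex= or include fltcoh/mltcoh in the preamble"
        )
    sex = normalize_sex(sex)
    report = report if report is not None else ParseReport()

    per_year: dict[int, dict[int, float | None]] = {}
    for raw in lines[header_idx + 1:]:
        if not raw.strip():
            continue
        parts = raw.split()
        if len(parts) != len(_HMD_COLUMNS):
            raise LifetableError(f"malformed HMD row: {raw!r}")
        year = int(parts[0])
        age = int(parts[1].rstrip("+"))
        mx_raw = parts[2]
        if mx_raw == ".":
            mx = None
        else:
            try:
                mx = float(mx_raw)
            except ValueError:
                raise LifetableError(f"non-numeric mx {mx_raw!r} in row {raw!r}")
        per_year.setdefault(year, {})[age] = mx

    rows = []
    for year, amap in per_year.items():
        last = None
        for age in sorted(amap):
            mx = amap[age]
            if mx is None:
                if last is None:
                    raise LifetableError(
                        f"mx missing at age {age} of cohort {year} with no earlier value"
                    )
                mx = last
                report.flag(year, sex, age)
            last = mx
            rows.append((sex, year, age, mx))
    return build_from_hazards(rows)


# ---------------------------------------------------------------------------
# simple hazard CSV (cohort, sex, age, hazard)


def write_simple_csv(tables: LifetableCollection, path_or_buf) -> None:
    recs = []
    for t in tables:
        for age, h in zip(t.ages, t.hazard):
            recs.append(
                {"cohort": "" if t.birth_year is None else t.birth_year,
                 "sex": t.sex, "age": int(age), "hazard": h}
            )
    pd.DataFrame(recs, columns=["cohort", "sex", "age", "hazard"]).to_csv(
        path_or_buf, index=False
    )


def read_simple_csv(path_or_buf) -> LifetableCollection:
    df = pd.read_csv(path_or_buf)
    required = {"cohort", "sex", "age", "hazard"}
    if not required.issubset(df.columns):
        raise LifetableError(
            f"hazard CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    rows = [
        (
            r.sex,
            None if pd.isna(r.cohort) or r.cohort == "" else int(r.cohort),
            int(r.age),
            float(r.hazard),
        )
        for r in df.itertuples()
    ]
    return build_from_hazards(rows)
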