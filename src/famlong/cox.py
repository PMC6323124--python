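"""Survival models: weighted left-truncated Cox PH and log-normal shared frailty.

``CoxModel`` follows the Model/Results convention: build it from a DataFrame,
call :meth:`CoxModel.fit`, and read estimates off the returned
:class:`CoxResults` (``summary()``, ``hazard_ratios``, ``vcov`` ...).  The
partial likelihood is maximised with Efron tie handling and delayed entry;
analytical (importance-style) weights use robust sandwich standard errors,
since model-based information is mis-sized under non-frequency weights.

``SharedFrailtyCoxModel`` adds a family-level Gaussian random intercept on the
log hazard (a log-normally distributed multiplicative frailty shared within
sibships).  It is fitted by penalized partial likelihood: inner Newton steps
in (beta, b) with the frailty block of the Hessian taken per-subject
("sparse" approximation, exact cross-block), and an outer Laplace-profile
maximisation of the frailty variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from lifelines import CoxPHFitter, KaplanMeierFitter, NelsonAalenFitter
from lifelines.exceptions import ConvergenceError

from ._ple import BreslowWorkspace

__all__ = [
    "CoxModel",
    "CoxResults",
    "SharedFrailtyCoxModel",
    "FrailtyResults",
    "ConvergenceFailure",
    "km_nelson_aalen",
    "check_ph",
    "bonferroni_posthoc",
]


class ConvergenceFailure(RuntimeError):
    """Fit did not converge (e.g. monotone likelihood under separation)."""


def _drop_constant(df: pd.DataFrame, cols: list[str], protected: list[str]):
    kept, dropped = [], []
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        if np.nanstd(v) < 1e-12:
            if c in protected:
                raise ValueError(f"exposure term {c!r} is constant: inestimable")
            dropped.append(c)
        else:
            kept.append(c)
    return kept, dropped


@dataclass
class CoxResults:
    """Wald summaries of a fitted Cox model."""

    summary_frame: pd.DataFrame          # index: term; coef, se, hr, ci_low, ci_high, p
    vcov: pd.DataFrame
    log_likelihood: float
    n: int
    events: int
    dropped_covariates: list[str] = field(default_factory=list)
    model: "CoxModel | None" = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        return self.summary_frame["coef"]

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.summary_frame["hr"]

    def conf_int(self, term: str) -> tuple[float, float]:
        row = self.summary_frame.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def significant(self, term: str, alpha: float = 0.05) -> bool:
        """CI (on the hazard-ratio scale) excludes 1 at the given level."""
        return float(self.summary_frame.loc[term, "p"]) < alpha

    def summary(self) -> pd.DataFrame:
        return self.summary_frame.copy()

    def lr_pvalue(self, term: str) -> float:
        """Likelihood-ratio p-value for one term (refits without it)."""
        if self.model is None:
            raise ValueError("results not attached to a model")
        reduced = self.model.without_term(term).fit()
        lr = 2.0 * (self.log_likelihood - reduced.log_likelihood)
        return float(stats.chi2.sf(max(lr, 0.0), df=1))

    def to_dict(self) -> dict:
        terms = {
            t: {
                "coef": float(r["coef"]), "se": float(r["se"]), "hr": float(r["hr"]),
                "ci_low": float(r["ci_low"]), "ci_high": float(r["ci_high"]),
                "p": float(r["p"]),
            }
            for t, r in self.summary_frame.iterrows()
        }
        return {
            "terms": terms, "n": int(self.n), "events": int(self.events),
            "loglik": float(self.log_likelihood),
        }


class CoxModel:
    """Weighted Cox proportional-hazards model with delayed entry.

    Parameters
    ----------
    data : DataFrame with one row per analysis unit.
    exposures / covariates : column names entering the linear predictor;
        constant covariates are silently dropped (recorded on the results),
        a constant exposure raises.
    entry_col : left-truncation age; rows must satisfy entry < duration.
    weights_col : analytical weights in (0, 1]; triggers sandwich SEs.
    strata : covariates moved out of the linear predictor into baseline strata.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        duration_col: str = "exit_age",
        event_col: str = "event",
        entry_col: str | None = "entry_age",
        weights_col: str | None = None,
        exposures: list[str] | None = None,
        covariates: list[str] | None = None,
        strata: list[str] | None = None,
        robust: bool | None = None,
        ties: str = "efron",
    ):
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.ties = ties
        self.exposures = list(exposures or [])
        covariates = list(covariates or [])
        if set(self.exposures) & set(covariates):
            raise ValueError("exposure and covariate sets must be disjoint")
        cols = self.exposures + covariates
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"columns not in data: {missing}")
        self.duration_col, self.event_col = duration_col, event_col
        self.entry_col = entry_col
        self.weights_col = weights_col
        self.strata = list(strata or [])
        use = cols + [duration_col, event_col] + self.strata
        if entry_col:
            use.append(entry_col)
        if weights_col:
            use.append(weights_col)
        self.data = data[list(dict.fromkeys(use))].copy()
        if entry_col is not None:
            bad = ~(self.data[entry_col] < self.data[duration_col])
            if bad.any():
                raise ValueError(f"{int(bad.sum())} rows violate entry < exit")
        if int(self.data[event_col].sum()) < 1:
            raise ValueError("at least one event is required")
        self.covariates, self.dropped = _drop_constant(self.data, covariates, [])
        _drop_constant(self.data, self.exposures, self.exposures)  # raises if constant
        if robust is None:
            robust = weights_col is not None
        self.robust = robust

    def without_term(self, term: str) -> "CoxModel":
        m = CoxModel.__new__(CoxModel)
        m.__dict__.update(self.__dict__)
        m.exposures = [t for t in self.exposures if t != term]
        m.covariates = [t for t in self.covariates if t != term]
        return m

    def fit(self) -> CoxResults:
        if self.ties == "breslow":
            return self._fit_breslow()
        cph = CoxPHFitter()
        terms = self.exposures + self.covariates
        kwargs = dict(
            duration_col=self.duration_col,
            event_col=self.event_col,
            formula=" + ".join(terms),
            robust=self.robust,
            fit_options={"precision": 1e-9, "max_steps": 500},
        )
        if self.entry_col:
            kwargs["entry_col"] = self.entry_col
        if self.weights_col:
            kwargs["weights_col"] = self.weights_col
        if self.strata:
            kwargs["strata"] = self.strata
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(self.data, **kwargs)
        except ConvergenceError as err:
            raise ConvergenceFailure(
                f"Cox partial likelihood did not converge (possible separation): {err}"
            ) from err
        if np.any(np.abs(cph.params_.to_numpy()) > 15):
            # monotone likelihood: the coefficient is drifting to +-inf
            raise ConvergenceFailure(
                "monotone partial likelihood (complete separation); no finite MLE"
            )
        s = cph.summary
        out = pd.DataFrame({
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        })
        out = out.loc[[t for t in terms if t in out.index]]
        return CoxResults(
            summary_frame=out,
            vcov=cph.variance_matrix_,
            log_likelihood=float(cph.log_likelihood_),
            n=len(self.data),
            events=int(self.data[self.event_col].sum()),
            dropped_covariates=self.dropped,
            model=self,
        )


    def _fit_breslow(self) -> CoxResults:
        """Newton maximisation of the weighted Breslow partial likelihood on
        the package's own risk-set engine (exact under tied event times)."""
        if self.strata:
            raise ValueError("strata are not supported with Breslow ties")
        terms = self.exposures + self.covariates
        X = self.data[terms].to_numpy(dtype=float)
        entry = (self.data[self.entry_col].to_numpy(dtype=float)
                 if self.entry_col else np.zeros(len(self.data)))
        exit_ = self.data[self.duration_col].to_numpy(dtype=float)
        event = self.data[self.event_col].to_numpy(dtype=float) > 0
        w = (self.data[self.weights_col].to_numpy(dtype=float)
             if self.weights_col else np.ones(len(self.data)))
        ws = BreslowWorkspace(entry, exit_, event, w, X)
        beta = np.zeros(len(terms))
        for _ in range(100):
            q = ws.quantities(X @ beta)
            g = X.T @ ws.grad_eta(q)
            H = ws.hess_beta(q)
            step = np.linalg.solve(H + 1e-12 * np.eye(len(terms)), g)
            beta = beta + step
            if np.max(np.abs(g)) < 1e-10 * (1 + abs(q["loglik"])):
                break
            if np.max(np.abs(beta)) > 15:
                raise ConvergenceFailure(
                    "monotone partial likelihood (complete separation); no finite MLE")
        q = ws.quantities(X @ beta)
        vcov = np.linalg.inv(ws.hess_beta(q))
        se = np.sqrt(np.diag(vcov))
        zc = stats.norm.ppf(0.975)
        z = beta / se
        summary = pd.DataFrame({
            "coef": beta, "se": se, "hr": np.exp(beta),
            "ci_low": np.exp(beta - zc * se), "ci_high": np.exp(beta + zc * se),
            "p": 2 * stats.norm.sf(np.abs(z)),
        }, index=terms)
        return CoxResults(
            summary_frame=summary,
            vcov=pd.DataFrame(vcov, index=terms, columns=terms),
            log_likelihood=q["loglik"],
            n=len(self.data), events=int(event.sum()),
            dropped_covariates=self.dropped, model=self,
        )


# ---------------------------------------------------------------------------
# log-normal shared frailty


@dataclass
class FrailtyResults(CoxResults):
    """Cox summaries plus the family-level log-frailty variance."""

    frailty_variance: float = 0.0
    frailty_variance_se: float = float("nan")
    bic: float = float("nan")
    n_groups: int = 0
    converged: bool = True
    random_effects: pd.Series | None = field(default=None, repr=False)

    def frailty_variance_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = max(self.frailty_variance - z * self.frailty_variance_se, 0.0)
        return lo, self.frailty_variance + z * self.frailty_variance_se

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["frailty_variance"] = float(self.frailty_variance)
        d["frailty_variance_se"] = float(self.frailty_variance_se)
        d["bic"] = float(self.bic)
        return d


class SharedFrailtyCoxModel:
    """Cox model with a shared Gaussian random intercept per family.

    The hazard for subject j of family i is
    ``u_i * lambda0(t) * exp(beta' Z_ij)`` with ``log u_i ~ N(0, theta)``.
    The variance ``theta`` is profiled on a Laplace approximation to the
    marginal likelihood; ties are handled by Breslow's method (simulated and
    registry ages here are effectively continuous).
    """

    THETA_MIN, THETA_MAX = 1e-4, 3.0

    def __init__(
        self,
        data: pd.DataFrame,
        duration_col: str = "exit_age",
        event_col: str = "event",
        entry_col: str | None = "entry_age",
        weights_col: str | None = None,
        exposures: list[str] | None = None,
        covariates: list[str] | None = None,
        group_col: str = "family_id",
    ):
        self.exposures = list(exposures or [])
        covariates = list(covariates or [])
        self.covariates, self.dropped = _drop_constant(data, covariates, [])
        _drop_constant(data, self.exposures, self.exposures)
        self.terms = self.exposures + self.covariates
        self.X = data[self.terms].to_numpy(dtype=float)
        self.entry = (data[entry_col].to_numpy(dtype=float) if entry_col
                      else np.zeros(len(data)))
        self.exit = data[duration_col].to_numpy(dtype=float)
        self.event = data[event_col].to_numpy(dtype=float) > 0
        self.w = (data[weights_col].to_numpy(dtype=float) if weights_col
                  else np.ones(len(data)))
        codes, self.group_labels = pd.factorize(data[group_col])
        self.groups = codes
        self.q = len(self.group_labels)
        if self.q < 2:
            raise ValueError("shared-frailty model needs at least 2 groups")
        self.ws = BreslowWorkspace(self.entry, self.exit, self.event, self.w, self.X)
        self._G = np.zeros((len(data), self.q))
        self._G[np.arange(len(data)), codes] = 1.0

    # -- inner penalized Newton ----------------------------------------------

    def _inner(self, theta, beta, b, max_iter=25, tol=1e-8):
        ws = self.ws
        X, g_idx = self.X, self.groups
        Hbeta = None
        for it in range(max_iter):
            eta = X @ beta + b[g_idx]
            q = ws.quantities(eta)
            pen = float(b @ b) / (2 * theta)
            ll = q["loglik"] - pen
            g_eta = ws.grad_eta(q)
            g_beta = X.T @ g_eta
            g_b = np.bincount(g_idx, weights=g_eta, minlength=self.q) - b / theta
            gnorm = max(np.max(np.abs(g_beta), initial=0.0), np.max(np.abs(g_b)))
            if gnorm < tol * (1 + abs(ll)):
                break
            r = q["r"]
            K = np.bincount(g_idx, weights=r * q["A"] - r**2 * q["B"], minlength=self.q)
            K = np.maximum(K, 1e-10)
            Hbb = K + 1.0 / theta
            # exact cross block: C[:, f] = sum_{i in f} r_i (x_i A_i - D_i)
            cross_rows = r[:, None] * (X * q["A"][:, None] - q["D"])
            C = np.zeros((len(self.terms), self.q))
            np.add.at(C.T, g_idx, cross_rows)
            if Hbeta is None or it % 4 == 0:
                # the covariate information changes slowly; refresh sparingly
                Hbeta = ws.hess_beta(q)
            # Schur solve for the Newton step
            CinvH = C / Hbb[None, :]
            S = Hbeta - CinvH @ C.T
            S[np.diag_indices_from(S)] += 1e-10
            rhs = g_beta - CinvH @ g_b
            try:
                step_beta = np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError as err:
                raise ConvergenceFailure(f"singular Hessian in frailty fit: {err}")
            step_b = (g_b - C.T @ step_beta) / Hbb
            # step-halving on the penalized likelihood
            scale = 1.0
            for _ in range(30):
                nb = beta + scale * step_beta
                nbv = b + scale * step_b
                ll_new = ws.loglik(X @ nb + nbv[g_idx]) - float(nbv @ nbv) / (2 * theta)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            beta, b = beta + scale * step_beta, b + scale * step_b
        eta = X @ beta + b[g_idx]
        q = ws.quantities(eta)
        r = q["r"]
        K = np.maximum(
            np.bincount(g_idx, weights=r * q["A"] - r**2 * q["B"], minlength=self.q),
            1e-10)
        return beta, b, q, K, it + 1

    def _profile(self, theta, state):
        beta, b = state["beta"], state["b"]
        beta, b, q, K, _ = self._inner(theta, beta.copy(), b.copy())
        state["beta"], state["b"], state["q"], state["K"] = beta, b, q, K
        lm = (q["loglik"] - float(b @ b) / (2 * theta)
              - 0.5 * float(np.sum(np.log1p(theta * K))))
        return lm

    def fit(self) -> FrailtyResults:
        p = len(self.terms)
        state = {"beta": np.zeros(p), "b": np.zeros(self.q)}

        def neg(log_theta):
            return -self._profile(math.exp(log_theta), state)

        res = optimize.minimize_scalar(
            neg, bounds=(math.log(self.THETA_MIN), math.log(self.THETA_MAX)),
            method="bounded", options={"xatol": 2e-2})
        theta = float(math.exp(res.x))
        lm_hat = -float(res.fun)
        # curvature of the profile in theta for an SE
        h = max(0.25 * theta, 5e-3)
        lp = -neg(math.log(theta + h))
        lmm = -neg(math.log(max(theta - h, self.THETA_MIN / 2))) if theta - h > 0 else \
            -neg(math.log(self.THETA_MIN))
        d2 = (lp - 2 * lm_hat + lmm) / h**2
        se_theta = math.sqrt(-1.0 / d2) if d2 < -1e-12 else float("nan")

        beta, b, q, K, _ = self._inner(theta, state["beta"], state["b"])
        r = q["r"]
        Hbb = K + 1.0 / theta
        cross_rows = r[:, None] * (self.X * q["A"][:, None] - q["D"])
        C = np.zeros((p, self.q))
        np.add.at(C.T, self.groups, cross_rows)
        Hbeta = self.ws.hess_beta(q)
        S = Hbeta - (C / Hbb[None, :]) @ C.T
        vcov = np.linalg.inv(S)
        se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
        z = beta / np.where(se > 0, se, np.nan)
        pvals = 2 * stats.norm.sf(np.abs(z))
        zc = stats.norm.ppf(0.975)
        summary = pd.DataFrame({
            "coef": beta, "se": se, "hr": np.exp(beta),
            "ci_low": np.exp(beta - zc * se), "ci_high": np.exp(beta + zc * se),
            "p": pvals,
        }, index=self.terms)
        n_events = int(self.event.sum())
        bic = -2 * q["loglik"] + (p + 1) * math.log(max(n_events, 2))
        return FrailtyResults(
            summary_frame=summary,
            vcov=pd.DataFrame(vcov, index=self.terms, columns=self.terms),
            log_likelihood=float(q["loglik"]),
            n=len(self.exit), events=n_events,
            dropped_covariates=self.dropped,
            model=None,
            frailty_variance=theta if theta > 2 * self.THETA_MIN else 0.0,
            frailty_variance_se=se_theta,
            bic=bic,
            n_groups=self.q,
            converged=bool(res.success),
            random_effects=pd.Series(b, index=self.group_labels),
        )


# ---------------------------------------------------------------------------
# baselines and diagnostics


def km_nelson_aalen(
    df: pd.DataFrame,
    by: str | None = None,
    duration_col: str = "exit_age",
    event_col: str = "event",
    entry_col: str | None = "entry_age",
    weights_col: str | None = None,
) -> dict:
    """Left-truncation-aware Kaplan-Meier and Nelson-Aalen estimators,
    optionally per level of an exposure column.  Empty levels are omitted
    with a warning."""
    out = {}
    levels = [None] if by is None else sorted(df[by].dropna().unique())
    for lev in levels:
        sub = df if lev is None else df[df[by] == lev]
        if len(sub) == 0 or sub[event_col].sum() == 0:
            warnings.warn(f"level {lev!r} empty or event-free; omitted")
            continue
        kw = {}
        if entry_col is not None:
            kw["entry"] = sub[entry_col]
        if weights_col is not None:
            kw["weights"] = sub[weights_col]
        km = KaplanMeierFitter()
        na = NelsonAalenFitter(nelson_aalen_smoothing=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km.fit(sub[duration_col], sub[event_col], **kw)
            na.fit(sub[duration_col], sub[event_col], **kw)
        out[lev if lev is not None else "all"] = {
            "survival": km.survival_function_,
            "cumulative_hazard": na.cumulative_hazard_,
        }
    return out


def check_ph(
    results: CoxResults,
    data: pd.DataFrame | None = None,
    time_transform: str = "rank",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scaled-Schoenfeld-residual trend test per term (Grambsch-Therneau).

    Works with delayed entry and weights via the package's own risk-set
    machinery.  Terms failing at the given level are recommended for
    stratification.
    """
    model = results.model
    if model is None or data is None and model is None:
        raise ValueError("check_ph needs the originating model")
    df = model.data if data is None else data
    terms = [t for t in results.summary_frame.index]
    X = df[terms].to_numpy(dtype=float)
    entry = df[model.entry_col].to_numpy(dtype=float) if model.entry_col else np.zeros(len(df))
    exit_ = df[model.duration_col].to_numpy(dtype=float)
    event = df[model.event_col].to_numpy(dtype=float) > 0
    w = df[model.weights_col].to_numpy(dtype=float) if model.weights_col else np.ones(len(df))
    ws = BreslowWorkspace(entry, exit_, event, w, X)
    beta = results.params.loc[terms].to_numpy(dtype=float)
    q = ws.quantities(X @ beta)
    resid = ws.schoenfeld(q)                       # m x p
    t = ws.t_events
    if time_transform == "rank":
        g = stats.rankdata(t)
    elif time_transform == "log":
        g = np.log(t)
    else:
        g = t
    g = g - g.mean()
    info = ws.hess_beta(q)
    m = ws.m
    vbar = np.diag(info) / m
    u = g @ resid
    denom = np.sum(g**2) * vbar
    chisq = np.where(denom > 0, u**2 / denom, np.nan)
    p = stats.chi2.sf(chisq, df=1)
    return pd.DataFrame({
        "chisq": chisq, "p": p, "fails_ph": p < alpha,
        "recommend_strata": p < alpha,
    }, index=terms)


def bonferroni_posthoc(
    results: CoxResults,
    group_terms: list[str],
    alpha: float = 0.05,
    reference: str = "g6",
) -> pd.DataFrame:
    """All pairwise Wald contrasts among percentile groups (reference included
    as a zero-coefficient group), with Bonferroni-adjusted verdicts.

    For k groups the number of pairs is m = k(k-1)/2 and the adjusted
    threshold alpha/m; missing groups are skipped and reported with NaNs.
    """
    labels = list(group_terms) + [reference]
    k = len(labels)
    m = k * (k - 1) // 2
    V = results.vcov
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            if (a != reference and a not in results.params.index) or \
               (b != reference and b not in results.params.index):
                rows.append({"pair": f"{a} vs {b}", "estimate": np.nan, "se": np.nan,
                             "p": np.nan, "significant": False, "skipped": True})
                continue
            ca = results.params[a] if a != reference else 0.0
            cb = results.params[b] if b != reference else 0.0
            var = 0.0
            if a != reference:
                var += float(V.loc[a, a])
            if b != reference:
                var += float(V.loc[b, b])
            if a != reference and b != reference:
                var -= 2 * float(V.loc[a, b])
            est = ca - cb
            se = math.sqrt(max(var, 0.0))
            z = est / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if se > 0 else np.nan
            rows.append({"pair": f"{a} vs {b}", "estimate": est, "se": se, "p": p,
                         "significant": bool(p < alpha / m) if p == p else False,
                         "skipped": False})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = alpha / m
    out.attrs["n_pairs"] = m
    return out
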