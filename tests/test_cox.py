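"""Cox and shared-frailty models against brute-force oracles and null sims."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from famlong.cox import (
    ConvergenceFailure,
    CoxModel,
    SharedFrailtyCoxModel,
    bonferroni_posthoc,
    check_ph,
    km_nelson_aalen,
)
from famlong.simulate import simulate_frailty_cohort


def handwritten_efron_logpl(beta, entry, exit_, event, x, w):
    """Weighted Efron log partial likelihood with delayed entry, written
    directly from the definition (the independent oracle)."""
    beta = float(beta)
    ll = 0.0
    for t in sorted(set(exit_[event == 1])):
        D = [i for i in range(len(x)) if event[i] == 1 and exit_[i] == t]
        R = [i for i in range(len(x)) if entry[i] < t <= exit_[i]]
        wd = sum(w[i] for i in D)
        sum_d_eta = sum(w[i] * beta * x[i] for i in D)
        s_r = sum(w[i] * math.exp(beta * x[i]) for i in R)
        s_d = sum(w[i] * math.exp(beta * x[i]) for i in D)
        m = len(D)
        wbar = wd / m
        ll += sum_d_eta
        for l in range(m):
            ll -= wbar * math.log(s_r - (l / m) * s_d)
    return ll


def oracle_coef(entry, exit_, event, x, w):
    grid = np.linspace(-4, 4, 161)
    vals = [handwritten_efron_logpl(b, entry, exit_, event, x, w) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    res = optimize.minimize_scalar(
        lambda b: -handwritten_efron_logpl(b, entry, exit_, event, x, w),
        bracket=(b0 - 0.1, b0, b0 + 0.1), method="brent",
        options={"xtol": 1e-10})
    return float(res.x)


FIXTURES = {
    "plain": dict(
        entry=np.zeros(6),
        exit_=np.array([2.0, 3.0, 5.0, 7.0, 8.0, 11.0]),
        event=np.array([1, 1, 0, 1, 1, 1]),
        x=np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0]),
        w=np.ones(6)),
    "delayed_entry": dict(
        entry=np.array([0.0, 1.0, 2.5, 0.0, 4.0, 0.5]),
        exit_=np.array([2.0, 3.0, 5.0, 7.0, 8.0, 11.0]),
        event=np.array([1, 1, 1, 1, 0, 1]),
        x=np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0]),
        w=np.ones(6)),
    "weighted": dict(
        entry=np.zeros(7),
        exit_=np.array([1.0, 2.0, 4.0, 6.0, 7.0, 9.0, 12.0]),
        event=np.array([1, 0, 1, 1, 1, 1, 0]),
        x=np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 1.0]),
        w=np.array([0.25, 1.0, 0.5, 1.0, 0.75, 1.0, 0.5])),
    "efron_ties": dict(
        entry=np.zeros(8),
        exit_=np.array([3.0, 3.0, 3.0, 5.0, 5.0, 8.0, 8.0, 10.0]),
        event=np.array([1, 1, 0, 1, 1, 1, 0, 1]),
        x=np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0]),
        w=np.ones(8)),
    "weighted_truncated": dict(
        entry=np.array([0.5, 0.0, 1.0, 2.0, 0.0, 3.0]),
        exit_=np.array([2.0, 3.5, 4.0, 6.0, 7.5, 9.0]),
        event=np.array([1, 1, 1, 0, 1, 1]),
        x=np.array([1.0, 0.0, 0.0, 1.0, 1.0, 0.0]),
        w=np.array([0.5, 1.0, 0.75, 1.0, 0.25, 1.0])),
}


class TestPartialLikelihoodOracle:
    @pytest.mark.parametrize("name", list(FIXTURES))
    def test_coefficient_matches_bruteforce_maximum(self, name):
        fx = FIXTURES[name]
        expected = oracle_coef(**fx)
        df = pd.DataFrame({
            "entry_age": fx["entry"], "exit_age": fx["exit_"],
            "event": fx["event"], "x": fx["x"], "w": fx["w"],
        })
        fit = CoxModel(df, exposures=["x"], weights_col="w").fit()
        assert fit.params["x"] == pytest.approx(expected, abs=1e-4)

    def test_half_weight_duplication_reproduces_unweighted_fit(self):
        fx = FIXTURES["plain"]
        df = pd.DataFrame({
            "entry_age": fx["entry"], "exit_age": fx["exit_"],
            "event": fx["event"], "x": fx["x"],
        })
        base = CoxModel(df, exposures=["x"], ties="breslow").fit()
        dup = pd.concat([df, df], ignore_index=True)
        dup["w"] = 0.5
        weighted = CoxModel(dup, exposures=["x"], weights_col="w",
                            robust=False, ties="breslow").fit()
        assert weighted.params["x"] == pytest.approx(base.params["x"], abs=1e-8)

    def test_constant_exposure_is_inestimable(self):
        df = pd.DataFrame({
            "entry_age": 0.0, "exit_age": [1.0, 2, 3, 4], "event": 1,
            "x": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            CoxModel(df, exposures=["x"])

    def test_complete_separation_flagged(self):
        df = pd.DataFrame({
            "entry_age": 0.0,
            "exit_age": [1.0, 2, 3, 10, 11, 12],
            "event": 1,
            "x": [1.0, 1, 1, 0, 0, 0]})
        with pytest.raises(ConvergenceFailure):
            CoxModel(df, exposures=["x"]).fit()


class TestNullCoverage:
    def test_ci_covers_unit_hazard_ratio_at_nominal_rate(self):
        """Exposure independent of an exponential lifetime: 95% CIs cover
        HR = 1 at the nominal rate (99% binomial band)."""
        rng = np.random.default_rng(99)
        n, reps, cover = 300, 150, 0
        for _ in range(reps):
            x = rng.binomial(1, 0.4, n).astype(float)
            t = rng.exponential(10.0, n)
            df = pd.DataFrame({"entry_age": 0.0, "exit_age": t, "event": 1, "x": x})
            fit = CoxModel(df, exposures=["x"]).fit()
            lo, hi = fit.conf_int("x")
            cover += lo <= 1.0 <= hi
        half = 2.576 * math.sqrt(0.95 * 0.05 / reps)
        assert abs(cover / reps - 0.95) < half


class TestSharedFrailty:
    def test_degenerate_limit_matches_plain_cox(self):
        d = simulate_frailty_cohort(400, 0.0, seed=2, censor_prob=0.1)
        plain = CoxModel(d, entry_col=None, exposures=["female"]).fit()
        fr = SharedFrailtyCoxModel(d, entry_col=None, exposures=["female"],
                                   group_col="family_id").fit()
        assert fr.frailty_variance <= 0.02
        assert fr.params["female"] == pytest.approx(plain.params["female"], abs=5e-3)

    def test_null_variance_estimated_near_zero(self):
        d = simulate_frailty_cohort(1200, 0.0, seed=3)
        fr = SharedFrailtyCoxModel(d, entry_col=None, exposures=["female"],
                                   group_col="family_id").fit()
        assert fr.frailty_variance <= 0.02

    def test_variance_recovery_within_ci(self):
        hits = 0
        for s in range(5):
            d = simulate_frailty_cohort(900, 0.3, seed=40 + s)
            fr = SharedFrailtyCoxModel(d, entry_col=None, exposures=["female"],
                                       group_col="family_id").fit()
            lo, hi = fr.frailty_variance_ci()
            hits += lo <= 0.3 <= hi
        assert hits >= 4

    def test_needs_at_least_two_groups(self):
        d = simulate_frailty_cohort(5, 0.1, seed=1)
        d["family_id"] = 0
        with pytest.raises(ValueError, match="2 groups"):
            SharedFrailtyCoxModel(d, entry_col=None, exposures=["female"],
                                  group_col="family_id")


class TestBaselines:
    def test_km_equals_empirical_without_censoring(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 200)
        df = pd.DataFrame({"exit_age": t, "event": 1, "entry_age": 0.0})
        est = km_nelson_aalen(df)["all"]["survival"]
        grid = np.sort(t)
        emp = 1.0 - np.arange(1, 201) / 200
        km_at = est["KM_estimate"].reindex(grid).to_numpy()
        assert np.allclose(km_at, emp, atol=1e-10)

    def test_nelson_aalen_jump_is_one_over_at_risk(self):
        df = pd.DataFrame({
            "exit_age": [5.0, 6, 7, 8, 9], "event": [1, 0, 0, 0, 0],
            "entry_age": 0.0})
        na = km_nelson_aalen(df)["all"]["cumulative_hazard"]
        assert na.loc[5.0].iloc[0] == pytest.approx(1 / 5)

    def test_neg_log_km_tracks_nelson_aalen(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(5, 2000)
        c = rng.exponential(8, 2000)
        df = pd.DataFrame({"exit_age": np.minimum(t, c),
                           "event": (t <= c).astype(int), "entry_age": 0.0})
        res = km_nelson_aalen(df)["all"]
        km = res["survival"]["KM_estimate"]
        na = res["cumulative_hazard"].iloc[:, 0]
        keep = km > 0.05
        assert np.max(np.abs(-np.log(km[keep]) - na[keep])) < 0.02


class TestProportionalHazards:
    def test_false_positive_rate_near_alpha_under_ph(self):
        rng = np.random.default_rng(7)
        reps, flagged = 120, 0
        for _ in range(reps):
            n = 150
            x = rng.binomial(1, 0.5, n).astype(float)
            t = rng.exponential(10 / np.exp(0.3 * x))
            df = pd.DataFrame({"entry_age": 0.0, "exit_age": t, "event": 1, "x": x})
            fit = CoxModel(df, exposures=["x"]).fit()
            flagged += bool(check_ph(fit).loc["x", "fails_ph"])
        rate = flagged / reps
        assert abs(rate - 0.05) < 2.576 * math.sqrt(0.05 * 0.95 / reps) + 0.02

    def test_crossing_hazards_flagged_with_power(self):
        """Effect reversing sign mid-follow-up must be detected at n = 2000."""
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        # exposed: high hazard before t=5, low after (time-varying effect)
        t0 = rng.exponential(4.0, n)
        t = np.where(x == 1, np.where(t0 < 3, t0 * 0.5, t0 * 2.0), t0)
        df = pd.DataFrame({"entry_age": 0.0, "exit_age": t + 1e-4, "event": 1, "x": x})
        fit = CoxModel(df, exposures=["x"]).fit()
        assert bool(check_ph(fit).loc["x", "fails_ph"])

    def test_stratifying_flagged_covariate_removes_it_from_checks(self):
        rng = np.random.default_rng(9)
        n = 600
        strat = rng.binomial(1, 0.5, n)
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(10 / np.exp(0.4 * strat), n)
        df = pd.DataFrame({"entry_age": 0.0, "exit_age": t, "event": 1,
                           "x": x, "s": strat})
        fit = CoxModel(df, exposures=["x"], strata=["s"]).fit()
        report = check_ph(fit)
        assert "s" not in report.index and "x" in report.index


class TestBonferroniPosthoc:
    @staticmethod
    def _group_fit(seed=0, effects=(0, 0, 0, 0, 0)):
        rng = np.random.default_rng(seed)
        n = 1200
        g = rng.integers(1, 7, n)
        eta = np.array([0.0] + list(effects) + [0.0])[np.where(g == 6, 0, g)]
        t = rng.exponential(10 / np.exp(eta), n)
        df = pd.DataFrame({"entry_age": 0.0, "exit_age": t, "event": 1})
        for i in range(1, 6):
            df[f"g{i}"] = (g == i).astype(float)
        return df, CoxModel(df, exposures=[f"g{i}" for i in range(1, 6)]).fit()

    def test_threshold_is_alpha_over_fifteen(self):
        _, fit = self._group_fit()
        ph = bonferroni_posthoc(fit, [f"g{i}" for i in range(1, 6)])
        assert ph.attrs["n_pairs"] == 15
        assert ph.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 15)
        assert len(ph) == 15

    def test_identical_groups_yield_no_significant_pair(self):
        _, fit = self._group_fit(seed=5)
        ph = bonferroni_posthoc(fit, [f"g{i}" for i in range(1, 6)])
        assert not ph["significant"].any()

    def test_contrast_matches_rereferenced_refit(self):
        """The g1-vs-g2 contrast p equals the g1 term p when g2 is made the
        reference category (independent re-reference oracle)."""
        df, fit = self._group_fit(seed=6, effects=(0.5, -0.3, 0.1, 0.0, 0.2))
        ph = bonferroni_posthoc(fit, [f"g{i}" for i in range(1, 6)])
        p_contrast = ph.loc[ph["pair"] == "g1 vs g2", "p"].iloc[0]
        # re-reference: drop g2 dummy, add g6 dummy (so g2 becomes baseline)
        df2 = df.copy()
        g6 = 1.0 - df2[[f"g{i}" for i in range(1, 6)]].sum(axis=1)
        df2["g6"] = g6
        refit = CoxModel(
            df2, exposures=["g1", "g3", "g4", "g5", "g6"]).fit()
        assert p_contrast == pytest.approx(refit.summary_frame.loc["g1", "p"], rel=1e-6)
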