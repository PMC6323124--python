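"""Lifetable construction, percentile mapping, top-x classification."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famlong.lifetables import (
    CohortLifetable,
    GompertzMakehamParams,
    LifetableError,
    LifetableLookupError,
    ParseReport,
    build_from_hazards,
    classify_top_x,
    read_hmd_cohort_table,
    read_simple_csv,
    synthesize_collection,
    synthesize_lifetable,
    write_simple_csv,
)


class TestBuildFromHazards:
    def test_zero_hazard_gives_unit_survival(self):
        rows = [("F", 1800, a, 0.0) for a in range(100)]
        lt = build_from_hazards(rows).lookup("F", 1800)
        assert np.allclose(lt.survival, 1.0)

    def test_constant_hazard_closed_form(self):
        rows = [("M", 1800, a, 0.01) for a in range(100)]
        lt = build_from_hazards(rows).lookup("M", 1800)
        assert lt.survival[50] == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_age_gap_reports_missing_age(self):
        rows = [("F", 1800, a, 0.01) for a in (0, 1, 3)]
        with pytest.raises(LifetableError, match="missing age 2"):
            build_from_hazards(rows)

    def test_negative_hazard_rejected(self):
        with pytest.raises(LifetableError, match="negative"):
            build_from_hazards([("F", 1800, 0, -0.1)])

    def test_survival_consistent_with_hazard_sum(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(0, 0.3, 100)
        lt = CohortLifetable("F", None, h)
        expected = np.exp(-np.concatenate([[0.0], np.cumsum(h)]))
        assert np.max(np.abs(lt.survival - expected)) < 1e-12


class TestGompertzDiscretization:
    def test_matches_fine_grid_integration_oracle(self):
        """Midpoint yearly discretization agrees with a fine-grid numerical
        integral of the continuous hazard (independent oracle) to the
        midpoint-rule error bound."""
        p = GompertzMakehamParams(makeham=0.0, gompertz_a=1e-4, gompertz_b=0.1)
        lt = synthesize_lifetable(p, "F", a_max=109)
        grid = np.arange(0, 110.0005, 1e-3)
        h_fine = p.hazard(grid)
        H_oracle = np.concatenate([[0.0], np.cumsum((h_fine[1:] + h_fine[:-1]) / 2) * 1e-3])
        ages = np.arange(0, 110)
        H_oracle_at_ages = H_oracle[(ages / 1e-3).round().astype(int)]
        # midpoint rule on e^{bt}: relative error b^2/24 per interval
        rel_bound = p.gompertz_b**2 / 24 * 1.01 + 1e-9
        err = np.abs(lt.cum_hazard[ages] - H_oracle_at_ages)
        assert np.all(err <= rel_bound * np.maximum(H_oracle_at_ages, 1e-12) + 1e-12)

    def test_top_decile_age_matches_analytic_inversion(self):
        p = GompertzMakehamParams(makeham=0.0, gompertz_a=1e-4, gompertz_b=0.1)
        lt = synthesize_lifetable(p, "F")
        t_star = math.log(1 + (p.gompertz_b / p.gompertz_a) * math.log(10)) / p.gompertz_b
        assert abs(lt.age_at_percentile(10) - t_star) <= 1.0

    def test_constant_limit_and_monotonicity_in_b(self):
        lt0 = synthesize_lifetable(
            GompertzMakehamParams(makeham=0.01, gompertz_a=1e-12, gompertz_b=0.1), "F")
        assert lt0.survival_at(10) == pytest.approx(math.exp(-0.1), rel=1e-6)
        s80 = [
            synthesize_lifetable(
                GompertzMakehamParams(0.0, 1e-4, b), "F").survival_at(80)
            for b in (0.08, 0.10, 0.12)
        ]
        assert s80[0] > s80[1] > s80[2]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GompertzMakehamParams(gompertz_a=0.0)
        with pytest.raises(ValueError):
            GompertzMakehamParams(gompertz_b=-0.1)


class TestPercentiles:
    def test_birth_is_percentile_100(self, const_lifetable):
        assert const_lifetable.survival_percentile(0) == pytest.approx(100.0)

    def test_constant_hazard_closed_form(self, const_lifetable):
        assert const_lifetable.survival_percentile(50) == pytest.approx(
            100 * math.exp(-0.5), abs=1e-9)
        assert const_lifetable.age_at_percentile(100 * math.exp(-0.5)) == 50
        assert const_lifetable.age_at_percentile(100.0) == 0

    def test_percentile_age_inverse_consistency(self):
        """survival_percentile(age_at_percentile(p)) <= p for integer p."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = GompertzMakehamParams(
                makeham=rng.uniform(0, 0.02),
                gompertz_a=10 ** rng.uniform(-5, -3.5),
                gompertz_b=rng.uniform(0.07, 0.13))
            lt = synthesize_lifetable(p, "M")
            for pct in range(1, 100):
                a = lt.age_at_percentile(pct)
                assert lt.survival_percentile(a) <= pct
                if a > 0:
                    assert lt.survival_percentile(a - 1) > pct

    def test_domain_errors(self, const_lifetable):
        with pytest.raises(ValueError):
            const_lifetable.survival_percentile(-1)
        with pytest.raises(ValueError):
            const_lifetable.age_at_percentile(0.0)
        with pytest.raises(ValueError):
            const_lifetable.age_at_percentile(101.0)

    def test_beyond_table_carries_last_hazard(self, gm_tables):
        lt = gm_tables.lookup("F")
        p120 = lt.survival_percentile(120)
        assert 0 < p120 < lt.survival_percentile(lt.a_max)

    @given(st.lists(st.floats(0.0, 0.5), min_size=2, max_size=120))
    @settings(max_examples=50, deadline=None)
    def test_survival_monotone_hazard_nonneg(self, hazards):
        lt = CohortLifetable("F", None, np.array(hazards))
        assert np.all(np.diff(lt.survival) <= 1e-15)
        assert np.all(np.diff(lt.cum_hazard) >= -1e-15)
        assert lt.survival[0] == 1.0


class TestClassifyTopX:
    def test_deceased_above_threshold_age_is_top(self, gm_tables):
        lt = gm_tables.lookup("F")
        age = lt.age_at_percentile(10) + 1
        assert classify_top_x("F", None, age, None, gm_tables, 10) == "top"

    def test_censored_below_threshold_is_not_top(self, gm_tables):
        lt = gm_tables.lookup("F")
        age = lt.age_at_percentile(10) - 5
        assert classify_top_x("F", None, None, age, gm_tables, 10) == "not_top"

    def test_censored_beyond_threshold_counts_as_top(self, gm_tables):
        lt = gm_tables.lookup("F")
        age = lt.age_at_percentile(10) + 2
        assert classify_top_x("F", None, None, age, gm_tables, 10) == "top"

    def test_missing_ages_are_unknown(self, gm_tables):
        assert classify_top_x("F", None, None, None, gm_tables, 10) == "unknown"

    def test_classification_nests_in_x(self, gm_tables):
        rng = np.random.default_rng(5)
        lt = gm_tables.lookup("M")
        ages = lt.sample_ages(200, rng)
        for age in ages:
            prev = False
            for x in range(1, 61):
                now = classify_top_x("M", None, float(age), None, gm_tables, x) == "top"
                assert now or not prev  # once top, stays top as x grows
                prev = now

    def test_missing_table_lists_available_cohorts(self):
        coll = build_from_hazards([("F", 1800, a, 0.01) for a in range(100)])
        with pytest.raises(LifetableLookupError, match="1800"):
            coll.lookup("F", 1900)


class TestCalibration:
    def test_top_decile_fraction_matches_sampling(self, gm_tables):
        """Lifetimes drawn from a table's own survival curve must classify as
        top-10% at rate 0.10 (99% binomial band)."""
        lt = gm_tables.lookup("F")
        rng = np.random.default_rng(17)
        n = 20_000
        ages = lt.sample_ages(n, rng)
        frac = np.mean(100.0 * lt.survival_at(ages, interpolate=True) <= 10.0)
        half = 2.576 * math.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.10) < half


HMD_TOY = """Sweden, Cohort death rates (cohort 1x1)

Year Age mx qx ax lx dx Lx Tx ex
1750 0 0.2 0.18 0.3 100000 18000 90000 3000000 30.0
1750 1 0.1 0.09 0.5 82000 7000 78000 2910000 35.5
1750 2 0.05 0.04 0.5 75000 3000 73000 2830000 37.7
"""

HMD_MISSING = HMD_TOY + "1750 3 . . . 72000 . . . .\n"


class TestHmdParser:
    def test_toy_block_transcribed(self):
        coll = read_hmd_cohort_table(io.StringIO(HMD_TOY), sex="F")
        lt = coll.lookup("F", 1750)
        assert np.allclose(lt.hazard, [0.2, 0.1, 0.05])

    def test_sex_inferred_from_fltcoh_naming(self):
        text = HMD_TOY.replace("(cohort 1x1)", "fltcoh (cohort 1x1)")
        lt = read_hmd_cohort_table(io.StringIO(text)).lookup("F", 1750)
        assert lt.sex == "F"

    def test_missing_mx_imputed_and_flagged(self):
        report = ParseReport()
        coll = read_hmd_cohort_table(io.StringIO(HMD_MISSING), sex="M", report=report)
        lt = coll.lookup("M", 1750)
        assert lt.hazard[3] == pytest.approx(0.05)
        assert (1750, "M", 3) in report.imputed

    def test_malformed_header_rejected(self):
        with pytest.raises(LifetableError, match="header"):
            read_hmd_cohort_table(io.StringIO("Year Age qx mx\n1750 0 0.1 0.1\n"), sex="F")

    def test_simple_csv_round_trip(self):
        coll = read_hmd_cohort_table(io.StringIO(HMD_TOY), sex="F")
        buf = io.StringIO()
        write_simple_csv(coll, buf)
        buf.seek(0)
        again = read_simple_csv(buf)
        assert np.array_equal(coll.lookup("F", 1750).hazard,
                              again.lookup("F", 1750).hazard)
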