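"""Crude/MH estimation from 2x2 tables and printed-summary reconstruction."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from prevratio import (ContingencyTable2x2, NoConsistentTableError,
                       StratifiedTables, UndefinedEstimateError,
                       ValidationError, crude_or, crude_pr, mh_pr,
                       reconstruct_table, wald_ci)

tables_st = st.builds(
    ContingencyTable2x2,
    a=st.integers(1, 400), b=st.integers(1, 400),
    c=st.integers(1, 400), d=st.integers(1, 400))


class TestCrudeEstimates:
    def test_symmetric_table_gives_null_ratios(self):
        t = ContingencyTable2x2(10, 10, 10, 10)
        assert crude_pr(t).point == pytest.approx(1.0)
        assert crude_or(t).point == pytest.approx(1.0)

    def test_known_table_point_and_se(self, simple_table):
        e = crude_pr(simple_table)
        assert e.point == pytest.approx(2.0)
        assert e.se_log == pytest.approx(math.sqrt(0.28))
        o = crude_or(simple_table)
        assert o.point == pytest.approx(10 * 95 / (90 * 5))
        assert o.se_log == pytest.approx(math.sqrt(1 / 10 + 1 / 90 + 1 / 5 + 1 / 95))

    def test_delta_se_agrees_with_multinomial_bootstrap(self):
        # large-count regime, where the first-order (delta) SE is accurate
        cells = np.array([500, 4500, 250, 4750])
        n = cells.sum()
        boot = np.random.default_rng(7).multinomial(n, cells / n, size=200_000)
        a, b, c, d = boot.T
        ok = (a > 0) & (c > 0)
        ln_pr = np.log((a[ok] / (a[ok] + b[ok])) / (c[ok] / (c[ok] + d[ok])))
        analytic = crude_pr(ContingencyTable2x2(*cells)).se_log
        assert ln_pr.std(ddof=1) == pytest.approx(analytic, rel=0.01)

    @pytest.mark.parametrize("cells,estimator", [
        ((10, 90, 0, 100), crude_pr),   # zero unexposed cases
        ((0, 100, 5, 95), crude_pr),    # zero exposed cases
        ((10, 0, 5, 95), crude_or),     # zero OR cell
    ])
    def test_zero_cells_are_reported_not_infinite(self, cells, estimator):
        with pytest.raises(UndefinedEstimateError):
            estimator(ContingencyTable2x2(*cells))

    def test_optional_continuity_correction(self):
        t = ContingencyTable2x2(10, 90, 0, 100)
        e = crude_pr(t, correction=0.5)
        assert e.point == pytest.approx((10.5 / 101) / (0.5 / 101))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @given(tables_st)
    def test_or_at_least_pr_for_risk_factors(self, t):
        pr, orr = crude_pr(t).point, crude_or(t).point
        if pr > 1 and 0 < t.p2 < t.p1 < 1:
            assert orr >= pr


class TestWaldCI:
    def test_reproduces_published_interval_limits(self):
        # +-1 in the last printed digit: the published point/SE inputs are
        # themselves rounded
        lo, hi = wald_ci(3.294, 0.7126)
        assert round(lo, 3) == 0.815
        lo2, hi2 = wald_ci(3.493, 0.2999)
        assert abs(lo2 - 1.940) <= 0.001
        assert abs(hi2 - 6.287) <= 0.001

    def test_zero_se_degenerates_to_point(self):
        assert wald_ci(2.5, 0.0) == (2.5, 2.5)

    @given(st.floats(0.05, 20), st.floats(0.001, 2), st.floats(0.5, 0.995))
    def test_round_trip_recovers_se(self, point, se, level):
        from scipy.stats import norm
        lo, hi = wald_ci(point, se, level)
        z = norm.ppf(0.5 + level / 2)
        assert math.log(hi / lo) / (2 * z) == pytest.approx(se, abs=1e-12)

    def test_interval_symmetric_on_log_scale(self, simple_table):
        e = crude_pr(simple_table)
        assert math.log(e.ci_high / e.point) == pytest.approx(
            math.log(e.point / e.ci_low), abs=1e-12)


class TestMantelHaenszel:
    def test_single_stratum_equals_crude(self, simple_table):
        pooled = mh_pr(StratifiedTables([("all", simple_table)]))
        crude = crude_pr(simple_table)
        assert pooled.point == crude.point
        assert pooled.se_log == pytest.approx(crude.se_log, abs=1e-12)

    def test_identical_strata_collapse_to_pooled_crude(self, simple_table):
        est = mh_pr([("s1", simple_table), ("s2", simple_table)])
        assert est.point == pytest.approx(2.0)

    def test_matches_direct_weighted_sum_oracle(self):
        # confounded pair: exposure and risk both higher in stratum 2
        strata = [("young", ContingencyTable2x2(8, 392, 10, 990)),
                  ("old", ContingencyTable2x2(60, 540, 15, 285))]
        est = mh_pr(strata)
        num = sum(t.a * t.n0 / t.n for _, t in strata)
        den = sum(t.c * t.n1 / t.n for _, t in strata)
        assert est.point == pytest.approx(num / den, abs=1e-12)
        v = sum(((t.a + t.c) * t.n1 * t.n0 - t.a * t.c * t.n) / t.n**2
                for _, t in strata)
        assert est.se_log == pytest.approx(math.sqrt(v / (num * den)), abs=1e-12)

    def test_adjustment_removes_positive_confounding(self):
        strata = [("young", ContingencyTable2x2(8, 392, 10, 990)),
                  ("old", ContingencyTable2x2(60, 540, 15, 285))]
        pooled = ContingencyTable2x2(
            a=sum(t.a for _, t in strata), b=sum(t.b for _, t in strata),
            c=sum(t.c for _, t in strata), d=sum(t.d for _, t in strata))
        assert crude_pr(pooled).point > mh_pr(strata).point

    def test_duplicate_stratum_labels_rejected(self, simple_table):
        with pytest.raises(ValidationError):
            StratifiedTables([("s", simple_table), ("s", simple_table)])


class TestReconstruction:
    def test_round_trip_contains_source_table(self, simple_table):
        e = crude_pr(simple_table)
        found = reconstruct_table(200, 0.075, 2.0, round(e.se_log, 5))
        assert simple_table in found
        keys = [(t.a, t.b) for t in found]
        assert keys == sorted(keys)  # deterministic (a, b) ordering

    def test_published_marijuana_row_reconstructs_and_refits(self, marijuana_table):
        t = marijuana_table
        e_pr, e_or = crude_pr(t), crude_or(t)
        assert round(e_pr.point, 3) == 3.493
        assert round(e_pr.se_log, 4) == 0.2999
        # published OR 3.771 at +-1 in the last printed digit (rounded inputs)
        assert abs(e_or.point - 3.771) <= 0.0015

    def test_infeasible_summary_reports_nearest_misses(self):
        with pytest.raises(NoConsistentTableError) as exc:
            reconstruct_table(10, 0.9, 5.0, 0.01)
        assert "no consistent table" in str(exc.value)

    def test_or_hint_filters_results(self, simple_table):
        e = crude_pr(simple_table)
        found = reconstruct_table(200, 0.075, 2.0, round(e.se_log, 5),
                                  or_hint=2.111)
        assert all(round(crude_or(t).point, 3) == 2.111 for t in found)
        assert simple_table in found

    def test_tolerance_widens_matching_window(self):
        # exact printed rounding admits no table for the published 1.8%-
        # prevalence row; a wider final-digit window returns approximants
        with pytest.raises(NoConsistentTableError):
            reconstruct_table(5810, 0.018, 3.294, 0.7126)
        near = reconstruct_table(5810, 0.018, 3.294, 0.7126, tol_units=4)
        assert near
        best = min(near, key=lambda t: abs(crude_pr(t).se_log - 0.7126))
        assert crude_pr(best).se_log == pytest.approx(0.7126, abs=4e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            reconstruct_table(100, 0.001, 2.0, 0.5)  # n * prevalence < 1
        with pytest.raises(ValidationError):
            reconstruct_table(0, 0.5, 2.0, 0.5)
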