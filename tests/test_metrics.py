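"""Accuracy metrics: percent differences, confusion, kappa, weight tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ipwet import (
    CohortConfig,
    IpwetError,
    OutOfRangeError,
    PercentDifferenceSummary,
    ZoneConfusion,
    cohort_summary,
    confusion_by_zone,
    corrected_summary,
    generate_cohort,
    percent_difference,
    pooled_sensitivity,
    predicted_weight,
    summarize_percent_difference_by_zone,
    within_tolerance_accuracy,
    zone_metrics,
    zone_weight_table,
)
from ipwet.tape import assign_zones

from conftest import make_cohort


def cohort_with_d(heights, d_values, tape):
    """Children at given heights whose percent differences are exactly d."""
    b = np.array([predicted_weight(h, tape) for h in heights])
    a = 100.0 * b / (100.0 + np.asarray(d_values, dtype=float))
    return make_cohort(heights=heights, weights=a)


class TestPercentDifference:
    def test_arithmetic(self):
        assert percent_difference(10.85, 10.0) == pytest.approx(8.5)
        assert percent_difference(10.0, 10.0) == 0.0

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(OutOfRangeError):
            percent_difference(10.0, 0.0)

    def test_not_antisymmetric_but_zero_on_diagonal(self):
        assert percent_difference(8.0, 10.0) != -percent_difference(10.0, 8.0)
        for x in (0.3, 5.0, 36.0):
            assert percent_difference(x, x) == 0.0


class TestZoneSummaries:
    def test_known_zone_mean_and_sd(self, broselow):
        c = cohort_with_d([50.0, 52.0, 54.0], [10.0, 8.0, 6.0], broselow)
        rows, overall = summarize_percent_difference_by_zone(c, broselow)
        assert len(rows) == 1 and rows[0].zone == "gray"
        assert rows[0].mean_d == pytest.approx(8.0)
        assert rows[0].sd_d == pytest.approx(2.0)
        assert overall.mean_d == pytest.approx(8.0)

    def test_overall_equals_weighted_zone_mean(self, study_cohort, broselow):
        rows, overall = summarize_percent_difference_by_zone(
            study_cohort, broselow
        )
        weighted = sum(r.n * r.mean_d for r in rows) / sum(r.n for r in rows)
        assert overall.mean_d == pytest.approx(weighted, abs=1e-12)
        assert sum(r.n for r in rows) == overall.n == len(study_cohort)

    def test_single_child_zone_flagged_degenerate(self, broselow):
        c = cohort_with_d([50.0], [5.0], broselow)
        rows, _ = summarize_percent_difference_by_zone(c, broselow)
        assert rows[0].degenerate and rows[0].sd_d == 0.0

    def test_out_of_range_child_listed(self, broselow):
        c = make_cohort(heights=[100.0, 160.0], weights=[15.0, 30.0])
        with pytest.raises(OutOfRangeError, match="K001"):
            summarize_percent_difference_by_zone(c, broselow)


class TestCorrectedSummary:
    @pytest.mark.parametrize(
        "mean_before, expected_after",
        [(4.30, -4.04), (9.86, 1.07)],  # pink and white zone means
    )
    def test_printed_table_cells(self, mean_before, expected_after):
        s = PercentDifferenceSummary(zone="z", n=10, mean_d=mean_before, sd_d=12.0)
        out = corrected_summary(s, 0.08)
        assert round(out.mean_d, 2) == expected_after

    def test_zero_factor_is_identity(self):
        s = PercentDifferenceSummary(zone="z", n=5, mean_d=3.3, sd_d=1.1)
        assert corrected_summary(s, 0.0) == s

    def test_invalid_factor_rejected(self):
        s = PercentDifferenceSummary(zone="z", n=5, mean_d=3.3, sd_d=1.1)
        with pytest.raises(IpwetError):
            corrected_summary(s, 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        mean=st.floats(-30, 30),
        sd=st.floats(0, 40),
        f=st.floats(0, 0.99, exclude_max=True),
    )
    def test_exact_identity(self, mean, sd, f):
        s = PercentDifferenceSummary(zone="z", n=3, mean_d=mean, sd_d=sd)
        out = corrected_summary(s, f)
        assert out.mean_d == pytest.approx((1 - f) * mean - 100 * f, abs=1e-9)
        assert out.sd_d == pytest.approx((1 - f) * sd, abs=1e-9)


class TestWithinTolerance:
    def test_perfect_cohort(self, broselow):
        c = cohort_with_d([50.0, 100.0, 140.0], [0.0, 0.0, 0.0], broselow)
        overall, per_zone = within_tolerance_accuracy(c, broselow)
        assert overall == 1.0
        assert all(v == 1.0 for v in per_zone.values())

    def test_two_of_three_within(self, broselow):
        c = cohort_with_d([50.0, 52.0, 54.0], [5.0, -9.0, 15.0], broselow)
        overall, _ = within_tolerance_accuracy(c, broselow, tol=0.10)
        assert overall == pytest.approx(2 / 3)

    def test_study_conditions_accuracy_band(self, large_cohort, broselow):
        # Monte-Carlo derived band for the study bias/dispersion
        overall, _ = within_tolerance_accuracy(large_cohort, broselow)
        assert 0.4 < overall < 0.7


class TestConfusion:
    def test_perfect_cohort_no_errors(self, ipwet_tape):
        heights = [55.0, 70.0, 78.0, 90.0, 100.0, 115.0, 125.0, 135.0, 145.0]
        b = [predicted_weight(h, ipwet_tape) for h in heights]
        c = make_cohort(heights=heights, weights=b)
        confusions, unclassified = confusion_by_zone(c, ipwet_tape)
        assert unclassified == 0
        assert all(cf.fp == 0 and cf.fn == 0 for cf in confusions)

    def test_hand_enumerated_counts(self, ipwet_tape):
        # six children, two zones; one red-height child has a gray weight
        heights = [55.0, 60.0, 62.0, 75.0, 78.0, 80.0]
        weights = [5.0, 5.5, 6.0, 9.0, 9.5, 5.2]
        c = make_cohort(heights=heights, weights=weights)
        confusions, unclassified = confusion_by_zone(c, ipwet_tape)
        by = {cf.zone: cf for cf in confusions}
        # brute-force enumeration by hand: gray holds children 0-2 by height
        # and 0-2,5 by weight; red holds 3-5 by height, 3-4 by weight
        assert (by["gray"].tp, by["gray"].fp, by["gray"].fn, by["gray"].tn) == (
            3, 0, 1, 2,
        )
        assert (by["red"].tp, by["red"].fp, by["red"].fn, by["red"].tn) == (
            2, 1, 0, 3,
        )
        assert unclassified == 0

    def test_tp_sum_equals_matched_children(self, study_cohort, broselow):
        confusions, _ = confusion_by_zone(study_cohort, broselow)
        matched = assign_zones(study_cohort, broselow)["match"].sum()
        assert sum(cf.tp for cf in confusions) == matched

    def test_pooled_sensitivity_equals_match_rate(self, study_cohort, broselow):
        confusions, _ = confusion_by_zone(study_cohort, broselow)
        az = assign_zones(study_cohort, broselow)
        classifiable = az["weight_zone"].notna()
        expected = az.loc[classifiable, "match"].mean()
        assert pooled_sensitivity(confusions) == pytest.approx(expected)


class TestZoneMetrics:
    def test_perfect_agreement(self):
        m = zone_metrics(ZoneConfusion("z", tp=50, fp=0, fn=0, tn=50))
        assert (m.sensitivity, m.specificity, m.kappa) == (1.0, 1.0, 1.0)

    def test_chance_agreement_kappa_zero(self):
        m = zone_metrics(ZoneConfusion("z", tp=25, fp=25, fn=25, tn=25))
        assert m.kappa == pytest.approx(0.0)

    def test_zero_margin_reported_undefined(self):
        m = zone_metrics(ZoneConfusion("z", tp=0, fp=0, fn=0, tn=10))
        assert m.sensitivity is None
        assert m.chi2_p is None

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 30),
        fp=st.integers(0, 30),
        fn=st.integers(0, 30),
        tn=st.integers(0, 30),
    )
    def test_kappa_matches_independent_po_pe_oracle(self, tp, fp, fn, tn):
        n = tp + fp + fn + tn
        m = zone_metrics(ZoneConfusion("z", tp, fp, fn, tn))
        if n == 0:
            assert m.kappa is None
            return
        p_o = (tp + tn) / n
        p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
        if p_e < 1:
            assert m.kappa == pytest.approx((p_o - p_e) / (1 - p_e))
            assert -1.0 <= m.kappa <= 1.0


class TestZoneWeightTable:
    def test_corrected_identity_and_known_example(self, broselow):
        c = cohort_with_d(
            [50.0, 52.0, 54.0, 100.0, 104.0], [6.0, 9.0, 12.0, 4.0, 11.0], broselow
        )
        rows = zone_weight_table(c, broselow, f=0.08)
        for r in rows:
            assert r.mean_corrected == pytest.approx(0.92 * r.mean_predicted)
            assert r.sd_corrected == pytest.approx(0.92 * r.sd_predicted)
            assert r.mean_corrected < r.mean_predicted

    def test_zero_factor_collapses_columns(self, study_cohort, broselow):
        rows = zone_weight_table(study_cohort, broselow, f=0.0)
        for r in rows:
            assert r.mean_corrected == r.mean_predicted
            assert r.p_corrected == r.p_uncorrected

    def test_single_child_zone_undefined_pvalues(self, broselow):
        c = cohort_with_d([50.0], [5.0], broselow)
        rows = zone_weight_table(c, broselow, f=0.08)
        assert rows[0].p_uncorrected is None


class TestCohortSummary:
    def test_exact_linear_cohort(self, broselow):
        h = np.linspace(60, 140, 12)
        c = make_cohort(
            heights=h,
            weights=0.15 * h,
            sexes=["M", "F"] * 6,
            ages=np.linspace(10, 120, 12),
        )
        s = cohort_summary(c, broselow)
        assert s.corr_weight_height == pytest.approx(1.0)
        assert s.r2_by_sex["M"] == pytest.approx(1.0)
        assert s.r2_by_sex["F"] == pytest.approx(1.0)

    def test_small_cohort_rejected(self, broselow):
        c = make_cohort(heights=[100.0, 101.0], weights=[14.0, 15.0])
        with pytest.raises(IpwetError):
            cohort_summary(c, broselow)

    def test_study_cohort_correlations(self, large_cohort, broselow):
        s = cohort_summary(large_cohort, broselow)
        assert s.corr_weight_height >= 0.90
        assert s.corr_height_predicted >= 0.95
        assert 0.8 <= min(s.r2_by_sex.values())
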