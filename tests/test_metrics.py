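"""Screening metrics, 2x2 reconstruction, Welch t and chi-square checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lacerisk import (
    ConfusionMatrix,
    GroupSummary,
    chi2_2x2,
    classification_metrics,
    compare_groups,
    confusion_matrix,
    reconstruct_confusion,
    welch_t_from_summary,
)

counts = st.integers(min_value=1, max_value=5000)


class TestConfusionMatrix:
    def test_simple_crosstab(self):
        cm = confusion_matrix([1, 0], [1, 0])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 0, 0, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_matrix([1], [1, 0])

    def test_reconstruction_from_reported_trauma_numbers(self):
        # sensitivity 13.81% of 804 positives, specificity 91.63% of 11,786;
        # the reported flagged count (1098) implies tn = 10,799, one off from
        # round(0.9163 * 11786) = 10,800 — a rounding ambiguity of the
        # printed specificity that shifts no derived metric beyond 0.02 pp.
        cm = reconstruct_confusion(804, 11_786, 0.1381, 0.9163)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (111, 986, 693, 10_800)
        assert abs(cm.n_flagged - 1098) <= 1

    def test_reconstruction_from_reported_general_numbers(self):
        cm = reconstruct_confusion(2_192, 16_928, 0.4480, 0.7147)
        assert (cm.tp, cm.fn) == (982, 1_210)
        assert abs(cm.tn - 12_099) <= 1


class TestClassificationMetrics:
    def test_trauma_screening_profile(self):
        m = classification_metrics(ConfusionMatrix(111, 987, 693, 10_799))
        assert m.sensitivity == pytest.approx(0.1381, abs=2e-4)
        assert m.specificity == pytest.approx(0.9163, abs=2e-4)
        assert m.ppv == pytest.approx(0.1011, abs=2e-4)
        assert m.npv == pytest.approx(0.9397, abs=2e-4)
        assert m.accuracy == pytest.approx(0.8668, abs=5e-4)

    def test_general_screening_profile(self):
        m = classification_metrics(ConfusionMatrix(982, 4_829, 1_210, 12_099))
        assert m.ppv == pytest.approx(0.1690, abs=2e-4)
        assert m.npv == pytest.approx(0.9091, abs=2e-4)
        assert m.accuracy == pytest.approx(0.684, abs=5e-4)
        assert m.prevalence == pytest.approx(0.1146, abs=5e-5)

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionMatrix(10, 0, 0, 90))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_undefined_metric_is_none_with_warning(self):
        with pytest.warns(RuntimeWarning, match="ppv"):
            m = classification_metrics(ConfusionMatrix(0, 0, 5, 95))
        assert m.ppv is None
        assert m.sensitivity == 0.0

    def test_accuracy_ci_contains_accuracy(self):
        m = classification_metrics(ConfusionMatrix(111, 987, 693, 10_799))
        lo, hi = m.accuracy_ci
        assert lo < m.accuracy < hi

    @given(tp=counts, fp=counts, fn=counts, tn=counts)
    def test_bayes_and_accuracy_identities(self, tp, fp, fn, tn):
        m = classification_metrics(ConfusionMatrix(tp, fp, fn, tn))
        prev, sens, spec = m.prevalence, m.sensitivity, m.specificity
        assert m.accuracy == pytest.approx(prev * sens + (1 - prev) * spec)
        flagged = prev * sens + (1 - prev) * (1 - spec)
        assert m.flagged_rate == pytest.approx(flagged)
        assert m.ppv == pytest.approx(prev * sens / flagged)
        assert m.npv == pytest.approx(
            (1 - prev) * spec / ((1 - prev) * spec + prev * (1 - sens)))
        assert m.nir == max(prev, 1 - prev)


class TestWelchT:
    def test_identical_groups_give_zero(self):
        g = GroupSummary(50, 5.0, 2.0)
        assert welch_t_from_summary(g, g).statistic == 0.0

    def test_general_cohort_lace_row(self):
        r = welch_t_from_summary(GroupSummary(2_192, 9.17, 3.09),
                                 GroupSummary(16_928, 7.82, 2.92))
        assert r.statistic == pytest.approx(19.38, abs=0.05)
        assert r.p < 0.001

    def test_general_cohort_age_row(self):
        r = welch_t_from_summary(GroupSummary(2_192, 51.64, 16.15),
                                 GroupSummary(16_928, 49.49, 17.33))
        assert r.statistic == pytest.approx(5.81, abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(GroupSummary(5, 1.0, 0.0),
                                 GroupSummary(5, 2.0, 0.0))

    @given(n1=st.integers(2, 500), n2=st.integers(2, 500),
           m1=st.floats(-5, 5), m2=st.floats(-5, 5),
           s1=st.floats(0.1, 5), s2=st.floats(0.1, 5))
    def test_df_within_welch_bounds(self, n1, n2, m1, m2, s1, s2):
        r = welch_t_from_summary(GroupSummary(n1, m1, s1),
                                 GroupSummary(n2, m2, s2))
        assert min(n1, n2) - 1 <= r.df + 1e-9
        assert r.df <= n1 + n2 - 2 + 1e-9


class TestChi2:
    def test_independent_table_is_zero(self):
        assert chi2_2x2(10, 10, 10, 10).statistic == 0.0

    def test_trauma_sex_table_with_correction(self):
        r = chi2_2x2(80, 724, 1_814, 9_972)
        assert r.statistic == pytest.approx(17.01, abs=0.05)
        assert r.df == 1 and r.p < 0.001

    def test_trauma_sex_table_without_correction(self):
        r = chi2_2x2(80, 724, 1_814, 9_972, correction=False)
        assert r.statistic == pytest.approx(17.44, abs=0.05)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 5, 5)

    @given(a=counts, b=counts, c=counts, d=counts)
    def test_yates_never_exceeds_uncorrected(self, a, b, c, d):
        corrected = chi2_2x2(a, b, c, d, correction=True).statistic
        plain = chi2_2x2(a, b, c, d, correction=False).statistic
        assert corrected <= plain + 1e-12


class TestCompareGroups:
    def test_copied_groups_give_null_statistics(self, scored_general_frame):
        half = scored_general_frame.head(100).copy()
        pos = half.assign(outcome="unplanned_readmission")
        neg = half.assign(outcome="other")
        table = compare_groups(pd.concat([pos, neg], ignore_index=True))
        for name, r in table.items():
            assert r.statistic == pytest.approx(0.0, abs=1e-9), name

    def test_summaries_match_raw_columns(self, scored_general_frame):
        table = compare_groups(scored_general_frame)
        pos = scored_general_frame[
            scored_general_frame["outcome"] == "unplanned_readmission"]
        g1 = table["lace_score"].summaries[0]
        assert g1.n == len(pos)
        assert g1.mean == pytest.approx(pos["lace_total"].mean())
        assert g1.sd == pytest.approx(pos["lace_total"].std(ddof=1))

    def test_expected_variables_present(self, scored_general_frame):
        table = compare_groups(scored_general_frame)
        assert set(table) == {"age", "los", "comorbidity_score", "lace_score",
                              "sex", "admission_type"}
        assert table["sex"].kind == "chi2_2x2"
        assert table["age"].kind == "welch_t"

    def test_empty_group_rejected(self, scored_general_frame):
        allneg = scored_general_frame.assign(outcome="other")
        with pytest.raises(ValueError, match="unplanned"):
            compare_groups(allneg)
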