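"""Text normalisation, keyword matching, CCI computation, concordance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lacerisk import (
    CharlsonExtractor,
    age_points,
    charlson_score,
    concordance,
    match_conditions,
    normalize_text,
    records_to_frame,
)
from lacerisk.records import PatientRecord


def _rec(text, age):
    return PatientRecord(
        patient_id="x", cohort="general", age=age, sex="unknown",
        admission_type="elective", los_days=0, ed_visits_6mo=0,
        history_text=text, outcome="other",
    )


class TestNormalizeText:
    @pytest.mark.parametrize(
        "raw,tokens",
        [
            ("Known DM, HPT.", ["known", "dm", "hpt"]),
            ("", []),
            ("   \t ", []),
            ("CA w/o mets", ["ca", "w/o", "mets"]),
            ("moderate‐severe CKD", ["moderate-severe", "ckd"]),
            ("fall; assault? (old notes)", ["fall", "assault", "old", "notes"]),
        ],
    )
    def test_examples(self, raw, tokens):
        assert normalize_text(raw) == tokens

    def test_deterministic(self):
        s = "Known DM / previous CVA - now stable."
        assert normalize_text(s) == normalize_text(s)


class TestMatchConditions:
    def test_two_plus_one_conditions(self, dictionary):
        hits = match_conditions(normalize_text("history of CCF and COPD"),
                                dictionary)
        assert sorted(hits.values()) == [1, 1]

    def test_longest_match_blocks_inner_abbreviation(self, dictionary):
        hits = match_conditions(normalize_text("metastatic solid CA"), dictionary)
        assert list(hits.values()) == [6]

    def test_synonyms_deduplicate(self, dictionary):
        hits = match_conditions(
            normalize_text("DM on insulin, diet-controlled diabetes"), dictionary)
        assert list(hits.values()) == [2]

    def test_severity_dominance_in_liver_group(self, dictionary):
        hits = match_conditions(
            normalize_text("cirrhosis with severe liver disease"), dictionary)
        assert list(hits.values()) == [3]

    def test_abbreviations_require_whole_tokens(self, dictionary):
        assert match_conditions(normalize_text("scam massive dmx"), dictionary) == {}

    def test_repeat_mentions_count_once(self, dictionary):
        once = match_conditions(normalize_text("stroke"), dictionary)
        thrice = match_conditions(normalize_text("stroke stroke stroke"), dictionary)
        assert once == thrice

    def test_negation_flag(self, dictionary):
        tokens = normalize_text("no DM, denies angina")
        assert sum(match_conditions(tokens, dictionary).values()) == 3
        assert match_conditions(tokens, dictionary, negation=True) == {}


class TestAgePoints:
    @pytest.mark.parametrize(
        "age,pts",
        [(0, 0), (35, 0), (40, 0), (41, 0), (49.9, 0), (50, 1), (52, 1),
         (59, 1), (60, 2), (75, 3), (85, 4), (95, 5), (100, 6)],
    )
    def test_completed_decades_past_40(self, age, pts):
        assert age_points(age) == pts

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            age_points(-1)

    @given(st.floats(min_value=0, max_value=110, allow_nan=False),
           st.floats(min_value=0, max_value=20, allow_nan=False))
    def test_non_decreasing_and_zero_through_40(self, age, bump):
        assert age_points(age + bump) >= age_points(age)
        if age <= 40:
            assert age_points(age) == 0


class TestCharlsonScore:
    @pytest.mark.parametrize(
        "text,age,expected",
        [
            ("metastatic solid CA", 35, 6),
            ("", 20, 0),
            ("jaundice", 52, 3 + 1),
            ("known DM and CCF", 75, 2 + 1 + 3),
            ("no significant history", 90, 5),
        ],
    )
    def test_examples(self, dictionary, text, age, expected):
        assert charlson_score(_rec(text, age), dictionary) == expected

    @given(st.sampled_from([
        "AIDS", "DM", "stroke", "jaundice", "COPD", "renal disease",
        "metastatic solid CA", "congestive cardiac failure",
    ]), st.sampled_from(["", "previously well", "known COPD and mass"]))
    def test_appending_a_surface_form_never_decreases_cci(
            self, dictionary, form, base):
        before = charlson_score(_rec(base, 30), dictionary)
        after = charlson_score(_rec(base + " , " + form, 30), dictionary)
        assert after >= before

    def test_phrase_order_irrelevant(self, dictionary):
        a = charlson_score(_rec("known DM. known stroke. known jaundice", 45),
                           dictionary)
        b = charlson_score(_rec("known jaundice. known DM. known stroke", 45),
                           dictionary)
        assert a == b == 2 + 1 + 3


class TestConcordance:
    def test_identical_sequences(self):
        assert concordance([3] * 52, [3] * 52) == 1.0

    def test_45_of_52(self):
        a = list(range(52))
        b = a[:45] + [x + 1 for x in a[45:]]
        assert round(concordance(a, b), 4) == 0.8654

    def test_errors(self):
        with pytest.raises(ValueError):
            concordance([], [])
        with pytest.raises(ValueError):
            concordance([1, 2], [1])


class TestCharlsonExtractor:
    def test_transform_matches_row_wise_scores(self, extractor, dictionary,
                                               small_general_frame):
        frame = small_general_frame.head(40)
        out = extractor.transform(frame).ravel()
        manual = [charlson_score(_rec(t, a), dictionary)
                  for t, a in zip(frame["history_text"], frame["age"])]
        assert out.tolist() == manual

    def test_requires_fit(self, small_general_frame):
        with pytest.raises(RuntimeError, match="not fitted"):
            CharlsonExtractor().transform(small_general_frame)

    def test_missing_columns(self, extractor):
        import pandas as pd
        with pytest.raises(KeyError, match="age"):
            extractor.transform(pd.DataFrame({"history_text": ["x"]}))

    def test_sklearn_params_round_trip(self):
        est = CharlsonExtractor(negation=True)
        assert CharlsonExtractor(**est.get_params()).negation is True
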