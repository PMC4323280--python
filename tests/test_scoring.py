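"""Risk-indicator derivation, sum score and referral flag."""

import dataclasses
from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kindex.scoring import (
    INDICATOR_NAMES,
    RISK_AREAS,
    ScoringConfig,
    derive_indicators,
    flag_referral,
    housing_index,
    interviews_to_frame,
    pss4_stress_risk,
    risk_profile,
    score_cohort,
    sum_score,
)

from conftest import make_interview, make_maximal_interview


class TestHousingIndex:
    @pytest.mark.parametrize("rooms,persons,ratio,risk", [
        (1, 2, Fraction(1, 2), True),   # exactly 0.5 counts as risk
        (3, 2, Fraction(3, 2), False),
        (2, 5, Fraction(2, 5), True),
    ])
    def test_ratio_and_rule(self, rooms, persons, ratio, risk):
        idx = housing_index(rooms, persons)
        assert idx == ratio
        iv = make_interview(rooms=rooms, persons=persons)
        vec = derive_indicators(iv)
        assert vec.values["crowded_housing"] is risk

    @pytest.mark.parametrize("rooms,persons", [(0, 2), (2, 0), (-1, 3)])
    def test_nonpositive_counts_rejected(self, rooms, persons):
        with pytest.raises(ValueError):
            housing_index(rooms, persons)

    def test_strict_comparator_excludes_boundary(self):
        cfg = ScoringConfig(housing_comparator="lt")
        iv = make_interview(rooms=1, persons=2)
        assert derive_indicators(iv, cfg).values["crowded_housing"] is False
        iv = make_interview(rooms=2, persons=5)
        assert derive_indicators(iv, cfg).values["crowded_housing"] is True


class TestPss4:
    @pytest.mark.parametrize("items,total,risk", [
        ((4, 4, 4, 4), 16, True),
        ((0, 0, 0, 0), 0, False),
        ((3, 3, 3, 2), 11, False),   # just below the cutoff
        ((3, 3, 3, 3), 12, True),    # exactly at the cutoff
    ])
    def test_sum_and_flag(self, items, total, risk):
        assert pss4_stress_risk(items) == (total, risk)

    def test_missing_item_propagates(self):
        assert pss4_stress_risk((1, None, 2, 3)) == (None, None)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pss4_stress_risk((5, 0, 0, 0))


class TestDeriveIndicators:
    def test_fully_benign_respondent_scores_zero(self, benign_interview):
        vec = derive_indicators(benign_interview)
        assert vec.complete
        assert sum_score(vec) == 0
        assert all(v is False for v in vec.values.values())

    def test_age_only_risk(self):
        vec = derive_indicators(make_interview(age_years=20))
        assert vec.values["age_21_or_younger"] is True
        assert sum_score(vec) == 1

    def test_maximal_archetype_hits_31(self, maximal_interview):
        vec = derive_indicators(maximal_interview)
        assert all(v is True for v in vec.values.values())
        assert sum_score(vec) == 31

    def test_area_structure(self):
        counts = tuple(len(v) for v in RISK_AREAS.values())
        assert counts == (1, 2, 1, 2, 3, 5, 1, 2, 4, 6, 4)
        assert len(INDICATOR_NAMES) == 31
        assert len(RISK_AREAS) == 11

    @pytest.mark.parametrize("field,value,indicator,expected", [
        ("age_years", 21, "age_21_or_younger", True),
        ("age_years", 22, "age_21_or_younger", False),
        ("joy_mother", 3, "low_joy_mother", True),
        ("joy_mother", 4, "low_joy_mother", False),
        ("worries_mother", 7, "high_worries_mother", True),
        ("worries_mother", 6, "high_worries_mother", False),
        ("joy_father", 3, "low_joy_father", True),
        ("joy_father", 4, "low_joy_father", False),
        ("worries_father", 7, "high_worries_father", True),
        ("worries_father", 6, "high_worries_father", False),
    ])
    def test_threshold_boundaries(self, field, value, indicator, expected):
        vec = derive_indicators(make_interview(**{field: value}))
        assert vec.values[indicator] is expected

    def test_pss4_boundary_through_interview(self):
        # raw answers: reverse-coded items q2,q3 at 0 contribute 4 each
        at = make_interview(pss4_items=(4, 0, 0, 0))     # recoded sum 12
        below = make_interview(pss4_items=(3, 0, 0, 0))  # recoded sum 11
        assert derive_indicators(at).values["high_perceived_stress"] is True
        assert derive_indicators(below).values["high_perceived_stress"] is False

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError, match="joy_mother"):
            make_interview(joy_mother=11)

    def test_missing_answer_gives_missing_indicator_and_sum(self):
        iv = make_interview(smoke_mother=None)
        vec = derive_indicators(iv)
        assert vec.values["smoking_mother"] is None
        assert not vec.complete
        assert sum_score(vec) is None
        assert any("smoking_mother" in d for d in vec.diagnostics)
        # per-area partial counts are still reported
        prof = risk_profile(iv)
        assert prof.area_counts["substance"] == 0
        assert prof.sum_score is None and prof.referral_flag is None

    def test_gestational_week_outside_window_warns_not_errors(self):
        with pytest.warns(UserWarning, match="gestational week"):
            make_interview(gestational_week=20)


class TestSumScoreAndReferral:
    def test_bonding_area_alone_counts_five(self):
        iv = make_interview(pregnancy_planned=False, joy_mother=0,
                            worries_mother=10, joy_father=1, worries_father=9)
        prof = risk_profile(iv)
        assert prof.area_counts["bonding"] == 5
        assert prof.sum_score == 5

    @pytest.mark.parametrize("score,expected", [(0, False), (1, False),
                                                (2, True), (14, True)])
    def test_referral_threshold(self, score, expected):
        assert flag_referral(score) is expected

    def test_referral_threshold_configurable(self):
        assert flag_referral(2, threshold=3) is False
        assert flag_referral(3, threshold=3) is True


def _random_interview(draw):
    return make_interview(
        respondent_id=f"r{draw(st.integers(0, 10 ** 6))}",
        age_years=draw(st.integers(18, 45)),
        mother_foreign_born=draw(st.booleans()),
        father_foreign_born=draw(st.booleans()),
        cohabiting_with_father=draw(st.booleans()),
        financial_worry=draw(st.booleans()),
        rooms=draw(st.integers(1, 5)),
        persons=draw(st.integers(1, 7)),
        pregnancy_planned=draw(st.booleans()),
        joy_mother=draw(st.integers(0, 10)),
        worries_mother=draw(st.integers(0, 10)),
        joy_father=draw(st.integers(0, 10)),
        worries_father=draw(st.integers(0, 10)),
        pss4_items=tuple(draw(st.integers(0, 4)) for _ in range(4)),
        physical_symptoms=draw(st.booleans()),
        complications=draw(st.booleans()),
        medical_risk=draw(st.booleans()),
        childhood_physical_abuse=draw(st.booleans()),
        childhood_sexual_abuse=draw(st.booleans()),
        ipv_increase_8w=draw(st.booleans()),
        ipv_vociferous_8w=draw(st.booleans()),
        ipv_physical_8w=draw(st.booleans()),
        ipv_ever=draw(st.booleans()),
        smoke_mother=draw(st.booleans()),
        alcohol_mother=draw(st.booleans()),
        drugs_mother=draw(st.booleans()),
        smoke_father=draw(st.booleans()),
        alcohol_father=draw(st.booleans()),
        drugs_father=draw(st.booleans()),
        psych_diagnosis_ever=draw(st.booleans()),
        psych_inpatient_ever=draw(st.booleans()),
        psychotropic_ever=draw(st.booleans()),
        sought_help_ever=draw(st.booleans()),
    )


def _oracle_sum(iv) -> int:
    """Independent brute-force re-derivation of every recoding rule."""
    risks = [
        iv.age_years <= 21,
        iv.mother_foreign_born, iv.father_foreign_born,
        not iv.cohabiting_with_father,
        iv.financial_worry, iv.rooms / iv.persons <= 0.5,
        iv.physical_symptoms, iv.complications, iv.medical_risk,
        not iv.pregnancy_planned,
        iv.joy_mother <= 3, iv.worries_mother >= 7,
        iv.joy_father <= 3, iv.worries_father >= 7,
        (iv.pss4_items[0] + (4 - iv.pss4_items[1])
         + (4 - iv.pss4_items[2]) + iv.pss4_items[3]) >= 12,
        iv.childhood_physical_abuse, iv.childhood_sexual_abuse,
        iv.ipv_increase_8w, iv.ipv_vociferous_8w, iv.ipv_physical_8w,
        iv.ipv_ever,
        iv.smoke_mother, iv.alcohol_mother, iv.drugs_mother,
        iv.smoke_father, iv.alcohol_father, iv.drugs_father,
        iv.psych_diagnosis_ever, iv.psych_inpatient_ever,
        iv.psychotropic_ever, iv.sought_help_ever,
    ]
    assert len(risks) == 31
    return sum(bool(r) for r in risks)


class TestOracleEquivalence:
    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_sum_matches_independent_rule_application(self, data):
        iv = _random_interview(data.draw)
        assert sum_score(derive_indicators(iv)) == _oracle_sum(iv)

    @given(st.data())
    @settings(derandomize=True, max_examples=30)
    def test_vectorized_cohort_path_matches_record_path(self, data):
        ivs = [_random_interview(data.draw) for _ in range(5)]
        for i, iv in enumerate(ivs):
            ivs[i] = dataclasses.replace(iv, respondent_id=f"r{i}")
        frame = score_cohort(interviews_to_frame(ivs))
        for iv in ivs:
            prof = risk_profile(iv)
            assert frame.loc[iv.respondent_id, "sum_score"] == prof.sum_score
            for name, v in prof.indicators.values.items():
                assert bool(frame.loc[iv.respondent_id, name]) == v

    @given(st.data())
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_raw_risk_conditions(self, data):
        """Adding any single raw risk condition never decreases the score."""
        iv = _random_interview(data.draw)
        base = sum_score(derive_indicators(iv))
        riskier = {
            "age_years": 19, "mother_foreign_born": True,
            "cohabiting_with_father": False, "financial_worry": True,
            "persons": 7, "pregnancy_planned": False, "joy_mother": 0,
            "worries_father": 10, "pss4_items": (4, 0, 0, 4),
            "childhood_physical_abuse": True, "ipv_ever": True,
            "drugs_mother": True, "psych_diagnosis_ever": True,
        }
        field, value = data.draw(st.sampled_from(sorted(riskier.items())))
        bumped = sum_score(derive_indicators(
            dataclasses.replace(iv, **{field: value})
        ))
        assert bumped >= base


class TestCohortFrame:
    def test_profile_table_shape_and_referral(self):
        ivs = [make_interview(respondent_id="a"),
               make_maximal_interview(respondent_id="b")]
        frame = score_cohort(ivs)
        assert list(frame.index) == ["a", "b"]
        assert frame.loc["a", "sum_score"] == 0
        assert frame.loc["b", "sum_score"] == 31
        assert not frame.loc["a", "referral_flag"]
        assert frame.loc["b", "referral_flag"]
        area_cols = [f"n_risks_{a}" for a in RISK_AREAS]
        assert frame.loc["b", area_cols].sum() == 31

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score_cohort(pd.DataFrame(columns=["age_years"]))
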