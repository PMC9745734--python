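"""Scoring rules: worked examples, threshold boundaries, invariants."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from _helpers import make_vitals
from triageaudit.screening_rules import (
    MissingPolicy,
    RuleThresholds,
    ScreenResult,
    combined_alert,
    mts_possible_sepsis_rule,
    news2_score,
    qsofa_score,
    sirs_alert,
    sirs_count,
)


class TestQsofa:
    def test_rr_boundary_is_inclusive(self):
        result = qsofa_score(make_vitals(resp_rate=22.0, sbp=120.0, gcs=15))
        assert result.value == 1
        assert result.criteria_met == {"resp_rate"}

    def test_all_criteria_met(self):
        assert qsofa_score(make_vitals(resp_rate=24.0, sbp=95.0, gcs=14)).value == 3

    def test_strict_policy_flags_missing_sbp(self):
        result = qsofa_score(
            make_vitals(resp_rate=18.0, sbp=None, gcs=15), MissingPolicy.STRICT
        )
        assert result.indeterminate
        assert result.missing_inputs == {"sbp"}
        assert result.value == 0

    def test_missing_normal_policy_never_indeterminate(self):
        result = qsofa_score(make_vitals(sbp=None, gcs=None,
                                         altered_mental_checkbox=None))
        assert not result.indeterminate
        assert result.value == 0

    def test_checkbox_fallback_only_when_gcs_absent(self):
        with_gcs = make_vitals(gcs=15, altered_mental_checkbox=True)
        assert "mental_status" not in qsofa_score(with_gcs).criteria_met
        without_gcs = make_vitals(gcs=None, altered_mental_checkbox=True)
        assert "mental_status" in qsofa_score(without_gcs).criteria_met


class TestSirs:
    def test_boundaries_are_strict(self):
        assert sirs_count(make_vitals(temp_c=38.0, heart_rate=90.0,
                                      resp_rate=20.0)).value == 0

    def test_all_strictly_past_thresholds(self):
        assert sirs_count(make_vitals(temp_c=35.9, heart_rate=91.0,
                                      resp_rate=21.0)).value == 3

    def test_missing_vital_listed_not_counted(self):
        result = sirs_count(make_vitals(temp_c=None, heart_rate=120.0,
                                        resp_rate=10.0))
        assert result.value == 1
        assert result.missing_inputs == {"temp_c"}


class TestNews2:
    def test_all_bands_normal(self):
        assert news2_score(make_vitals(resp_rate=12, spo2=96, supplemental_o2=False,
                                       temp_c=37.0, sbp=120, heart_rate=70,
                                       avpu="A")).value == 0

    def test_maximal_bands_sum_to_twenty(self):
        v = make_vitals(resp_rate=25, spo2=91, supplemental_o2=True, temp_c=35.0,
                        sbp=90, heart_rate=131, avpu="V")
        assert news2_score(v).value == 3 + 3 + 2 + 3 + 3 + 3 + 3

    def test_single_heart_rate_band(self):
        assert news2_score(make_vitals(heart_rate=91)).value == 1

    def test_missing_components_score_zero_and_are_listed(self):
        result = news2_score(make_vitals(spo2=None, temp_c=None))
        assert result.value == 0
        assert {"spo2", "temp_c"} <= result.missing_inputs


class TestMtsRule:
    def test_one_criterion_suffices(self):
        assert mts_possible_sepsis_rule(make_vitals(resp_rate=30.0)).value is True

    def test_all_normal_negative(self):
        assert mts_possible_sepsis_rule(make_vitals()).value is False

    def test_indeterminate_propagates_under_strict(self):
        v = make_vitals(resp_rate=18.0, sbp=None)
        result = mts_possible_sepsis_rule(v, MissingPolicy.STRICT)
        assert result.indeterminate

    def test_definite_positive_overrides_missing(self):
        v = make_vitals(resp_rate=30.0, sbp=None)
        result = mts_possible_sepsis_rule(v, MissingPolicy.STRICT)
        assert result.value is True and not result.indeterminate


class TestAlerts:
    def test_no_suspicion_never_fires(self):
        sirs = sirs_count(make_vitals(temp_c=39.0, heart_rate=120, resp_rate=28))
        assert sirs.value == 3
        assert sirs_alert(False, True, sirs) is False

    def test_altered_mental_arm(self):
        sirs = sirs_count(make_vitals())
        assert sirs.value == 0
        assert sirs_alert(True, True, sirs) is True

    def test_single_sirs_criterion_insufficient(self):
        sirs = sirs_count(make_vitals(heart_rate=110))
        assert sirs.value == 1
        assert sirs_alert(True, False, sirs) is False

    @pytest.mark.parametrize(
        "mts,sirs,expected",
        [(True, False, True), (False, False, False), (False, True, True),
         (True, True, True)],
    )
    def test_combined_is_union(self, mts, sirs, expected):
        assert combined_alert(mts, sirs) is expected


BOUNDARY_CASES = [
    # (vitals override below threshold, override at/over threshold, rule, criterion)
    ({"resp_rate": 21.0}, {"resp_rate": 22.0}, qsofa_score, "resp_rate"),
    ({"sbp": 100.0}, {"sbp": 99.0}, qsofa_score, "sbp"),
    ({"gcs": 15}, {"gcs": 14}, qsofa_score, "mental_status"),
    ({"temp_c": 36.0}, {"temp_c": 35.9}, sirs_count, "temperature"),
    ({"temp_c": 38.0}, {"temp_c": 38.1}, sirs_count, "temperature"),
    ({"heart_rate": 90.0}, {"heart_rate": 91.0}, sirs_count, "heart_rate"),
    ({"resp_rate": 20.0}, {"resp_rate": 21.0}, sirs_count, "resp_rate"),
]


@pytest.mark.parametrize("below,above,rule,criterion", BOUNDARY_CASES)
def test_each_boundary_flips_exactly_its_criterion(below, above, rule, criterion):
    negative = rule(make_vitals(**below))
    positive = rule(make_vitals(**above))
    assert criterion not in negative.criteria_met
    assert criterion in positive.criteria_met
    assert positive.criteria_met - negative.criteria_met == {criterion}


vitals_strategy = st.builds(
    make_vitals,
    resp_rate=st.one_of(st.none(), st.floats(5, 50)),
    sbp=st.one_of(st.none(), st.floats(50, 220)),
    gcs=st.one_of(st.none(), st.integers(3, 15)),
    temp_c=st.one_of(st.none(), st.floats(33, 42)),
    heart_rate=st.one_of(st.none(), st.floats(30, 180)),
    spo2=st.one_of(st.none(), st.floats(70, 100)),
)


@given(vitals_strategy, st.floats(0.5, 15))
def test_worsening_a_vital_never_lowers_scores(v, delta):
    """Raising RR/HR or dropping SBP/GCS is monotone for every scorer."""
    from dataclasses import replace

    if v.resp_rate is not None:
        worse = replace(v, resp_rate=v.resp_rate + delta)
        assert qsofa_score(worse).value >= qsofa_score(v).value
        assert sirs_count(worse).value >= sirs_count(v).value
        if v.resp_rate >= 12:  # NEWS2 bands are U-shaped; up is worse from normal
            assert news2_score(worse).value >= news2_score(v).value
    if v.sbp is not None:
        worse = replace(v, sbp=max(0.0, v.sbp - delta))
        assert qsofa_score(worse).value >= qsofa_score(v).value
        if v.sbp <= 219:  # below the hypertensive NEWS2 band, lower is worse
            assert news2_score(worse).value >= news2_score(v).value
    if v.gcs is not None and v.gcs > 3:
        worse = replace(v, gcs=v.gcs - 1)
        assert qsofa_score(worse).value >= qsofa_score(v).value


@given(vitals_strategy)
def test_scorers_are_pure(v):
    for rule in (qsofa_score, sirs_count, news2_score):
        assert rule(v) == rule(v)


def test_screen_result_requires_missing_inputs_when_indeterminate():
    with pytest.raises(ValueError):
        ScreenResult(value=0, criteria_met=frozenset(), indeterminate=True)


def test_threshold_validation():
    with pytest.raises(ValueError):
        RuleThresholds(sirs_temp_low_exclusive=39.0)
    with pytest.raises(ValueError):
        RuleThresholds(qsofa_rr_min=0)
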