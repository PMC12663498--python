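"""Risk-engine rules: derivations, points, flags, categories, and the
rule-set invariants (monotonicity, exhaustiveness, structural zeros)."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioscore.cohort_model import PredictorProfile, RiskCategory
from cardioscore.scoring import (
    DEFAULT_CONFIG,
    HIGH_AGE80,
    HIGH_CAD,
    MissingPredictorError,
    ScoringConfig,
    categorize,
    collect_risk_flags,
    derive_predictors,
    score_medium_points,
    score_subject,
    stratify_cohort,
)


def clean_profile(**overrides) -> PredictorProfile:
    base = dict(
        subject_id="T", age=50.0, sex="female", systolic_bp=120.0,
        diastolic_bp=75.0, antihypertensive_use=False, diabetes=False,
        coronary_artery_disease=False, cerebrovascular_disease=False,
        peripheral_artery_disease=False, heart_failure=False,
        valvular_disease=False, arrhythmia=False, egfr=90.0,
        ckd_diagnosis=False, current_smoker=False, bmi=24.0,
        total_cholesterol=4.5, hdl_cholesterol=1.5,
        prior_anthracycline=False, prior_nonanthracycline_chemo=False,
        prior_chest_rt=False)
    base.update(overrides)
    return PredictorProfile(**base)


class TestDerivedPredictors:
    @pytest.mark.parametrize("overrides, field, expected", [
        ({"systolic_bp": 150.0}, "hypertension", True),
        ({"systolic_bp": 140.0, "diastolic_bp": 90.0}, "hypertension", False),
        ({"diastolic_bp": 95.0}, "hypertension", True),
        ({"antihypertensive_use": True}, "hypertension", True),
        ({"total_cholesterol": 5.6, "hdl_cholesterol": 1.3}, "hyperlipidemia", True),
        ({"total_cholesterol": 5.0, "hdl_cholesterol": 1.3}, "hyperlipidemia", False),
        ({"egfr": 55.0}, "ckd", True),
        ({"egfr": 60.0}, "ckd", False),
        ({"ckd_diagnosis": True}, "ckd", True),
        ({"bmi": 30.0}, "obesity", False),  # strict inequality at boundary
        ({"bmi": 30.1}, "obesity", True),
    ])
    def test_derivation_rules(self, overrides, field, expected):
        derived = derive_predictors(clean_profile(**overrides))
        assert getattr(derived, field) is expected

    def test_non_hdl_is_total_minus_hdl(self):
        derived = derive_predictors(
            clean_profile(total_cholesterol=5.6, hdl_cholesterol=1.3))
        assert derived.non_hdl == pytest.approx(4.3)

    def test_systolic_only_rule_ignores_diastolic(self):
        cfg = ScoringConfig(hypertension_rule="systolic_only")
        profile = clean_profile(diastolic_bp=95.0)
        assert derive_predictors(profile, cfg).hypertension is False
        assert derive_predictors(profile).hypertension is True

    def test_strict_mode_names_subject_and_field(self):
        with pytest.raises(MissingPredictorError, match="T.*bmi"):
            derive_predictors(clean_profile(bmi=None))


class TestMediumPoints:
    @pytest.mark.parametrize("overrides, expected", [
        ({}, 0),
        ({"age": 70.0, "antihypertensive_use": True, "diabetes": True}, 4),
        ({"antihypertensive_use": True, "diabetes": True, "egfr": 50.0,
          "current_smoker": True, "bmi": 31.0}, 5),
        ({"age": 85.0}, 0),  # age >= 80 is a high factor, no medium points
        ({"arrhythmia": True}, 2),
        ({"age": 67.0}, 2),
        ({"prior_chest_rt": True, "prior_nonanthracycline_chemo": True}, 2),
    ])
    def test_point_sums(self, overrides, expected):
        profile = clean_profile(**overrides)
        derived = derive_predictors(profile)
        assert score_medium_points(derived, profile) == expected


class TestRiskFlags:
    def test_coronary_artery_disease_is_high(self):
        high, very_high = collect_risk_flags(
            clean_profile(coronary_artery_disease=True))
        assert HIGH_CAD in high and not very_high

    def test_heart_failure_is_very_high(self):
        _, very_high = collect_risk_flags(clean_profile(heart_failure=True))
        assert very_high

    def test_age_80_plus_is_the_only_flag_on_an_otherwise_clean_profile(self):
        high, very_high = collect_risk_flags(clean_profile(age=81.0))
        assert high == frozenset({HIGH_AGE80}) and not very_high

    def test_valvular_toggle(self):
        profile = clean_profile(valvular_disease=True)
        assert collect_risk_flags(profile)[0]
        off = ScoringConfig(valvular_is_high=False)
        assert not collect_risk_flags(profile, off)[0]


class TestCategorize:
    @pytest.mark.parametrize("points, high, very_high, expected", [
        (0, set(), set(), RiskCategory.LOW),
        (1, set(), set(), RiskCategory.LOW),
        (2, set(), set(), RiskCategory.MODERATE),
        (4, set(), set(), RiskCategory.MODERATE),
        (5, set(), set(), RiskCategory.HIGH),
        (2, {"pad"}, set(), RiskCategory.HIGH),
        (0, {"pad"}, {"hf"}, RiskCategory.VERY_HIGH),
    ])
    def test_category_rules(self, points, high, very_high, expected):
        assert categorize(points, high, very_high) is expected

    def test_negative_points_rejected(self):
        with pytest.raises(ValueError):
            categorize(-1, set(), set())


class TestStratifyCohort:
    def test_all_heart_failure_cohort_is_all_very_high(self):
        profiles = [dataclasses.replace(clean_profile(heart_failure=True),
                                        subject_id=f"S{i}") for i in range(10)]
        _, table = stratify_cohort(profiles)
        assert table.set_index("category").loc["very_high", "n"] == 10

    def test_empty_cohort(self):
        assessments, table = stratify_cohort([])
        assert assessments == [] and table["n"].sum() == 0

    def test_crafted_low_moderate_high(self):
        profiles = [
            clean_profile(),  # no factors
            dataclasses.replace(
                clean_profile(antihypertensive_use=True, diabetes=True,
                              current_smoker=True), subject_id="T2"),
            dataclasses.replace(clean_profile(coronary_artery_disease=True),
                                subject_id="T3"),
        ]
        assessments, _ = stratify_cohort(profiles)
        assert [a.category for a in assessments] == [
            RiskCategory.LOW, RiskCategory.MODERATE, RiskCategory.HIGH]
        assert sum(a.medium_points for a in assessments) == 0 + 3 + 0


# ---------------------------------------------------------------------------
# Property tests over fuzzed profiles
# ---------------------------------------------------------------------------

profile_strategy = st.builds(
    clean_profile,
    age=st.floats(20, 99),
    systolic_bp=st.floats(80, 220),
    diastolic_bp=st.floats(40, 130),
    antihypertensive_use=st.booleans(),
    diabetes=st.booleans(),
    coronary_artery_disease=st.booleans(),
    cerebrovascular_disease=st.booleans(),
    peripheral_artery_disease=st.booleans(),
    heart_failure=st.booleans(),
    valvular_disease=st.booleans(),
    arrhythmia=st.booleans(),
    egfr=st.floats(10, 120),
    ckd_diagnosis=st.booleans(),
    current_smoker=st.booleans(),
    bmi=st.floats(15, 45),
    total_cholesterol=st.floats(2.5, 9.0),
    hdl_cholesterol=st.floats(0.5, 2.4),
    prior_anthracycline=st.booleans(),
    prior_nonanthracycline_chemo=st.booleans(),
    prior_chest_rt=st.booleans(),
)

_MEDIUM_SETTERS = [
    ("diabetes", True), ("current_smoker", True), ("arrhythmia", True),
    ("antihypertensive_use", True), ("bmi", 35.0), ("egfr", 40.0),
    ("prior_chest_rt", True), ("prior_nonanthracycline_chemo", True),
]


@settings(max_examples=200, derandomize=True)
@given(profile=profile_strategy)
def test_every_complete_profile_maps_to_exactly_one_category(profile):
    assessment = score_subject(profile)
    assert assessment.category in RiskCategory
    # the invariant linking flags/points to the category
    if assessment.very_high_factors:
        assert assessment.category is RiskCategory.VERY_HIGH
    elif assessment.high_factors or assessment.medium_points >= 5:
        assert assessment.category is RiskCategory.HIGH
    elif assessment.medium_points >= 2:
        assert assessment.category is RiskCategory.MODERATE
    else:
        assert assessment.category is RiskCategory.LOW


@settings(max_examples=200, derandomize=True)
@given(profile=profile_strategy, which=st.integers(0, len(_MEDIUM_SETTERS) - 1))
def test_adding_a_medium_factor_never_lowers_the_category(profile, which):
    before = score_subject(profile).category
    name, value = _MEDIUM_SETTERS[which]
    after = score_subject(dataclasses.replace(profile, **{name: value})).category
    assert after >= before


@settings(max_examples=200, derandomize=True)
@given(profile=profile_strategy)
def test_high_and_very_high_factors_dominate(profile):
    with_cad = dataclasses.replace(profile, coronary_artery_disease=True)
    assert score_subject(with_cad).category >= RiskCategory.HIGH
    with_hf = dataclasses.replace(profile, heart_failure=True)
    assert score_subject(with_hf).category is RiskCategory.VERY_HIGH


@settings(max_examples=300, derandomize=True)
@given(profile=profile_strategy)
def test_structural_zeros_below_high(profile):
    """CAD, cerebrovascular, PAD and valvular disease never appear in LOW or
    MODERATE; arrhythmia never appears in LOW."""
    category = score_subject(profile).category
    if category < RiskCategory.HIGH:
        assert not profile.coronary_artery_disease
        assert not profile.cerebrovascular_disease
        assert not profile.peripheral_artery_disease
        assert not profile.valvular_disease
    if category is RiskCategory.LOW:
        assert not profile.arrhythmia
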