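"""The modified HFA-ICOS risk engine.

The harmonised proforma assigns, from baseline clinical predictors only:

* **medium-level points** — 2 points for age 65-79 years and for arrhythmia
  (AF/flutter/VT); 1 point each for hypertension, diabetes, hyperlipidemia
  (non-HDL cholesterol > 3.8 mmol/L), chronic kidney disease, current
  smoking, obesity (BMI > 30 kg/m^2), prior chest/mediastinal radiotherapy,
  and prior non-anthracycline chemotherapy;
* **high-risk factors** — arterial vascular disease (PAD/TIA/stroke),
  coronary artery disease (MI/revascularisation/stable angina), prior
  anthracycline exposure, age >= 80 years, and (by default) valvular disease;
* **very-high-risk factor** — heart failure or cardiomyopathy.

Categories: LOW (no flags, <= 1 point), MODERATE (2-4 points), HIGH (any
high factor or >= 5 points), VERY_HIGH (any very-high factor), with
precedence VERY_HIGH > HIGH > MODERATE > LOW.

Derived predictor definitions: hypertension = antihypertensive use or blood
pressure > 140/90 mmHg (disjunctive over the two components by default);
CKD = eGFR < 60 mL/min/1.73 m^2 or a CKD diagnosis.  All threshold
inequalities are strict.  Valvular disease is not a row of the published
harmonised table, but the published category-stratified prevalences show
exactly 0% valvular disease below HIGH, which is only possible if it forces
>= HIGH; it is therefore a high factor by default and toggleable in
:class:`ScoringConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal, Sequence

import pandas as pd

from .cohort_model import PredictorProfile, RiskCategory


class AgeBand(str, Enum):
    UNDER65 = "under65"
    FROM65TO79 = "65to79"
    OVER80 = "80plus"


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds and rule toggles for the risk engine.

    All inequalities are strict.  ``hypertension_rule`` selects whether BP
    exceedance is systolic-or-diastolic (default) or systolic-only; the
    published definition ("blood pressure >140/90 mm Hg") does not resolve it.
    """

    sbp_threshold: float = 140.0
    dbp_threshold: float = 90.0
    non_hdl_threshold: float = 3.8  # mmol/L
    bmi_threshold: float = 30.0
    egfr_threshold: float = 60.0
    hypertension_rule: Literal["either", "systolic_only"] = "either"
    valvular_is_high: bool = True
    strict: bool = True  # error on missing fields; False = treat missing as absent/False


DEFAULT_CONFIG = ScoringConfig()

#: Fields the engine reads; used for strict-mode completeness checks.
SCORING_FIELDS = (
    "age", "systolic_bp", "diastolic_bp", "antihypertensive_use", "diabetes",
    "coronary_artery_disease", "cerebrovascular_disease",
    "peripheral_artery_disease", "heart_failure", "valvular_disease",
    "arrhythmia", "egfr", "ckd_diagnosis", "current_smoker", "bmi",
    "total_cholesterol", "hdl_cholesterol", "prior_anthracycline",
    "prior_nonanthracycline_chemo", "prior_chest_rt",
)

# Canonical factor names.
HIGH_ARTERIAL = "arterial_vascular_disease"
HIGH_CAD = "coronary_artery_disease"
HIGH_ANTHRACYCLINE = "prior_anthracycline"
HIGH_AGE80 = "age80plus"
HIGH_VALVULAR = "valvular_disease"
VERY_HIGH_HF = "heart_failure"

MEDIUM_FACTORS_2P = ("age65to79", "arrhythmia")
MEDIUM_FACTORS_1P = (
    "hypertension", "diabetes", "hyperlipidemia", "ckd", "current_smoker",
    "obesity", "prior_chest_rt", "prior_nonanthracycline_chemo",
)


@dataclass
class DerivedPredictors:
    """Composite predictors derived from a complete profile."""

    hypertension: bool
    hyperlipidemia: bool
    ckd: bool
    obesity: bool
    age_band: AgeBand
    non_hdl: float | None  # mmol/L


@dataclass
class RiskAssessment:
    """Points, fired factors and the final four-level category for one subject."""

    subject_id: str
    medium_points: int
    high_factors: frozenset[str]
    very_high_factors: frozenset[str]
    category: RiskCategory


class MissingPredictorError(ValueError):
    """A required predictor is missing in strict mode."""

    def __init__(self, subject_id: str, field_name: str):
        self.subject_id, self.field_name = subject_id, field_name
        super().__init__(f"subject {subject_id}: missing predictor {field_name!r}")


def _get(profile: PredictorProfile, name: str, config: ScoringConfig):
    v = getattr(profile, name)
    if v is None and config.strict:
        raise MissingPredictorError(profile.subject_id, name)
    return v


def _flag(profile: PredictorProfile, name: str, config: ScoringConfig) -> bool:
    return bool(_get(profile, name, config))


def derive_predictors(
    profile: PredictorProfile, config: ScoringConfig = DEFAULT_CONFIG
) -> DerivedPredictors:
    """Derive hypertension, hyperlipidemia, CKD, obesity and the age band.

    Deterministic; strict mode raises :class:`MissingPredictorError` naming
    the subject and field when a needed value is missing (missingness is
    meant to be resolved upstream by imputation).  In non-strict mode a
    missing input simply cannot fire its factor.
    """
    age = _get(profile, "age", config)
    if age is None:
        band = AgeBand.UNDER65  # non-strict fallback; age is mandatory on read
    elif age >= 80:
        band = AgeBand.OVER80
    elif age >= 65:
        band = AgeBand.FROM65TO79
    else:
        band = AgeBand.UNDER65

    sbp = _get(profile, "systolic_bp", config)
    dbp = _get(profile, "diastolic_bp", config)
    bp_high = sbp is not None and sbp > config.sbp_threshold
    if config.hypertension_rule == "either":
        bp_high = bp_high or (dbp is not None and dbp > config.dbp_threshold)
    hypertension = _flag(profile, "antihypertensive_use", config) or bp_high

    total = _get(profile, "total_cholesterol", config)
    hdl = _get(profile, "hdl_cholesterol", config)
    non_hdl = total - hdl if (total is not None and hdl is not None) else None
    hyperlipidemia = non_hdl is not None and non_hdl > config.non_hdl_threshold

    egfr = _get(profile, "egfr", config)
    ckd = (egfr is not None and egfr < config.egfr_threshold) or _flag(
        profile, "ckd_diagnosis", config)

    bmi = _get(profile, "bmi", config)
    obesity = bmi is not None and bmi > config.bmi_threshold

    return DerivedPredictors(hypertension, hyperlipidemia, ckd, obesity, band, non_hdl)


def score_medium_points(
    derived: DerivedPredictors, profile: PredictorProfile,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> int:
    """Sum the medium-level points (age >= 80 contributes none: it is a high factor)."""
    points = 0
    if derived.age_band is AgeBand.FROM65TO79:
        points += 2
    if _flag(profile, "arrhythmia", config):
        points += 2
    for flag in (derived.hypertension, _flag(profile, "diabetes", config),
                 derived.hyperlipidemia, derived.ckd,
                 _flag(profile, "current_smoker", config), derived.obesity,
                 _flag(profile, "prior_chest_rt", config),
                 _flag(profile, "prior_nonanthracycline_chemo", config)):
        if flag:
            points += 1
    return points


def collect_risk_flags(
    profile: PredictorProfile, config: ScoringConfig = DEFAULT_CONFIG
) -> tuple[frozenset[str], frozenset[str]]:
    """Return (high_factors, very_high_factors) fired by the profile."""
    high: set[str] = set()
    if (_flag(profile, "peripheral_artery_disease", config)
            or _flag(profile, "cerebrovascular_disease", config)):
        high.add(HIGH_ARTERIAL)
    if _flag(profile, "coronary_artery_disease", config):
        high.add(HIGH_CAD)
    if _flag(profile, "prior_anthracycline", config):
        high.add(HIGH_ANTHRACYCLINE)
    age = _get(profile, "age", config)
    if age is not None and age >= 80:
        high.add(HIGH_AGE80)
    if config.valvular_is_high and _flag(profile, "valvular_disease", config):
        high.add(HIGH_VALVULAR)

    very_high: set[str] = set()
    if _flag(profile, "heart_failure", config):
        very_high.add(VERY_HIGH_HF)
    return frozenset(high), frozenset(very_high)


def categorize(
    points: int, high_factors: Iterable[str], very_high_factors: Iterable[str]
) -> RiskCategory:
    """Map points and flags to the four-level category (VERY_HIGH > HIGH > ...)."""
    if points < 0:
        raise ValueError("points must be nonnegative")
    if set(very_high_factors):
        return RiskCategory.VERY_HIGH
    if set(high_factors) or points >= 5:
        return RiskCategory.HIGH
    if points >= 2:
        return RiskCategory.MODERATE
    return RiskCategory.LOW


def score_subject(
    profile: PredictorProfile, config: ScoringConfig = DEFAULT_CONFIG
) -> RiskAssessment:
    """Full assessment for one subject: derive, score, flag, categorise."""
    derived = derive_predictors(profile, config)
    points = score_medium_points(derived, profile, config)
    high, very_high = collect_risk_flags(profile, config)
    return RiskAssessment(profile.subject_id, points, high, very_high,
                          categorize(points, high, very_high))


def stratify_cohort(
    profiles: Sequence[PredictorProfile], config: ScoringConfig = DEFAULT_CONFIG
) -> tuple[list[RiskAssessment], pd.DataFrame]:
    """Assess every subject; returns assessments and a category count table.

    The table has one row per :class:`RiskCategory` (including empty ones)
    with columns ``n`` and ``proportion``; counts sum to ``len(profiles)``.
    """
    assessments = [score_subject(p, config) for p in profiles]
    n = len(assessments)
    counts = {cat: 0 for cat in RiskCategory}
    for a in assessments:
        counts[a.category] += 1
    table = pd.DataFrame({
        "category": [c.label for c in RiskCategory],
        "n": [counts[c] for c in RiskCategory],
        "proportion": [counts[c] / n if n else float("nan") for c in RiskCategory],
    })
    return assessments, table


def assessments_to_frame(assessments: Sequence[RiskAssessment]) -> pd.DataFrame:
    """Tabular view: subject_id, medium_points, factors fired, category."""
    return pd.DataFrame({
        "subject_id": [a.subject_id for a in assessments],
        "medium_points": [a.medium_points for a in assessments],
        "high_factors": [";".join(sorted(a.high_factors)) for a in assessments],
        "very_high_factors": [";".join(sorted(a.very_high_factors)) for a in assessments],
        "category": [a.category.label for a in assessments],
    })
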