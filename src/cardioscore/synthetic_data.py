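"""Synthetic cohort generator calibrated to published category margins.

Emulates an unselected cancer cohort (n ~ 2,290) stratified by the modified
HFA-ICOS tool: category mix 28/35/34/3%, category-conditional predictor
prevalences taken from the published baseline table, treatment-received
distributions, and per-category event rates calibrated so that the composite
CVD cumulative incidence at the pooled median follow-up (6.9 y) is
7/21/29/37% and all-cause mortality at 8.7 y is 32/55/79/89%.

Construction is category-first: draw the intended category from the mix,
draw predictors from that category's conditional prevalence table, then
*repair* the draw minimally so the scoring engine maps it back to the
intended category (e.g. force heart failure for VERY_HIGH, strip high
factors and cap points for LOW).  Every repaired field is counted so
prevalence distortion is measurable.

Event times: per category, a latent composite-CVD time ``T_cvd ~
Exp(lambda_cvd)`` and a latent death time ``T_death ~ Exp(lambda_death)``
are drawn independently.  The first of the two is the subject's first event;
CVD first events are fatal (CVD death) with the configured probability,
otherwise the subject's later death at ``T_death`` is also emitted.
Administrative censoring is Uniform(11, 17) years (diagnosis 2006-2012,
follow-up through 2023).  Under this model the composite-CVD cumulative
incidence is the competing-exponential CIF and all-cause mortality is
available in closed form, which is what the calibration inverts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .cohort_model import (
    CANCER_TYPES,
    CancerContext,
    DxPosition,
    EventRecord,
    EventType,
    PredictorProfile,
    RiskCategory,
)
from .scoring import DEFAULT_CONFIG, ScoringConfig, score_subject

# --------------------------------------------------------------------------
# Category-conditional defaults (LOW, MODERATE, HIGH, VERY_HIGH)
# --------------------------------------------------------------------------

_DEFAULT_PREVALENCE = {
    "age_mean": (52.6, 66.9, 74.4, 73.9),
    "age_sd": (9.2, 8.6, 8.9, 8.5),
    "male": (0.44, 0.52, 0.58, 0.65),
    "diabetes": (0.01, 0.06, 0.15, 0.24),
    "coronary_artery_disease": (0.0, 0.0, 0.43, 0.65),
    "cerebrovascular_disease": (0.0, 0.0, 0.24, 0.18),
    "peripheral_artery_disease": (0.0, 0.0, 0.17, 0.24),
    "heart_failure": (0.0, 0.0, 0.0, 1.0),
    "valvular_disease": (0.0, 0.0, 0.10, 0.25),
    "arrhythmia": (0.0, 0.05, 0.13, 0.57),
    "ckd": (0.0, 0.04, 0.23, 0.43),
    "current_smoker": (0.22, 0.29, 0.25, 0.18),
    "obesity": (0.09, 0.32, 0.30, 0.35),
    "sbp_mean": (127.0, 142.0, 141.0, 133.0),
    "sbp_sd": (16.0, 19.0, 20.0, 21.0),
    "antihypertensive_use": (0.08, 0.37, 0.62, 0.72),
    "total_cholesterol_mean": (5.6, 5.8, 5.4, 4.9),
    "total_cholesterol_sd": (1.0, 1.1, 1.2, 1.1),
    "hdl_mean": (1.4, 1.4, 1.3, 1.2),
    "hdl_sd": (0.3, 0.4, 0.3, 0.3),
    # prior exposures are not printed per category; small realistic defaults
    "prior_anthracycline": (0.0, 0.0, 0.05, 0.05),
    "prior_chest_rt": (0.01, 0.03, 0.03, 0.03),
    "prior_nonanthracycline_chemo": (0.02, 0.05, 0.05, 0.05),
    "metastatic": (0.13, 0.17, 0.24, 0.22),
    "received_anthracycline": (0.20, 0.12, 0.04, 0.04),
    "received_her2": (0.03, 0.01, 0.0, 0.01),
    "received_vegf_iv": (0.04, 0.02, 0.01, 0.0),
    "received_myeloma_tx": (0.01, 0.01, 0.02, 0.06),
    "received_cardiotoxic_rt": (0.10, 0.07, 0.06, 0.06),
}

#: cancer-type mix per category (normalised on use)
_DEFAULT_CANCER_MIX = (
    (16, 6, 13, 21, 8, 18, 7, 11),
    (22, 8, 11, 12, 6, 20, 8, 14),
    (28, 13, 12, 6, 4, 18, 8, 12),
    (38, 10, 12, 9, 4, 15, 10, 1),
)

#: predictors that must have zero prevalence below HIGH (structural zeros)
_HIGH_ONLY = ("coronary_artery_disease", "cerebrovascular_disease",
              "peripheral_artery_disease", "valvular_disease",
              "prior_anthracycline")


@dataclass
class SyntheticCohortConfig:
    """Study conditions for cohort generation; defaults emulate the published cohort."""

    n: int = 2290
    seed: int = 0
    category_mix: tuple[float, float, float, float] = (0.28, 0.35, 0.34, 0.03)
    #: composite-CVD cumulative incidence targets and their anchor (years)
    cvd_targets: tuple[float, float, float, float] = (0.07, 0.21, 0.29, 0.37)
    cvd_anchor_years: float = 6.9
    #: all-cause mortality targets and their anchor (years)
    mortality_targets: tuple[float, float, float, float] = (0.32, 0.55, 0.79, 0.89)
    mortality_anchor_years: float = 8.7
    #: first-event split of the composite: HF hosp, MI, stroke, CVD death
    cause_split: tuple[float, float, float, float] = (0.19, 0.35, 0.28, 0.18)
    censor_window: tuple[float, float] = (11.0, 17.0)
    #: MCAR missingness rate per predictor field name (empty = complete data)
    missingness: dict[str, float] = field(default_factory=dict)
    prevalence: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_PREVALENCE))
    cancer_mix: tuple = _DEFAULT_CANCER_MIX
    #: optional explicit per-category (lambda_cvd, lambda_death); None = calibrate
    hazards: tuple[tuple[float, float], ...] | None = None
    #: Weibull shape for event times (1 = exponential; >1 rising hazard)
    weibull_shape: float = 1.0

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        if abs(sum(self.cause_split) - 1.0) > 1e-9:
            raise ValueError("cause_split must sum to 1")
        lo, hi = self.censor_window
        if not (0 < lo <= hi):
            raise ValueError("censoring window must be positive with min <= max")
        for name in _HIGH_ONLY + ("heart_failure",):
            prev = self.prevalence[name]
            if prev[0] > 0 or prev[1] > 0:
                raise ValueError(
                    f"prevalence of {name!r} must be 0 in LOW and MODERATE "
                    "(it forces category >= HIGH)")
        if self.hazards is not None and any(
                l < 0 for pair in self.hazards for l in pair):
            raise ValueError("hazard rates must be nonnegative")


# --------------------------------------------------------------------------
# Hazard calibration
# --------------------------------------------------------------------------

def competing_cif(t: float, lam_k: float, lam_total: float) -> float:
    """CIF of one cause under competing exponentials:
    ``(lam_k / L)(1 - exp(-L t))``."""
    if lam_total == 0:
        return 0.0
    return lam_k / lam_total * (1.0 - math.exp(-lam_total * t))


def calibrate_exponential_hazards(
    target_cif_cvd: float, target_cif_death: float, horizon_years: float,
) -> tuple[float, float]:
    """Rates of two competing exponentials hitting both CIF targets at one horizon.

    Closed form: the cause fractions are ``lambda_k / Lambda = p_k / (p_1 +
    p_2)`` and ``Lambda = -ln(1 - p_1 - p_2) / t``.  Round-trip: plugging the
    returned rates into :func:`competing_cif` reproduces the targets.
    Infeasible targets (sum >= 1) raise.
    """
    p1, p2 = target_cif_cvd, target_cif_death
    if not (0 < p1 < 1) or p2 < 0 or p2 >= 1:
        raise ValueError("targets must lie in (0,1) (death target may be 0)")
    if p1 + p2 >= 1:
        raise ValueError("infeasible targets: CIFs must sum to < 1")
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    total = -math.log1p(-(p1 + p2)) / horizon_years
    return p1 / (p1 + p2) * total, p2 / (p1 + p2) * total


def all_cause_mortality(t: float, lam_cvd: float, lam_death: float,
                        cvd_death_share: float) -> float:
    """P(dead by t) under the parallel-death model: the latent death time is
    Exp(lam_death) regardless of CVD events, plus fatal CVD first events."""
    return (1.0 - math.exp(-lam_death * t)
            + cvd_death_share * (1.0 - math.exp(-lam_cvd * t))
            * math.exp(-lam_death * t))


def calibrate_hazards_all_cause(
    target_cif_cvd: float, cvd_anchor: float,
    target_mortality: float, mortality_anchor: float,
    cvd_death_share: float = 0.18,
) -> tuple[float, float]:
    """Solve (lambda_cvd, lambda_death) so the composite-CVD CIF hits its
    target at ``cvd_anchor`` and *all-cause* mortality hits its target at
    ``mortality_anchor``.

    Unlike :func:`calibrate_exponential_hazards`, the mortality target is not
    a competing-cause CIF — it counts deaths occurring after nonfatal CVD
    events too — so targets like (0.37, 0.89) are feasible.
    """
    if not (0 < target_cif_cvd < 1 and 0 < target_mortality < 1):
        raise ValueError("targets must lie in (0, 1)")

    def equations(log_lams):
        lc, ld = np.exp(log_lams)
        return [competing_cif(cvd_anchor, lc, lc + ld) - target_cif_cvd,
                all_cause_mortality(mortality_anchor, lc, ld, cvd_death_share)
                - target_mortality]

    x0 = np.log([max(-math.log1p(-target_cif_cvd) / cvd_anchor, 1e-6),
                 max(-math.log1p(-target_mortality) / mortality_anchor, 1e-6)])
    sol = optimize.root(equations, x0, tol=1e-12)
    lc, ld = np.exp(sol.x)
    resid = equations(np.log([lc, ld]))
    if not sol.success or max(abs(r) for r in resid) > 1e-10:
        raise ValueError(
            f"calibration failed for targets ({target_cif_cvd}, {target_mortality})")
    return float(lc), float(ld)


def default_category_hazards(config: SyntheticCohortConfig) -> list[tuple[float, float]]:
    """Per-category (lambda_cvd, lambda_death) from the config's targets."""
    if config.hazards is not None:
        return [tuple(pair) for pair in config.hazards]
    share = config.cause_split[3]  # CVD-death fraction of first events
    return [calibrate_hazards_all_cause(p_cvd, config.cvd_anchor_years,
                                        p_dead, config.mortality_anchor_years, share)
            for p_cvd, p_dead in zip(config.cvd_targets, config.mortality_targets)]


# --------------------------------------------------------------------------
# Subject drawing and minimal repair
# --------------------------------------------------------------------------

def _draw_profile(sid: str, k: int, cfg: SyntheticCohortConfig,
                  rng: np.random.Generator) -> PredictorProfile:
    P = cfg.prevalence

    def coin(name):
        return bool(rng.random() < P[name][k])

    age = float(np.clip(rng.normal(P["age_mean"][k], P["age_sd"][k]), 20.0, 99.0))
    sbp = float(max(rng.normal(P["sbp_mean"][k], P["sbp_sd"][k]), 80.0))
    dbp = float(max(rng.normal(0.55 * sbp + 5.0, 6.0), 40.0))
    obese = coin("obesity")
    bmi = float(rng.uniform(30.1, 40.0)) if obese else \
        float(np.clip(rng.normal(26.0, 2.5), 16.0, 29.9))
    tc = float(max(rng.normal(P["total_cholesterol_mean"][k],
                              P["total_cholesterol_sd"][k]), 2.0))
    hdl = float(np.clip(rng.normal(P["hdl_mean"][k], P["hdl_sd"][k]),
                        0.4, tc - 0.3))
    ckd = coin("ckd")
    egfr = float(rng.uniform(25.0, 59.0)) if ckd else float(rng.uniform(65.0, 110.0))
    return PredictorProfile(
        subject_id=sid,
        age=age,
        sex="male" if rng.random() < P["male"][k] else "female",
        systolic_bp=sbp, diastolic_bp=dbp,
        antihypertensive_use=coin("antihypertensive_use"),
        diabetes=coin("diabetes"),
        coronary_artery_disease=coin("coronary_artery_disease"),
        cerebrovascular_disease=coin("cerebrovascular_disease"),
        peripheral_artery_disease=coin("peripheral_artery_disease"),
        heart_failure=coin("heart_failure"),
        valvular_disease=coin("valvular_disease"),
        arrhythmia=coin("arrhythmia"),
        egfr=egfr, ckd_diagnosis=bool(ckd and rng.random() < 0.3),
        current_smoker=coin("current_smoker"),
        bmi=bmi, total_cholesterol=tc, hdl_cholesterol=hdl,
        prior_anthracycline=coin("prior_anthracycline"),
        prior_nonanthracycline_chemo=coin("prior_nonanthracycline_chemo"),
        prior_chest_rt=coin("prior_chest_rt"),
    )


# medium factors in the order they are sacrificed / added during repair
_MEDIUM_DROP_ORDER = ("arrhythmia", "prior_nonanthracycline_chemo",
                      "prior_chest_rt", "obesity", "current_smoker", "ckd",
                      "hyperlipidemia", "diabetes", "hypertension")
_MEDIUM_ADD_ORDER = ("hypertension", "diabetes", "current_smoker", "obesity")


def _drop_medium(profile: PredictorProfile, factor: str) -> bool:
    """Clear one fired medium factor in place; returns True if anything changed."""
    if factor == "arrhythmia" and profile.arrhythmia:
        profile.arrhythmia = False
    elif factor == "prior_nonanthracycline_chemo" and profile.prior_nonanthracycline_chemo:
        profile.prior_nonanthracycline_chemo = False
    elif factor == "prior_chest_rt" and profile.prior_chest_rt:
        profile.prior_chest_rt = False
    elif factor == "obesity" and profile.bmi is not None and profile.bmi > 30:
        profile.bmi = 27.0
    elif factor == "current_smoker" and profile.current_smoker:
        profile.current_smoker = False
    elif factor == "ckd" and (profile.ckd_diagnosis or profile.egfr < 60):
        profile.ckd_diagnosis = False
        profile.egfr = max(profile.egfr, 80.0)
    elif factor == "hyperlipidemia" and (profile.total_cholesterol
                                         - profile.hdl_cholesterol > 3.8):
        profile.total_cholesterol = profile.hdl_cholesterol + 3.3
    elif factor == "diabetes" and profile.diabetes:
        profile.diabetes = False
    elif factor == "hypertension" and (profile.antihypertensive_use
                                       or profile.systolic_bp > 140
                                       or profile.diastolic_bp > 90):
        profile.antihypertensive_use = False
        profile.systolic_bp = min(profile.systolic_bp, 135.0)
        profile.diastolic_bp = min(profile.diastolic_bp, 85.0)
    else:
        return False
    return True


def _add_medium(profile: PredictorProfile, factor: str) -> bool:
    if factor == "hypertension" and not profile.antihypertensive_use:
        profile.antihypertensive_use = True
    elif factor == "diabetes" and not profile.diabetes:
        profile.diabetes = True
    elif factor == "current_smoker" and not profile.current_smoker:
        profile.current_smoker = True
    elif factor == "obesity" and profile.bmi <= 30:
        profile.bmi = 31.5
    else:
        return False
    return True


def repair_profile(
    profile: PredictorProfile, intended: RiskCategory,
    scoring_config: ScoringConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Minimally adjust a drawn profile so scoring yields ``intended``.

    Returns the list of fields changed (the repair log).  Changes are made in
    a fixed priority order, fewest fields first.
    """
    rng = rng or np.random.default_rng(0)
    changed: list[str] = []

    if intended is RiskCategory.VERY_HIGH:
        if not profile.heart_failure:
            profile.heart_failure = True
            changed.append("heart_failure")
        return changed
    if profile.heart_failure:
        profile.heart_failure = False
        changed.append("heart_failure")

    if intended is RiskCategory.HIGH:
        a = score_subject(profile, scoring_config)
        if not a.high_factors and a.medium_points < 5:
            profile.coronary_artery_disease = True  # most prevalent high factor
            changed.append("coronary_artery_disease")
        return changed

    # LOW / MODERATE: strip all high factors
    for name in ("coronary_artery_disease", "cerebrovascular_disease",
                 "peripheral_artery_disease", "valvular_disease",
                 "prior_anthracycline"):
        if getattr(profile, name):
            setattr(profile, name, False)
            changed.append(name)
    if profile.age >= 80:
        profile.age = float(rng.uniform(70.0, 79.0))
        changed.append("age")
    if intended is RiskCategory.LOW and profile.age >= 65:
        profile.age = float(rng.uniform(45.0, 64.0))  # age 65-79 alone is 2 points
        changed.append("age")

    cap = 1 if intended is RiskCategory.LOW else 4
    floor = 0 if intended is RiskCategory.LOW else 2
    for _ in range(20):
        a = score_subject(profile, scoring_config)
        if a.medium_points <= cap:
            break
        for factor in _MEDIUM_DROP_ORDER:
            if _drop_medium(profile, factor):
                changed.append(factor)
                break
    for _ in range(10):
        a = score_subject(profile, scoring_config)
        if a.medium_points >= floor:
            break
        for factor in _MEDIUM_ADD_ORDER:
            if _add_medium(profile, factor):
                changed.append(factor)
                break
    return changed


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

_CAUSE_ORDER = (EventType.HF_HOSP, EventType.MI, EventType.STROKE, EventType.CVD_DEATH)


@dataclass
class SyntheticCohort:
    profiles: list[PredictorProfile]
    contexts: list[CancerContext]
    events: list[EventRecord]
    intended_categories: list[RiskCategory]
    hazards: list[tuple[float, float]]  # per category (lambda_cvd, lambda_death)
    repair_counts: dict[str, int]


def _draw_event_time(rng: np.random.Generator, lam: float, shape: float) -> float:
    if lam <= 0:
        return math.inf
    if shape == 1.0:
        return float(rng.exponential(1.0 / lam))
    # Weibull with the same cumulative hazard scale: H(t) = (lam * t)^shape
    return float(rng.weibull(shape) / lam)


def generate_cohort(
    config: SyntheticCohortConfig,
    scoring_config: ScoringConfig = DEFAULT_CONFIG,
) -> SyntheticCohort:
    """Generate a cohort whose scored categories equal the intended draw.

    Deterministic for a fixed config (byte-identical CSVs across runs).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    hazards = default_category_hazards(config)
    cause_p = np.asarray(config.cause_split, dtype=float)

    profiles, contexts, events = [], [], []
    intended: list[RiskCategory] = []
    repair_counts: dict[str, int] = {}
    width = len(str(max(config.n, 1)))

    cats = rng.choice(4, size=config.n, p=np.asarray(config.category_mix))
    for i in range(config.n):
        k = int(cats[i])
        sid = f"S{i:0{width}d}"
        profile = _draw_profile(sid, k, config, rng)
        for f in repair_profile(profile, RiskCategory(k), scoring_config, rng):
            repair_counts[f] = repair_counts.get(f, 0) + 1
        intended.append(RiskCategory(k))

        lam_cvd, lam_death = hazards[k]
        t_cvd = _draw_event_time(rng, lam_cvd, config.weibull_shape)
        t_death = _draw_event_time(rng, lam_death, config.weibull_shape)
        censor = float(rng.uniform(*config.censor_window))
        profile.followup_years = censor
        profiles.append(profile)

        cause = _CAUSE_ORDER[int(rng.choice(4, p=cause_p))]
        mi_dx = DxPosition.PRIMARY if rng.random() < 0.5 else DxPosition.SECONDARY
        if t_cvd < t_death and t_cvd <= censor:
            if cause is EventType.CVD_DEATH:
                events.append(EventRecord(sid, cause, t_cvd))
            else:
                dx = mi_dx if cause is EventType.MI else DxPosition.PRIMARY
                events.append(EventRecord(sid, cause, t_cvd, dx))
                if t_death <= censor:
                    events.append(EventRecord(sid, EventType.NONCVD_DEATH, t_death))
        elif t_death <= censor:
            events.append(EventRecord(sid, EventType.NONCVD_DEATH, t_death))

        ct_w = np.asarray(config.cancer_mix[k], dtype=float)
        ctype = CANCER_TYPES[int(rng.choice(len(CANCER_TYPES), p=ct_w / ct_w.sum()))]
        contexts.append(CancerContext(
            subject_id=sid, cancer_type=ctype,
            metastatic=bool(rng.random() < config.prevalence["metastatic"][k]),
            received_anthracycline=bool(rng.random() < config.prevalence["received_anthracycline"][k]),
            received_her2=bool(rng.random() < config.prevalence["received_her2"][k]),
            received_vegf_iv=bool(rng.random() < config.prevalence["received_vegf_iv"][k]),
            received_myeloma_tx=bool(rng.random() < config.prevalence["received_myeloma_tx"][k]),
            received_cardiotoxic_rt=bool(rng.random() < config.prevalence["received_cardiotoxic_rt"][k]),
        ))

    # MCAR missingness applied last so repairs operate on complete data
    for name, rate in config.missingness.items():
        if rate <= 0:
            continue
        for profile in profiles:
            if rng.random() < rate:
                setattr(profile, name, None)

    return SyntheticCohort(profiles, contexts, events, intended, hazards,
                           repair_counts)


def expected_crude_cvd_incidence(
    lam_cvd: float, lam_death: float, censor_window: tuple[float, float]
) -> float:
    """Closed-form P(composite CVD event before administrative censoring).

    With C ~ Uniform(a, b): E[CIF(C)] = (lam_cvd/L)(1 - E[e^{-LC}]) and
    E[e^{-LC}] = (e^{-La} - e^{-Lb}) / (L (b - a)).
    """
    a, b = censor_window
    L = lam_cvd + lam_death
    if L == 0:
        return 0.0
    e_exp = (math.exp(-L * a) - math.exp(-L * b)) / (L * (b - a)) if b > a \
        else math.exp(-L * a)
    return lam_cvd / L * (1.0 - e_exp)


def generate_validation_scenario(
    config: SyntheticCohortConfig,
    scoring_config: ScoringConfig = DEFAULT_CONFIG,
) -> tuple[SyntheticCohort, dict]:
    """Cohort plus closed-form expectations for test assertions."""
    cohort = generate_cohort(config, scoring_config)
    n = config.n
    per_category = []
    total_expected = 0.0
    for k, (lam_cvd, lam_death) in enumerate(cohort.hazards):
        p = expected_crude_cvd_incidence(lam_cvd, lam_death, config.censor_window)
        n_k = config.category_mix[k] * n
        per_category.append({
            "category": RiskCategory(k).label,
            "lambda_cvd": lam_cvd, "lambda_death": lam_death,
            "expected_crude_cvd_incidence": p,
            "expected_n": n_k, "expected_events": p * n_k,
            "target_cif_cvd": config.cvd_targets[k],
            "cif_cvd_at_anchor": competing_cif(
                config.cvd_anchor_years, lam_cvd, lam_cvd + lam_death),
        })
        total_expected += p * n_k
    return cohort, {"per_category": per_category,
                    "expected_total_events": total_expected}
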