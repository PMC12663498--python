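"""Pipeline runner: impute -> score -> outcomes -> validate -> report.

Also holds the published validation-cohort margins (``REFERENCE_COHORT``)
that the synthetic generator emulates, and the worked-example reconstruction
of the 2x2 classification table from those printed margins.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import endpoints, imputation, scoring, survival_stats
from .cohort_model import (
    EventType,
    OutcomeRecord,
    PredictorProfile,
    RiskCategory,
    read_cohort,
)
from .scoring import DEFAULT_CONFIG, ScoringConfig, derive_predictors
from .survival_stats import ConfusionMatrix, classification_metrics
from .synthetic_data import SyntheticCohortConfig, generate_cohort

logger = logging.getLogger("cardioscore")

#: Published margins of the validation cohort the generator's defaults emulate.
REFERENCE_COHORT = {
    "n": 2290,
    "category_n": {"low": 631, "moderate": 806, "high": 785, "very_high": 68},
    "crude_cvd_incidence": {"low": 0.07, "moderate": 0.21, "high": 0.29,
                            "very_high": 0.37},
    "all_cause_mortality": {"low": 0.32, "moderate": 0.55, "high": 0.79,
                            "very_high": 0.89},
    "total_cvd_events": 460,
    "first_event_counts": {"HF_HOSP": 87, "MI": 161, "STROKE": 130,
                           "CVD_DEATH": 82},
    "cvd_events_first_year": 91,
    "median_followup_years": 6.9,
    "mortality_median_followup_years": 8.7,
    "harrell_c": 0.696,
}


def reconstruct_reference_confusion() -> ConfusionMatrix:
    """Reconstruct the low-moderate vs high-very-high 2x2 table from printed
    margins: group sizes, total events, and the two positive-stratum crude
    incidences.

    tp = round(0.29*785 + 0.37*68); fn = 460 - tp; fp = n_positive - tp;
    tn = n_negative - fn.
    """
    ref = REFERENCE_COHORT
    n_high = ref["category_n"]["high"]
    n_vh = ref["category_n"]["very_high"]
    tp = round(ref["crude_cvd_incidence"]["high"] * n_high
               + ref["crude_cvd_incidence"]["very_high"] * n_vh)
    fn = ref["total_cvd_events"] - tp
    fp = (n_high + n_vh) - tp
    tn = (ref["category_n"]["low"] + ref["category_n"]["moderate"]) - fn
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


# --------------------------------------------------------------------------
# Imputation plumbing: profile list <-> numeric table
# --------------------------------------------------------------------------

_CONTINUOUS = ("age", "systolic_bp", "diastolic_bp", "egfr", "bmi",
               "total_cholesterol", "hdl_cholesterol")
_BINARY = ("antihypertensive_use", "diabetes", "coronary_artery_disease",
           "cerebrovascular_disease", "peripheral_artery_disease",
           "heart_failure", "valvular_disease", "arrhythmia", "ckd_diagnosis",
           "current_smoker", "prior_anthracycline",
           "prior_nonanthracycline_chemo", "prior_chest_rt")


def default_imputation_methods() -> dict[str, str]:
    methods = {c: "pmm" for c in _CONTINUOUS}
    methods.update({c: "logistic" for c in _BINARY})
    methods["male"] = "logistic"
    return methods


def profiles_to_table(profiles: Sequence[PredictorProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {c: getattr(p, c) for c in _CONTINUOUS}
        row.update({c: (None if getattr(p, c) is None else float(getattr(p, c)))
                    for c in _BINARY})
        row["male"] = None if p.sex is None else float(p.sex == "male")
        rows.append(row)
    return pd.DataFrame(rows, index=[p.subject_id for p in profiles],
                        dtype=float)


def table_to_profiles(
    table: pd.DataFrame, originals: Sequence[PredictorProfile]
) -> list[PredictorProfile]:
    out = []
    for p in originals:
        row = table.loc[p.subject_id]
        kw = dataclasses.asdict(p)
        for c in _CONTINUOUS:
            kw[c] = float(row[c])
        for c in _BINARY:
            kw[c] = bool(row[c] >= 0.5)
        kw["sex"] = "male" if row["male"] >= 0.5 else "female"
        out.append(PredictorProfile(**kw))
    return out


def impute_cohort(
    profiles: Sequence[PredictorProfile], outcomes: Sequence[OutcomeRecord],
    m: int = 5, iterations: int = 5, seed: int = 0,
) -> tuple[list[PredictorProfile], dict]:
    """MICE-impute the predictor table (outcome as Nelson-Aalen covariate +
    event flag) and return the single randomly selected completed dataset."""
    table = profiles_to_table(profiles)
    na_cov = imputation.nelson_aalen_outcome_covariate(list(outcomes))
    table["_outcome_cumhaz"] = na_cov
    table["_outcome_event"] = [float(o.status == 1) for o in outcomes]
    spec = imputation.ImputationSpec(methods=default_imputation_methods(),
                                     m=m, iterations=iterations, seed=seed)
    completed, diagnostics = imputation.mice_impute(table, spec)
    selected, idx = imputation.select_single_dataset(completed, seed=seed + 1)
    diagnostics["selected_index"] = idx
    return table_to_profiles(selected, profiles), diagnostics


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One validation run: exactly one input source (CSV paths or synthetic)."""

    cohort_csv: str | None = None
    events_csv: str | None = None
    synthetic: SyntheticCohortConfig | None = None
    horizon_years: float | None = None  # cap on per-subject follow-up
    analysis: str = "composite"  # composite | hf_only | mi_only
    exclude_metastatic: bool = False
    landmark_years: float | None = None
    subgroup: str | None = None  # None | anthracycline | pooled_cardiotoxic
    merge_high_very_high: bool = False
    impute: bool = True
    imputation_m: int = 5
    imputation_iterations: int = 5
    seed: int = 0
    output_dir: str | None = None
    #: profile fields fitted as per-predictor Fine-Gray sHRs
    fg_predictors: tuple[str, ...] = (
        "heart_failure", "valvular_disease", "coronary_artery_disease",
        "cerebrovascular_disease", "arrhythmia", "diabetes",
        "current_smoker",
    )

    def validate(self) -> None:
        if (self.synthetic is None) == (self.cohort_csv is None):
            raise ValueError("exactly one input source: cohort_csv or synthetic")
        if self.horizon_years is not None and self.horizon_years <= 0:
            raise ValueError("horizon must be positive")
        if self.analysis not in ("composite", "hf_only", "mi_only"):
            raise ValueError(f"unknown analysis {self.analysis!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticCohortConfig(**syn)
        return cfg


def _category_dummies(categories: np.ndarray, merge: bool) -> tuple[np.ndarray, list[str]]:
    levels = [RiskCategory.MODERATE, RiskCategory.HIGH] if merge else \
        [RiskCategory.MODERATE, RiskCategory.HIGH, RiskCategory.VERY_HIGH]
    cats = np.minimum(categories, RiskCategory.HIGH) if merge else categories
    X = np.column_stack([(cats == lvl).astype(float) for lvl in levels])
    names = [("high_very_high" if merge and lvl is RiskCategory.HIGH else lvl.label)
             for lvl in levels]
    return X, names


def run_validation(config: RunConfig,
                   scoring_config: ScoringConfig = DEFAULT_CONFIG) -> dict:
    """Execute the full analysis and return the report dictionary.

    Deterministic for a fixed config/seed.  If ``output_dir`` is set, the
    report is also written as JSON and markdown.
    """
    config.validate()

    # ---- input ----------------------------------------------------------
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic, scoring_config)
        profiles, contexts, events = cohort.profiles, cohort.contexts, cohort.events
    else:
        profiles, contexts, events = read_cohort(config.cohort_csv, config.events_csv)

    subject_ids = [p.subject_id for p in profiles]
    horizons = {}
    for p in profiles:
        h = p.followup_years if p.followup_years is not None else config.horizon_years
        if h is None:
            raise ValueError(f"subject {p.subject_id}: no follow-up horizon available")
        if config.horizon_years is not None:
            h = min(h, config.horizon_years)
        horizons[p.subject_id] = h

    cause = {"composite": None, "hf_only": EventType.HF_HOSP,
             "mi_only": EventType.MI}[config.analysis]
    outcomes = endpoints.build_outcomes(events, horizons, subject_ids, cause=cause)

    # ---- imputation (precedes scoring) ----------------------------------
    imputation_diag = None
    has_missing = profiles_to_table(profiles).isna().any().any()
    if config.impute and has_missing:
        profiles, imputation_diag = impute_cohort(
            profiles, outcomes, m=config.imputation_m,
            iterations=config.imputation_iterations, seed=config.seed)

    # ---- scoring ---------------------------------------------------------
    assessments, _ = scoring.stratify_cohort(profiles, scoring_config)

    # ---- filters ---------------------------------------------------------
    by_id = dict(zip(subject_ids, range(len(subject_ids))))
    keep = np.ones(len(subject_ids), dtype=bool)
    if config.exclude_metastatic:
        for c in contexts:
            if c.metastatic:
                keep[by_id[c.subject_id]] = False
    if config.subgroup == "anthracycline":
        for c in contexts:
            if not c.received_anthracycline:
                keep[by_id[c.subject_id]] = False
    elif config.subgroup == "pooled_cardiotoxic":
        for c in contexts:
            if not (c.received_anthracycline or c.received_her2
                    or c.received_vegf_iv or c.received_myeloma_tx):
                keep[by_id[c.subject_id]] = False
    if config.landmark_years is not None:
        for i, o in enumerate(outcomes):
            if o.time < config.landmark_years:
                keep[i] = False

    kept = np.where(keep)[0]
    profiles = [profiles[i] for i in kept]
    assessments = [assessments[i] for i in kept]
    outcomes = [outcomes[i] for i in kept]
    n = len(kept)
    if n == 0:
        raise ValueError("no subjects remain after filtering")

    categories = np.array([int(a.category) for a in assessments])
    if config.merge_high_very_high:
        categories = np.minimum(categories, int(RiskCategory.HIGH))
    times = np.array([o.time for o in outcomes])
    status = np.array([o.status for o in outcomes])
    event1 = (status == 1).astype(int)

    # ---- per-category summaries -----------------------------------------
    cat_levels = sorted(set(categories.tolist()))
    per_category = []
    for lvl in cat_levels:
        mask = categories == lvl
        label = RiskCategory(lvl).label if not (
            config.merge_high_very_high and lvl == int(RiskCategory.HIGH)) \
            else "high_very_high"
        sub_out = [o for o, m in zip(outcomes, mask) if m]
        km = survival_stats.kaplan_meier(times[mask], event1[mask]) \
            if mask.sum() else None
        aj = survival_stats.aalen_johansen_cif(times[mask], status[mask]) \
            if (status[mask] > 0).any() else None
        per_category.append({
            "category": label,
            "n": int(mask.sum()),
            "proportion": float(mask.mean()),
            "crude_incidence": endpoints.crude_incidence(sub_out),
            "km": None if km is None else {
                "times": km.times.tolist(), "survival": km.survival.tolist()},
            "cif_cvd": None if aj is None else {
                "times": aj.times.tolist(), "cif": aj.cif1.tolist()},
        })

    interval = endpoints.interval_incidence(outcomes)

    # ---- discrimination & regression ------------------------------------
    conc = survival_stats.harrell_c(categories, times, event1)
    X_cat, names = _category_dummies(categories, config.merge_high_very_high)
    cox = survival_stats.cox_ph_fit(X_cat, times, event1, names=names)
    try:
        fg = survival_stats.fine_gray_fit(X_cat, times, status, names=names)
        fg_summary = fg.summary()
    except ValueError as exc:  # e.g. no competing events in a tiny subgroup
        logger.warning("category Fine-Gray fit skipped: %s", exc)
        fg_summary = None

    cm = survival_stats.dichotomize_and_tabulate(
        [RiskCategory(c) for c in categories], outcomes)
    metrics = classification_metrics(cm)

    # ---- per-predictor Fine-Gray sHRs (unadjusted and age/sex-adjusted) --
    age = np.array([p.age for p in profiles], dtype=float)
    male = np.array([1.0 if p.sex == "male" else 0.0 for p in profiles])
    predictor_fits = []
    for name in config.fg_predictors:
        x = np.array([float(bool(getattr(p, name))) for p in profiles])
        if x.std() == 0:
            continue
        try:
            un = survival_stats.fine_gray_fit(x[:, None], times, status, names=[name])
            adj = survival_stats.fine_gray_fit(
                np.column_stack([x, age, male]), times, status,
                names=[name, "age", "male"])
        except ValueError as exc:
            logger.warning("predictor %s: Fine-Gray fit failed (%s)", name, exc)
            continue
        predictor_fits.append({
            "predictor": name,
            "unadjusted": un.summary()[0],
            "adjusted": adj.summary()[0],
        })

    report = {
        "config": {
            "analysis": config.analysis, "n": n,
            "exclude_metastatic": config.exclude_metastatic,
            "landmark_years": config.landmark_years,
            "subgroup": config.subgroup,
            "merge_high_very_high": config.merge_high_very_high,
            "seed": config.seed,
        },
        "per_category": per_category,
        "interval_incidence": interval.to_dict("records"),
        "first_event_composition": endpoints.first_event_composition(outcomes),
        "harrell_c": {"c": conc.c, "ci": [conc.ci_lower, conc.ci_upper],
                      "comparable_pairs": conc.comparable_pairs},
        "cox_vs_low": cox.summary(),
        "fine_gray_vs_low": fg_summary,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "classification_metrics": {
            "raw": {k: v for k, v in metrics.__dict__.items()},
            "rounded": metrics.rounded(),
        },
        "predictor_shr": predictor_fits,
        "imputation": imputation_diag if imputation_diag is None else {
            "selected_index": imputation_diag["selected_index"],
            "n_missing": imputation_diag["n_missing"],
        },
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "report.md").write_text(render_markdown(report))
    return report


def render_markdown(report: dict) -> str:
    """Compact human-readable summary of a validation report."""
    lines = ["# Risk-stratification validation report", ""]
    cfg = report["config"]
    lines.append(f"Analysis: **{cfg['analysis']}**, n = {cfg['n']}, "
                 f"seed = {cfg['seed']}")
    lines += ["", "## Incidence by risk category", "",
              "| category | n | proportion | crude incidence |",
              "|---|---|---|---|"]
    for row in report["per_category"]:
        lines.append(f"| {row['category']} | {row['n']} | "
                     f"{row['proportion']:.3f} | {row['crude_incidence']:.3f} |")
    c = report["harrell_c"]
    lines += ["", f"Harrell C = {c['c']:.3f} "
              f"(95% CI {c['ci'][0]:.3f}-{c['ci'][1]:.3f})", ""]
    lines += ["## Hazard ratios vs low risk", "",
              "| covariate | HR | 95% CI |", "|---|---|---|"]
    for row in report["cox_vs_low"]:
        lines.append(f"| {row['covariate']} | {row['hr']:.2f} | "
                     f"{row['hr_ci_lower']:.2f}-{row['hr_ci_upper']:.2f} |")
    m = report["classification_metrics"]["rounded"]
    lines += ["", "## Dichotomised classification (low-moderate vs high-very-high)",
              "", f"sensitivity {m['sensitivity']}%, specificity {m['specificity']}%, "
              f"PPV {m['ppv']}%, NPV {m['npv']}%, accuracy {m['accuracy']}%", ""]
    return "\n".join(lines)
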