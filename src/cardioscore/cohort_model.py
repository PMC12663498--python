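"""Domain types shared by all stages, and the cohort CSV dialect.

A cohort is transported as two plain-text CSV files:

* a **subject table** — one row per subject holding the baseline clinical
  predictors (:class:`PredictorProfile`) and cancer descriptors
  (:class:`CancerContext`), booleans serialised as ``0``/``1`` and missing
  values as the canonical token ``NA`` (empty cells also read as missing);
* a **long-format event table** — one row per registry event
  (:class:`EventRecord`): ``subject_id, event_type, time_years, dx_position``.

Times are stored in years from cancer diagnosis (the index date).  Raw data
recorded in days can be converted on read with ``times_in_days=True``
(division by 365.25).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("cardioscore")

DAYS_PER_YEAR = 365.25
#: Canonical serialisation of a missing cell.
MISSING_TOKEN = "NA"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class EventType(str, Enum):
    HF_HOSP = "HF_HOSP"
    MI = "MI"
    STROKE = "STROKE"
    CVD_DEATH = "CVD_DEATH"
    NONCVD_DEATH = "NONCVD_DEATH"


#: Event types that terminate follow-up.
DEATH_EVENTS = frozenset({EventType.CVD_DEATH, EventType.NONCVD_DEATH})


class DxPosition(str, Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"


class RiskCategory(IntEnum):
    """Four-level baseline risk category; ordinal, LOW < VERY_HIGH."""

    LOW = 0
    MODERATE = 1
    HIGH = 2
    VERY_HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()


#: The eight cancer-diagnosis groups used for cohort description.
CANCER_TYPES = (
    "gastrointestinal",
    "lung",
    "melanoma",
    "breast",
    "female_genital",
    "prostate",
    "lymphoma_hematological",
    "other_solid",
)


@dataclass
class PredictorProfile:
    """One subject's raw baseline clinical variables.

    Any field except ``subject_id`` may be ``None`` (missing).  Booleans are
    Python bools; continuous variables floats in the stated units.
    """

    subject_id: str
    age: float | None = None  # years
    sex: str | None = None  # "male" / "female"
    systolic_bp: float | None = None  # mmHg
    diastolic_bp: float | None = None  # mmHg
    antihypertensive_use: bool | None = None
    diabetes: bool | None = None
    coronary_artery_disease: bool | None = None  # MI, PCI, CABG or stable angina
    cerebrovascular_disease: bool | None = None  # stroke / TIA
    peripheral_artery_disease: bool | None = None
    heart_failure: bool | None = None
    valvular_disease: bool | None = None
    arrhythmia: bool | None = None  # AF, flutter, VT
    egfr: float | None = None  # mL/min/1.73 m^2
    ckd_diagnosis: bool | None = None
    current_smoker: bool | None = None
    bmi: float | None = None  # kg/m^2
    total_cholesterol: float | None = None  # mmol/L
    hdl_cholesterol: float | None = None  # mmol/L
    prior_anthracycline: bool | None = None  # exposure before baseline
    prior_nonanthracycline_chemo: bool | None = None
    prior_chest_rt: bool | None = None  # left chest / mediastinum
    followup_years: float | None = None  # administrative end of follow-up

    def validate(self) -> None:
        if self.age is not None and not self.age > 0:
            raise ValueError(f"subject {self.subject_id}: age must be > 0")
        for name in ("systolic_bp", "diastolic_bp", "egfr", "bmi",
                     "total_cholesterol", "hdl_cholesterol"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"subject {self.subject_id}: {name} must be nonnegative")
        if (self.hdl_cholesterol is not None and self.total_cholesterol is not None
                and self.hdl_cholesterol > self.total_cholesterol):
            raise ValueError(
                f"subject {self.subject_id}: HDL exceeds total cholesterol")


@dataclass
class CancerContext:
    """Cancer descriptors and post-baseline treatment-received flags.

    Treatments received *after* the baseline assessment never feed the risk
    score; they define subgroups only.
    """

    subject_id: str
    cancer_type: str | None = None
    metastatic: bool | None = None
    received_anthracycline: bool | None = None
    received_her2: bool | None = None
    received_vegf_iv: bool | None = None
    received_myeloma_tx: bool | None = None
    received_cardiotoxic_rt: bool | None = None

    def validate(self) -> None:
        if self.cancer_type is not None and self.cancer_type not in CANCER_TYPES:
            raise ValueError(
                f"subject {self.subject_id}: unknown cancer_type {self.cancer_type!r}")


@dataclass
class EventRecord:
    """One registry event: type, time (years from diagnosis), dx position."""

    subject_id: str
    event_type: EventType
    time: float
    dx_position: DxPosition | None = None  # meaningful for hospitalisations

    def __post_init__(self) -> None:
        self.event_type = EventType(self.event_type)
        if self.dx_position is not None:
            self.dx_position = DxPosition(self.dx_position)
        if self.time < 0:
            raise ValueError(
                f"subject {self.subject_id}: negative event time {self.time}")


@dataclass
class OutcomeRecord:
    """Competing-risk outcome: 0=censored, 1=composite CVD event, 2=non-CVD death."""

    subject_id: str
    time: float
    status: int
    first_event_type: EventType | None = None

    def __post_init__(self) -> None:
        if self.status not in (0, 1, 2):
            raise ValueError(f"invalid status {self.status}")
        if (self.status == 1) != (self.first_event_type is not None):
            raise ValueError("first_event_type must be set iff status == 1")


# --------------------------------------------------------------------------
# CSV dialect
# --------------------------------------------------------------------------

_PROFILE_BOOL = (
    "antihypertensive_use", "diabetes", "coronary_artery_disease",
    "cerebrovascular_disease", "peripheral_artery_disease", "heart_failure",
    "valvular_disease", "arrhythmia", "ckd_diagnosis", "current_smoker",
    "prior_anthracycline", "prior_nonanthracycline_chemo", "prior_chest_rt",
)
_PROFILE_FLOAT = (
    "age", "systolic_bp", "diastolic_bp", "egfr", "bmi",
    "total_cholesterol", "hdl_cholesterol", "followup_years",
)
_CONTEXT_BOOL = (
    "metastatic", "received_anthracycline", "received_her2",
    "received_vegf_iv", "received_myeloma_tx", "received_cardiotoxic_rt",
)

SUBJECT_COLUMNS: tuple[str, ...] = (
    ("subject_id",)
    + tuple(f.name for f in fields(PredictorProfile))[1:]
    + tuple(f.name for f in fields(CancerContext))[1:]
)
#: Columns that must be present in a subject CSV.
MANDATORY_SUBJECT_COLUMNS = ("subject_id", "age", "sex")

EVENT_COLUMNS = ("subject_id", "event_type", "time_years", "dx_position")


def _parse_float(raw, subject_id: str, column: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s in ("", MISSING_TOKEN):
        return None
    try:
        return float(s)
    except ValueError:
        logger.warning("subject %s: unparseable %s cell %r -> missing",
                       subject_id, column, raw)
        return None


def _parse_bool(raw, subject_id: str, column: str) -> bool | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s in ("", MISSING_TOKEN):
        return None
    if s in ("0", "1"):
        return s == "1"
    if s.lower() in ("true", "false"):
        return s.lower() == "true"
    logger.warning("subject %s: unparseable %s cell %r -> missing",
                   subject_id, column, raw)
    return None


def _parse_str(raw) -> str | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    return None if s in ("", MISSING_TOKEN) else s


def read_subjects(path: str | Path) -> tuple[list[PredictorProfile], list[CancerContext]]:
    """Read the subject table; returns profiles and cancer contexts.

    Raises on a missing mandatory column or a duplicated ``subject_id``;
    unparseable cells become missing values with a logged warning so the row
    count is always conserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANDATORY_SUBJECT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate subject_id: {dup.iloc[0]!r}")

    profiles: list[PredictorProfile] = []
    contexts: list[CancerContext] = []
    for row in df.to_dict("records"):
        sid = str(row["subject_id"])
        kw: dict = {"subject_id": sid}
        for name in _PROFILE_FLOAT:
            kw[name] = _parse_float(row.get(name), sid, name)
        for name in _PROFILE_BOOL:
            kw[name] = _parse_bool(row.get(name), sid, name)
        kw["sex"] = _parse_str(row.get("sex"))
        profile = PredictorProfile(**kw)
        profile.validate()
        profiles.append(profile)

        ckw: dict = {"subject_id": sid, "cancer_type": _parse_str(row.get("cancer_type"))}
        for name in _CONTEXT_BOOL:
            ckw[name] = _parse_bool(row.get(name), sid, name)
        context = CancerContext(**ckw)
        context.validate()
        contexts.append(context)
    return profiles, contexts


def read_events(path: str | Path, times_in_days: bool = False) -> list[EventRecord]:
    """Read the long-format event table and enforce its invariants."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("subject_id", "event_type", "time_years"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    records: list[EventRecord] = []
    for row in df.to_dict("records"):
        sid = str(row["subject_id"])
        t = float(row["time_years"])
        if times_in_days:
            t /= DAYS_PER_YEAR
        dx = _parse_str(row.get("dx_position"))
        records.append(EventRecord(sid, EventType(row["event_type"]), t,
                                   DxPosition(dx) if dx else None))
    validate_events(records)
    return records


def validate_events(events: Iterable[EventRecord]) -> None:
    """At most one death per subject; death never precedes another event."""
    by_subject: dict[str, list[EventRecord]] = {}
    for e in events:
        by_subject.setdefault(e.subject_id, []).append(e)
    for sid, recs in by_subject.items():
        deaths = [e for e in recs if e.event_type in DEATH_EVENTS]
        if len(deaths) > 1:
            raise ValueError(f"subject {sid}: more than one death record")
        if deaths:
            t_death = deaths[0].time
            if any(e.time > t_death for e in recs):
                raise ValueError(f"subject {sid}: event recorded after death")


def read_cohort(
    cohort_path: str | Path, events_path: str | Path | None = None,
    times_in_days: bool = False,
) -> tuple[list[PredictorProfile], list[CancerContext], list[EventRecord]]:
    """Read subject and (optionally) event CSVs; see module docstring for dialect."""
    profiles, contexts = read_subjects(cohort_path)
    events = read_events(events_path, times_in_days) if events_path else []
    return profiles, contexts, events


def _cell(value) -> str:
    if value is None:
        return MISSING_TOKEN
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, float):
        return repr(value)  # shortest round-tripping decimal
    return str(value)


def write_subjects(
    profiles: Sequence[PredictorProfile], contexts: Sequence[CancerContext],
    path: str | Path,
) -> None:
    """Write the subject table; inverse of :func:`read_subjects`."""
    ctx_by_id = {c.subject_id: c for c in contexts}
    rows = []
    for p in profiles:
        c = ctx_by_id.get(p.subject_id, CancerContext(p.subject_id))
        row = {f.name: _cell(getattr(p, f.name)) for f in fields(PredictorProfile)}
        row.update({f.name: _cell(getattr(c, f.name))
                    for f in fields(CancerContext) if f.name != "subject_id"})
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(SUBJECT_COLUMNS))
    df.to_csv(path, index=False)


def write_events(events: Sequence[EventRecord], path: str | Path) -> None:
    rows = [{"subject_id": e.subject_id, "event_type": e.event_type.value,
             "time_years": repr(float(e.time)),
             "dx_position": e.dx_position.value if e.dx_position else MISSING_TOKEN}
            for e in events]
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(path, index=False)


def write_cohort(
    profiles: Sequence[PredictorProfile], contexts: Sequence[CancerContext],
    events: Sequence[EventRecord], cohort_path: str | Path,
    events_path: str | Path | None = None,
) -> None:
    """Write cohort CSVs; ``read_cohort(write_cohort(x)) == x`` (round-trip)."""
    write_subjects(profiles, contexts, cohort_path)
    if events_path is not None:
        write_events(events, events_path)


def write_outcomes(outcomes: Sequence[OutcomeRecord], path: str | Path) -> None:
    rows = [{"subject_id": o.subject_id, "time_years": repr(float(o.time)),
             "status": o.status,
             "first_event_type": o.first_event_type.value if o.first_event_type else MISSING_TOKEN}
            for o in outcomes]
    pd.DataFrame(rows).to_csv(path, index=False)
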