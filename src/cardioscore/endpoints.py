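"""Composite competing-risk endpoint construction and interval incidence.

The composite CVD endpoint is the *first* occurrence of: HF hospitalisation
(primary diagnosis only), nonfatal stroke (primary diagnosis only), nonfatal
MI (primary or secondary diagnosis), or CVD death.  Non-CVD death before any
qualifying event is the competing event (status 2); subjects with neither by
their administrative horizon are censored (status 0).

Conventions: follow-up starts at time 0 (cancer diagnosis; no delayed
entry); an event at exactly the horizon counts (censoring applies strictly
after); a qualifying CVD event tied with a death at the identical time
resolves to the CVD event.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_model import (
    DxPosition,
    EventRecord,
    EventType,
    OutcomeRecord,
    validate_events,
)

#: event types eligible for the composite, with their diagnosis-position rule
_COMPOSITE_RULES: dict[EventType, frozenset[DxPosition | None]] = {
    EventType.HF_HOSP: frozenset({DxPosition.PRIMARY}),
    EventType.STROKE: frozenset({DxPosition.PRIMARY}),
    EventType.MI: frozenset({DxPosition.PRIMARY, DxPosition.SECONDARY}),
    EventType.CVD_DEATH: frozenset({DxPosition.PRIMARY, DxPosition.SECONDARY, None}),
}


def _qualifies(event: EventRecord, rules: Mapping[EventType, frozenset]) -> bool:
    allowed = rules.get(event.event_type)
    return allowed is not None and event.dx_position in allowed


def _build(events: Sequence[EventRecord], horizon: float,
           rules: Mapping[EventType, frozenset],
           subject_id: str | None) -> OutcomeRecord:
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if subject_id is None:
        subject_id = events[0].subject_id if events else ""
    if any(e.subject_id != subject_id for e in events):
        raise ValueError("events must all belong to one subject")
    validate_events(events)

    qualifying = [e for e in events if _qualifies(e, rules) and e.time <= horizon]
    if qualifying:
        # earliest qualifying event; CVD event wins exact ties with death
        first = min(qualifying, key=lambda e: e.time)
        return OutcomeRecord(subject_id, first.time, 1, first.event_type)
    deaths = [e for e in events
              if e.event_type is EventType.NONCVD_DEATH and e.time <= horizon]
    if deaths:
        return OutcomeRecord(subject_id, deaths[0].time, 2)
    return OutcomeRecord(subject_id, horizon, 0)


def build_outcome(
    events: Sequence[EventRecord], horizon: float, subject_id: str | None = None
) -> OutcomeRecord:
    """Composite first-event outcome for one subject.

    ``horizon`` is the subject's administrative end of follow-up in years.
    Pass ``subject_id`` explicitly for subjects with no events.
    """
    return _build(events, horizon, _COMPOSITE_RULES, subject_id)


def build_single_cause_outcome(
    events: Sequence[EventRecord], cause: EventType, horizon: float,
    subject_id: str | None = None,
) -> OutcomeRecord:
    """Single-cause outcome (HF hospitalisation alone, or MI alone).

    Only the named cause qualifies (HF keeps its primary-diagnosis rule; MI
    keeps primary+secondary); *all* deaths of any cause become the competing
    event.
    """
    if cause not in (EventType.HF_HOSP, EventType.MI):
        raise ValueError(f"unsupported single cause: {cause}")
    rules = {cause: _COMPOSITE_RULES[cause]}
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if subject_id is None:
        subject_id = events[0].subject_id if events else ""
    validate_events(events)
    qualifying = [e for e in events if _qualifies(e, rules) and e.time <= horizon]
    deaths = [e for e in events
              if e.event_type in (EventType.NONCVD_DEATH, EventType.CVD_DEATH)
              and e.time <= horizon]
    if qualifying:
        first = min(qualifying, key=lambda e: e.time)
        # a death strictly before the first qualifying event competes
        if deaths and min(d.time for d in deaths) < first.time:
            return OutcomeRecord(subject_id, min(d.time for d in deaths), 2)
        return OutcomeRecord(subject_id, first.time, 1, first.event_type)
    if deaths:
        return OutcomeRecord(subject_id, min(d.time for d in deaths), 2)
    return OutcomeRecord(subject_id, horizon, 0)


def build_outcomes(
    events: Sequence[EventRecord], horizons: Mapping[str, float] | float,
    subject_ids: Sequence[str], cause: EventType | None = None,
) -> list[OutcomeRecord]:
    """Outcomes for a whole cohort; one record per subject in ``subject_ids``.

    ``horizons`` is either a single administrative horizon (years) or a
    per-subject mapping.  ``cause=None`` builds the composite; otherwise the
    single-cause variant.
    """
    by_subject: dict[str, list[EventRecord]] = defaultdict(list)
    for e in events:
        by_subject[e.subject_id].append(e)
    out = []
    for sid in subject_ids:
        h = horizons[sid] if isinstance(horizons, Mapping) else float(horizons)
        if cause is None:
            out.append(build_outcome(by_subject.get(sid, []), h, sid))
        else:
            out.append(build_single_cause_outcome(by_subject.get(sid, []), cause, h, sid))
    return out


def interval_incidence(
    outcomes: Sequence[OutcomeRecord], bin_years: float = 0.5
) -> pd.DataFrame:
    """Event incidence per time interval (default 6 months).

    Intervals are half-open ``[k*bin, (k+1)*bin)``; ``n_at_risk`` counts
    subjects with outcome time >= the interval start, ``n_events`` the
    composite events (status 1) inside the interval, ``rate`` their ratio.
    The event counts across all intervals sum to the total status-1 count.
    """
    if bin_years <= 0:
        raise ValueError("bin width must be positive")
    times = np.asarray([o.time for o in outcomes], dtype=float)
    status = np.asarray([o.status for o in outcomes], dtype=int)
    if len(times) == 0:
        return pd.DataFrame(columns=["interval_start", "interval_end",
                                     "n_at_risk", "n_events", "rate"])
    n_bins = int(np.floor(times.max() / bin_years)) + 1
    rows = []
    for k in range(n_bins):
        lo, hi = k * bin_years, (k + 1) * bin_years
        at_risk = int(np.sum(times >= lo))
        events = int(np.sum((status == 1) & (times >= lo) & (times < hi)))
        if k == n_bins - 1:  # times == max fall in the closing interval
            events += int(np.sum((status == 1) & (times == hi)))
        rows.append({"interval_start": lo, "interval_end": hi,
                     "n_at_risk": at_risk, "n_events": events,
                     "rate": events / at_risk if at_risk else 0.0})
    return pd.DataFrame(rows)


def crude_incidence(outcomes: Sequence[OutcomeRecord]) -> float:
    """Proportion of subjects with a composite event over entire follow-up."""
    if not outcomes:
        return float("nan")
    return sum(o.status == 1 for o in outcomes) / len(outcomes)


def first_event_composition(outcomes: Sequence[OutcomeRecord]) -> dict[str, float]:
    """Share of each first-event type among composite events."""
    firsts = [o.first_event_type for o in outcomes if o.status == 1]
    total = len(firsts)
    comp = {}
    for et in (EventType.HF_HOSP, EventType.MI, EventType.STROKE, EventType.CVD_DEATH):
        comp[et.value] = (sum(f is et for f in firsts) / total) if total else float("nan")
    return comp
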