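"""CTCAE adverse-event summarization, DLT classification and 3+3 escalation.

Two distinct counting bases are used, matching clinical-trial reporting
conventions: per-patient frequency tables deduplicate repeated occurrences of
a term within a patient by keeping the maximum-grade record, while
grade/attribution tables count every event.

A dose-limiting toxicity (DLT) is grade >= 3 acute CNS toxicity attributable
to the intervention persisting 96 hours or more, OR grade >= 3 attributable
non-CNS toxicity, inside the 28-day evaluation window.  "Attributable" means
the recorded relation is possible, probable or definite (configurable).
Escalation follows the canonical 3+3 decision table; the modeled trial used
a modified 3+3 whose specific modifications are not published, so the
canonical rules are used and labeled as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

RELATION_CATEGORIES = ("definite", "probable", "possible", "unlikely", "unrelated")
ATTRIBUTABLE_DEFAULT = ("possible", "probable", "definite")
GRADE_LABELS = {1: "mild", 2: "moderate", 3: "severe", 4: "life-threatening", 5: "death"}


@dataclass
class AdverseEvent:
    """One CTCAE-graded adverse event."""

    patient_id: str
    term: str
    grade: int
    relation: str
    cns: bool
    onset_day: float
    resolution_day: float | None = None
    serious: bool = False
    cohort: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.grade) <= 5:
            raise ValueError(f"CTCAE grade must be 1..5, got {self.grade}")
        if self.relation not in RELATION_CATEGORIES:
            raise ValueError(f"unknown relation category {self.relation!r}")
        if self.resolution_day is not None and self.resolution_day < self.onset_day:
            raise ValueError("resolution must not precede onset")

    @property
    def duration_h(self) -> float | None:
        if self.resolution_day is None:
            return None
        return (self.resolution_day - self.onset_day) * 24.0


@dataclass
class EscalationState:
    """Bookkeeping for one cohort at a 3+3 decision point."""

    cohort_id: int
    n_treated: int
    n_dlt: int
    dsmb_approved: bool = True

    def __post_init__(self) -> None:
        if self.n_dlt > self.n_treated:
            raise ValueError("cannot have more DLTs than treated patients")


def _as_frame(events: Iterable[AdverseEvent] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        df = events.copy()
    else:
        df = pd.DataFrame([vars(e) for e in events])
    bad = ~df["grade"].between(1, 5)
    if bad.any():
        raise ValueError(f"invalid CTCAE grades: {sorted(df.loc[bad, 'grade'].unique())}")
    return df


def dedupe_max_grade(events: Iterable[AdverseEvent] | pd.DataFrame) -> pd.DataFrame:
    """Keep one record per (patient, term): the maximum-grade occurrence."""
    df = _as_frame(events)
    idx = df.groupby(["patient_id", "term"])["grade"].idxmax()
    return df.loc[idx.sort_values()].reset_index(drop=True)


def patient_frequency_table(
    events: Iterable[AdverseEvent] | pd.DataFrame, n_patients: int
) -> pd.DataFrame:
    """Per-patient term frequencies (deduplicated basis), percent of cohort.

    A term's frequency is the number of distinct patients reporting it at
    least once; percentages are on a per-patient basis.
    """
    dd = dedupe_max_grade(events)
    counts = dd.groupby("term")["patient_id"].nunique().sort_values(ascending=False)
    return pd.DataFrame(
        {"n_patients": counts, "percent": (100.0 * counts / n_patients).round(1)}
    )


def grade_relation_summary(
    events: Iterable[AdverseEvent] | pd.DataFrame | None = None,
    grade_counts: pd.DataFrame | None = None,
    relation_counts: pd.DataFrame | None = None,
) -> dict:
    """Event-level grade and attribution tables, per cohort and overall.

    Accepts either a raw event table (counted here, *without*
    deduplication) or pre-tabulated per-cohort count tables — the published
    per-cohort counts are valid inputs in place of patient-level events.
    Overall percentages are over all events, to one decimal.
    """
    if events is not None:
        df = _as_frame(events)
        grade_counts = (
            df.groupby("cohort")["grade"].value_counts().unstack(fill_value=0).sort_index()
        )
        relation_counts = (
            df.groupby("cohort")["relation"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=list(RELATION_CATEGORIES), fill_value=0)
            .sort_index()
        )
    if grade_counts is None or relation_counts is None:
        raise ValueError("provide either events or both count tables")
    n_events = int(grade_counts.to_numpy().sum())
    n_events_rel = int(relation_counts.to_numpy().sum())

    def _percent(tab: pd.DataFrame, total: int) -> pd.Series:
        return (100.0 * tab.sum(axis=0) / total).round(1)

    return {
        "grade_by_cohort": grade_counts,
        "relation_by_cohort": relation_counts,
        "grade_overall_percent": _percent(grade_counts, n_events),
        "relation_overall_percent": _percent(relation_counts, n_events_rel),
        "per_cohort_grade_percent": (
            100.0 * grade_counts.div(grade_counts.sum(axis=1), axis=0)
        ).round(1),
        "per_cohort_relation_percent": (
            100.0 * relation_counts.div(relation_counts.sum(axis=1), axis=0)
        ).round(1),
        "n_events": n_events,
    }


def classify_dlt(
    event: AdverseEvent,
    window_days: float = 28.0,
    attributable: Sequence[str] = ATTRIBUTABLE_DEFAULT,
    cns_persistence_h: float = 96.0,
) -> tuple[bool, str]:
    """Apply the protocol DLT definition to one event.

    DLT iff the event starts inside the evaluation window, is attributable,
    and is either (a) grade >= 3 CNS toxicity persisting >= 96 h, or (b)
    grade >= 3 non-CNS toxicity.  A CNS grade >= 3 event with no recorded
    resolution is treated as persisting (conservative).  Returns the flag
    and the clause that fired (or why not).
    """
    if event.onset_day > window_days:
        return False, f"onset day {event.onset_day:g} outside {window_days:g}-day window"
    if event.relation not in attributable:
        return False, f"relation '{event.relation}' not attributable"
    if event.grade < 3:
        return False, f"grade {event.grade} below DLT threshold"
    if not event.cns:
        return True, "grade >=3 attributable non-CNS toxicity"
    dur = event.duration_h
    if dur is None:
        return True, (
            f"grade >=3 attributable CNS toxicity with no recorded resolution; "
            f"treated as persisting >= {cns_persistence_h:g} h"
        )
    if dur >= cns_persistence_h:
        return True, f"grade >=3 attributable CNS toxicity persisting {dur:g} h >= {cns_persistence_h:g} h"
    return False, f"CNS toxicity resolved in {dur:g} h < {cns_persistence_h:g} h"


Decision = Literal["escalate", "expand", "stop_MTD_exceeded", "complete"]


def escalation_decision(state: EscalationState) -> Decision:
    """Canonical 3+3 decision at a completed cohort of 3 or 6.

    0/3 DLT -> escalate; 1/3 -> expand to 6; <=1/6 -> escalate; >=2 at
    either size -> stop (MTD exceeded).  DSMB sign-off is modeled as an
    external approval flag gating escalation.
    """
    if state.n_treated not in (3, 6):
        raise ValueError(
            f"3+3 decisions are taken at n=3 or n=6, not mid-cohort (n={state.n_treated})"
        )
    if state.n_dlt >= 2:
        return "stop_MTD_exceeded"
    if state.n_treated == 3:
        decision = "escalate" if state.n_dlt == 0 else "expand"
    else:
        decision = "escalate"
    if decision == "escalate" and not state.dsmb_approved:
        raise ValueError("escalation requires DSMB approval")
    return decision


def replay_escalation(history: Sequence[tuple[int, int, int]]) -> dict:
    """Replay a completed escalation: [(cohort_id, n_treated, n_dlt), ...].

    Returns the per-cohort decision log and whether an MTD was reached
    (i.e. any cohort stopped with >= 2 DLTs).
    """
    log = []
    mtd_exceeded_at = None
    for cohort_id, n_treated, n_dlt in history:
        decision = escalation_decision(EscalationState(cohort_id, n_treated, n_dlt))
        log.append({"cohort": cohort_id, "n_treated": n_treated, "n_dlt": n_dlt, "decision": decision})
        if decision == "stop_MTD_exceeded":
            mtd_exceeded_at = cohort_id
            break
    if mtd_exceeded_at is None and log:
        log[-1]["decision"] = "complete"
    return {"log": log, "mtd_reached": mtd_exceeded_at is not None, "stopped_at": mtd_exceeded_at}


def count_dlts(
    events: Iterable[AdverseEvent] | pd.DataFrame,
    window_days: float = 28.0,
) -> pd.DataFrame:
    """Per-cohort DLT counts from an event table."""
    df = _as_frame(events)
    flags = []
    for _, row in df.iterrows():
        ev = AdverseEvent(
            patient_id=row["patient_id"],
            term=row["term"],
            grade=int(row["grade"]),
            relation=row["relation"],
            cns=bool(row["cns"]),
            onset_day=float(row["onset_day"]),
            resolution_day=row.get("resolution_day"),
            cohort=int(row["cohort"]) if "cohort" in row else None,
        )
        flags.append(classify_dlt(ev, window_days=window_days)[0])
    df = df.assign(dlt=flags)
    per_patient = df.groupby(["cohort", "patient_id"])["dlt"].any().reset_index()
    return per_patient.groupby("cohort")["dlt"].sum().rename("n_dlt").to_frame()
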