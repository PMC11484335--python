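"""Hierarchical ARI case detection from coded clinical event streams.

The phenotyping core: filter a date-stamped event stream down to codes in
the level-1 ARI codelist, group events per patient, collapse repeat coding
of the same illness into single infection episodes with a 28-day
deduplication window, and assign each episode a level-3 indicator (and by
hierarchy its level-2 group).

Deduplication semantics
-----------------------
Default is a *rolling* window: an event opens a new case iff it falls
strictly more than ``window_days`` after the immediately preceding ARI
event of the same patient; a gap of exactly ``window_days`` therefore joins
the current episode. An alternative *fixed* mode anchors the window to the
episode's index (first) event instead, for sensitivity analysis.

Classification
--------------
An episode may contain events matching several level-3 indicators (a code
may also belong to more than one codelist, since the terminology is
polyhierarchical). The episode is assigned to the matched level-3 indicator
whose level-2 group ranks highest in a configurable priority order
(default ILI > ECLD > LRTI > URTI > ARI-NOS); within the winning group the
earliest-dated matching event decides, then the lexicographically smallest
level-3 id.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codelists import CANONICAL_LEVEL2_GROUPS, Codelist, IndicatorHierarchy

__all__ = [
    "ClinicalEvent",
    "AriCase",
    "DEFAULT_WINDOW_DAYS",
    "DEFAULT_LEVEL2_PRIORITY",
    "filter_ari_events",
    "deduplicate_to_cases",
    "classify_case",
    "detect_cases",
    "read_events_csv",
    "write_cases_csv",
    "cases_to_frame",
]

DEFAULT_WINDOW_DAYS = 28
DEFAULT_LEVEL2_PRIORITY: tuple[str, ...] = CANONICAL_LEVEL2_GROUPS


@dataclass(frozen=True, order=True)
class ClinicalEvent:
    """One date-stamped coded event from a patient's medical record."""

    patient_id: str
    practice_id: str
    date: dt.date
    code: str

    def __post_init__(self):
        if not self.code:
            raise ValueError("event code must be non-empty")
        if not isinstance(self.date, dt.date) or isinstance(self.date, dt.datetime):
            raise TypeError("event date must be a datetime.date")


@dataclass(frozen=True)
class AriCase:
    """A deduplicated infection episode with its indicator assignment."""

    patient_id: str
    practice_id: str
    index_date: dt.date
    level3: str
    level2: str
    n_events: int


def filter_ari_events(
    events: Iterable[ClinicalEvent], level1_codelist: Codelist
) -> list[ClinicalEvent]:
    """Keep only events whose code is in the level-1 codelist, order preserved."""
    return [e for e in events if e.code in level1_codelist]


def deduplicate_to_cases(
    patient_events: Sequence[ClinicalEvent],
    window_days: int = DEFAULT_WINDOW_DAYS,
    mode: str = "rolling",
) -> list[list[ClinicalEvent]]:
    """Collapse one patient's date-sorted ARI events into episodes.

    Parameters
    ----------
    patient_events
        Events for a single patient, sorted ascending by date.
    window_days
        Deduplication window; an event more than this many days beyond the
        reference event opens a new episode ("more than" is strict).
    mode
        ``"rolling"`` measures the gap from the immediately preceding event;
        ``"fixed"`` measures it from the episode's index (first) event.

    Returns
    -------
    list of episodes, each the list of its constituent events in order.
    """
    if mode not in ("rolling", "fixed"):
        raise ValueError(f"mode must be 'rolling' or 'fixed', got {mode!r}")
    events = list(patient_events)
    if not events:
        return []
    patients = {e.patient_id for e in events}
    if len(patients) > 1:
        raise ValueError(f"events span multiple patients: {sorted(patients)}")
    for prev, cur in zip(events, events[1:]):
        if cur.date < prev.date:
            raise ValueError("events must be sorted ascending by date")
    episodes: list[list[ClinicalEvent]] = [[events[0]]]
    for event in events[1:]:
        current = episodes[-1]
        anchor = current[-1] if mode == "rolling" else current[0]
        if (event.date - anchor.date).days > window_days:
            episodes.append([event])
        else:
            current.append(event)
    return episodes


def classify_case(
    case_events: Sequence[ClinicalEvent],
    codelists: Mapping[str, Codelist],
    hierarchy: IndicatorHierarchy,
    priority: Sequence[str] = DEFAULT_LEVEL2_PRIORITY,
) -> tuple[str, str]:
    """Assign an episode its (level-3, level-2) indicator pair.

    Every constituent event must match at least one level-3 codelist; an
    unmatched event indicates the episode was not filtered through the
    level-1 codelist and is an error.
    """
    rank = {g: i for i, g in enumerate(priority)}
    # level3 id -> earliest date of a matching event
    matched: dict[str, dt.date] = {}
    level3_lists = [(ind.id, codelists[ind.id]) for ind in hierarchy.level3]
    for event in case_events:
        hit = False
        for l3_id, cl in level3_lists:
            if event.code in cl:
                hit = True
                if l3_id not in matched or event.date < matched[l3_id]:
                    matched[l3_id] = event.date
        if not hit:
            raise ValueError(
                f"event code {event.code!r} matches no level-3 codelist "
                "(should have been filtered out)"
            )
    best = min(
        matched.items(),
        key=lambda kv: (rank[hierarchy.parent_of(kv[0])], kv[1], kv[0]),
    )
    level3 = best[0]
    return level3, hierarchy.parent_of(level3)


def _code_priority_rank(
    code: str,
    codelists: Mapping[str, Codelist],
    hierarchy: IndicatorHierarchy,
    rank: Mapping[str, int],
) -> int:
    # best (smallest) level-2 priority rank among the groups the code belongs to
    best = len(rank)
    for ind in hierarchy.level3:
        if code in codelists[ind.id]:
            best = min(best, rank[ind.level2_parent])
    return best


def detect_cases(
    events: Iterable[ClinicalEvent],
    codelists: Mapping[str, Codelist],
    hierarchy: IndicatorHierarchy,
    window_days: int = DEFAULT_WINDOW_DAYS,
    mode: str = "rolling",
    priority: Sequence[str] = DEFAULT_LEVEL2_PRIORITY,
) -> list[AriCase]:
    """Run the full phenotyping pipeline over an event stream.

    filter → group by patient → sort by date → deduplicate → classify.
    Same-day events are ordered deterministically by (date, level-2
    priority of the code's best group, code) and always share an episode.
    Output is sorted by (patient id, index date).
    """
    level1 = codelists[hierarchy.level1]
    rank = {g: i for i, g in enumerate(priority)}
    ari_events = filter_ari_events(events, level1)
    by_patient: dict[str, list[ClinicalEvent]] = {}
    for e in ari_events:
        by_patient.setdefault(e.patient_id, []).append(e)
    cases: list[AriCase] = []
    for patient_id in sorted(by_patient):
        pevents = sorted(
            by_patient[patient_id],
            key=lambda e: (
                e.date,
                _code_priority_rank(e.code, codelists, hierarchy, rank),
                e.code,
            ),
        )
        for episode in deduplicate_to_cases(pevents, window_days, mode):
            level3, level2 = classify_case(episode, codelists, hierarchy, priority)
            cases.append(
                AriCase(
                    patient_id=patient_id,
                    practice_id=episode[0].practice_id,
                    index_date=episode[0].date,
                    level3=level3,
                    level2=level2,
                    n_events=len(episode),
                )
            )
    cases.sort(key=lambda c: (c.patient_id, c.index_date))
    return cases


def detect_cases_flat(
    events: Iterable[ClinicalEvent],
    codelist: Codelist,
    window_days: int = DEFAULT_WINDOW_DAYS,
    mode: str = "rolling",
) -> list[AriCase]:
    """Run detection with a single flat codelist (legacy-algorithm style).

    No hierarchical classification is possible; every case carries the
    codelist's indicator id as both its level-3 and level-2 label.
    """
    matched = filter_ari_events(events, codelist)
    by_patient: dict[str, list[ClinicalEvent]] = {}
    for e in matched:
        by_patient.setdefault(e.patient_id, []).append(e)
    cases: list[AriCase] = []
    for patient_id in sorted(by_patient):
        pevents = sorted(by_patient[patient_id], key=lambda e: (e.date, e.code))
        for episode in deduplicate_to_cases(pevents, window_days, mode):
            cases.append(
                AriCase(
                    patient_id=patient_id,
                    practice_id=episode[0].practice_id,
                    index_date=episode[0].date,
                    level3=codelist.indicator_id,
                    level2=codelist.indicator_id,
                    n_events=len(episode),
                )
            )
    cases.sort(key=lambda c: (c.patient_id, c.index_date))
    return cases


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def read_events_csv(path: Path | str) -> list[ClinicalEvent]:
    """Read ``patient_id,practice_id,date,code`` CSV with ISO-8601 dates."""
    df = pd.read_csv(path, dtype={"patient_id": str, "practice_id": str, "code": str})
    required = {"patient_id", "practice_id", "date", "code"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events CSV missing columns: {sorted(missing)}")
    return [
        ClinicalEvent(
            patient_id=row.patient_id,
            practice_id=row.practice_id,
            date=dt.date.fromisoformat(row.date),
            code=row.code,
        )
        for row in df.itertuples()
    ]


def cases_to_frame(cases: Sequence[AriCase]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.patient_id, c.practice_id, c.index_date.isoformat(), c.level3, c.level2, c.n_events)
            for c in cases
        ],
        columns=["patient_id", "practice_id", "index_date", "level3", "level2", "n_events"],
    )


def write_cases_csv(cases: Sequence[AriCase], path: Path | str) -> None:
    cases_to_frame(cases).to_csv(path, index=False)


def read_cases_csv(path: Path | str) -> list[AriCase]:
    df = pd.read_csv(path, dtype={"patient_id": str, "practice_id": str})
    return [
        AriCase(
            patient_id=row.patient_id,
            practice_id=row.practice_id,
            index_date=dt.date.fromisoformat(row.index_date),
            level3=row.level3,
            level2=row.level2,
            n_events=int(row.n_events),
        )
        for row in df.itertuples()
    ]
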