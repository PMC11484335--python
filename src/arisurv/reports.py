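"""The three validation reports: codelist, case and weekly-rate comparison.

Each ``run_part*`` function is a pure computation returning a plain dict
(serialisable as JSON); the CLI layer handles files, manifests and exit
codes. The comparisons are between a legacy flat ("old") level-1 codelist
and the rule-based hierarchical ("new") algorithm run over the same event
stream and registers.

Case matching for Part 2: old and new case sets are keyed by
``(patient_id, index_date)``. Cases present in both are *shared*; new
cases without an old counterpart are *newly included*, old cases without a
new counterpart are *newly excluded*. By construction
``new_total = old_total + included − excluded`` holds exactly.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from typing import Mapping, Sequence

import pandas as pd

from .case_detection import (
    AriCase,
    ClinicalEvent,
    DEFAULT_LEVEL2_PRIORITY,
    DEFAULT_WINDOW_DAYS,
    detect_cases,
    detect_cases_flat,
    filter_ari_events,
)
from .codelists import (
    Codelist,
    IndicatorHierarchy,
    code_frequency_coverage,
    compare_codelists,
    resolve_codelists,
)
from .surveillance import (
    FlatIndicatorSet,
    SurveillancePeriod,
    WeeklyRateTable,
    median_weekly_rate,
    weekly_rates,
)
from .terminology import ConceptGraph
from .util import percent_change

__all__ = ["run_part1", "run_part2", "run_part3", "DataError"]


class DataError(RuntimeError):
    """Input data make the requested analysis impossible."""


def run_part1(
    old_codelist: Codelist,
    hierarchy: IndicatorHierarchy,
    graph: ConceptGraph,
) -> dict:
    """Codelist comparison: set analysis of old vs new level-1 codelists."""
    codelists = resolve_codelists(hierarchy, graph)
    new_level1 = codelists[hierarchy.level1]
    cmp = compare_codelists(old_codelist, new_level1)
    return {
        "comparison": cmp.to_dict(),
        "only_old": sorted(cmp.only_a),
        "only_new": sorted(cmp.only_b),
        "level2_sizes": {g: len(codelists[g]) for g in hierarchy.level2},
        "level1_size_new": len(new_level1),
        "level1_size_old": len(old_codelist),
    }


def _case_keys(cases: Sequence[AriCase]) -> set[tuple[str, dt.date]]:
    return {(c.patient_id, c.index_date) for c in cases}


def _index_code_counts(
    cases: Sequence[AriCase], events: Sequence[ClinicalEvent]
) -> dict[str, int]:
    # codes recorded on each case's index date (Figure-3-style frequency)
    by_patient_date: dict[tuple[str, dt.date], list[str]] = {}
    for e in events:
        by_patient_date.setdefault((e.patient_id, e.date), []).append(e.code)
    counter: Counter[str] = Counter()
    for c in cases:
        codes = by_patient_date.get((c.patient_id, c.index_date), [])
        if codes:
            counter[sorted(codes)[0]] += 1
    return dict(counter)


def run_part2(
    events: Sequence[ClinicalEvent],
    old_codelist: Codelist,
    hierarchy: IndicatorHierarchy,
    graph: ConceptGraph,
    window_days: int = DEFAULT_WINDOW_DAYS,
    mode: str = "rolling",
    priority: Sequence[str] = DEFAULT_LEVEL2_PRIORITY,
    coverage_threshold: float = 0.9,
) -> dict:
    """Case comparison: run both algorithms over one stream and reconcile."""
    codelists = resolve_codelists(hierarchy, graph)
    new_cases = detect_cases(events, codelists, hierarchy, window_days, mode, priority)
    old_cases = detect_cases_flat(events, old_codelist, window_days, mode)

    new_keys = _case_keys(new_cases)
    old_keys = _case_keys(old_cases)
    shared = new_keys & old_keys
    included_cases = [c for c in new_cases if (c.patient_id, c.index_date) not in shared]
    excluded_cases = [c for c in old_cases if (c.patient_id, c.index_date) not in shared]

    old_events = filter_ari_events(events, old_codelist)
    new_events = filter_ari_events(events, codelists[hierarchy.level1])
    old_counts = Counter(e.code for e in old_events)
    new_counts = Counter(e.code for e in new_events)

    def _coverage(counts: Counter) -> dict:
        if not counts:
            return {"k": 0, "covered_fraction": 0.0, "codes_used": 0}
        k, frac = code_frequency_coverage(counts, coverage_threshold)
        return {"k": k, "covered_fraction": frac, "codes_used": len(counts)}

    level2_totals = Counter(c.level2 for c in new_cases)
    report = {
        "old_total": len(old_cases),
        "new_total": len(new_cases),
        "shared": len(shared),
        "newly_included": len(included_cases),
        "newly_excluded": len(excluded_cases),
        "net_change": len(new_cases) - len(old_cases),
        "percent_change": (
            percent_change(len(old_cases), len(new_cases)) if old_cases else None
        ),
        "identity_holds": len(new_cases) - len(old_cases)
        == len(included_cases) - len(excluded_cases),
        "level2_case_totals": dict(sorted(level2_totals.items())),
        "code_frequency": {
            "old": dict(sorted(old_counts.items())),
            "new": dict(sorted(new_counts.items())),
            "included_index_codes": _index_code_counts(included_cases, new_events),
            "excluded_index_codes": _index_code_counts(excluded_cases, old_events),
        },
        "coverage": {
            "threshold": coverage_threshold,
            "old": _coverage(old_counts),
            "new": _coverage(new_counts),
        },
    }
    return report


def run_part3(
    old_cases: Sequence[AriCase],
    new_cases: Sequence[AriCase],
    practices: pd.DataFrame,
    patients: pd.DataFrame,
    hierarchy: IndicatorHierarchy,
    period: SurveillancePeriod,
    strata: Sequence[str] = ("all", "age", "risk"),
    max_relative_jump: float = 0.20,
    old_indicator_id: str = "ARI-OLD",
) -> dict:
    """Weekly-rate comparison on reliable-denominator practices only.

    Old (flat) rates are computed for the level-1 indicator; new rates for
    level 1 and every level-2 group. Medians and percent changes are
    reported overall and per stratum.
    """
    new_rates = weekly_rates(
        new_cases, practices, patients, hierarchy, period, strata, max_relative_jump
    )
    if not new_rates.included_practices:
        raise DataError("no practice passed the denominator reliability filter")
    old_rates = weekly_rates(
        old_cases,
        practices,
        patients,
        FlatIndicatorSet(old_indicator_id),
        period,
        strata,
        max_relative_jump,
    )

    strata_names = sorted(new_rates.table["stratum"].unique())
    summary: dict[str, dict] = {}
    for stratum in strata_names:
        new_med = median_weekly_rate(new_rates, hierarchy.level1, stratum)
        old_med = median_weekly_rate(old_rates, old_indicator_id, stratum)
        n_new = int(
            new_rates.table.loc[
                (new_rates.table["indicator"] == hierarchy.level1)
                & (new_rates.table["stratum"] == stratum),
                "cases",
            ].sum()
        )
        n_old = int(
            old_rates.table.loc[
                (old_rates.table["indicator"] == old_indicator_id)
                & (old_rates.table["stratum"] == stratum),
                "cases",
            ].sum()
        )
        summary[stratum] = {
            "old_cases": n_old,
            "new_cases": n_new,
            "additional_cases": n_new - n_old,
            "old_median_rate": old_med,
            "new_median_rate": new_med,
            "rate_percent_change": (
                percent_change(old_med, new_med) if old_med > 0 else None
            ),
        }
    level2_medians = {
        g: median_weekly_rate(new_rates, g, "all") for g in hierarchy.level2
    }
    return {
        "included_practices": sorted(new_rates.included_practices),
        "n_included_practices": len(new_rates.included_practices),
        "summary_by_stratum": summary,
        "new_level2_median_rates": level2_medians,
        "new_rate_table": new_rates.table.to_dict(orient="list"),
        "old_rate_table": old_rates.table.to_dict(orient="list"),
    }
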