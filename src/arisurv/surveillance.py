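"""Weekly stratified incidence rates for sentinel surveillance reporting.

Case counts from the phenotyping pipeline are converted into weekly rates
per 100,000 registered patients. Weeks follow ISO-8601 numbering (Monday
start; week 1 contains the year's first Thursday) and the default
surveillance year runs ISO week 39 of one year to ISO week 38 of the next
(52 weeks). Rates are stratified by three age bands (0–17, 18–69, 70+
completed years) and by a per-patient risk-group flag.

Practices without a dependable denominator are excluded before any rate is
computed: a practice is *reliable* over the reporting period iff it reports
a positive weekly list size for every week and its week-on-week relative
list-size change never exceeds a configurable jump threshold (default 20%).
This completeness-plus-bounded-jump rule is this package's own definition
of denominator quality, and both pieces are configurable.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .case_detection import AriCase
from .codelists import IndicatorHierarchy
from .util import percent_change, round_half_up

__all__ = [
    "AGE_BANDS",
    "SurveillancePeriod",
    "WeeklyRateTable",
    "iso_week_of",
    "age_band_of",
    "filter_reliable_practices",
    "weekly_rates",
    "median_weekly_rate",
    "percent_change",
    "read_practices_csv",
    "read_patients_csv",
]

logger = logging.getLogger(__name__)

AGE_BANDS: tuple[str, ...] = ("0-17", "18-69", "70+")
RISK_STRATA: tuple[str, ...] = ("risk", "no-risk")
ALL_STRATUM = "all"


def iso_week_of(date: dt.date) -> tuple[int, int]:
    """ISO-8601 (week-numbering year, week number) of a calendar date."""
    iso = date.isocalendar()
    return iso.year, iso.week


def age_band_of(date_of_birth: dt.date, reference_date: dt.date) -> str:
    """Age band from completed years at *reference_date*.

    The bands 0–17, 18–69 and 70+ partition all non-negative ages; band
    bounds are inclusive in completed years (an exact 18th birthday falls
    in 18–69).
    """
    if date_of_birth > reference_date:
        raise ValueError(
            f"date of birth {date_of_birth} is after reference date {reference_date}"
        )
    years = reference_date.year - date_of_birth.year
    if (reference_date.month, reference_date.day) < (
        date_of_birth.month,
        date_of_birth.day,
    ):
        years -= 1
    if years < 18:
        return "0-17"
    if years < 70:
        return "18-69"
    return "70+"


@dataclass(frozen=True)
class FlatIndicatorSet:
    """Duck-typed stand-in for a hierarchy when rating a flat codelist.

    Legacy single-level codelists have no level-2 groups; rate tables for
    them carry only the level-1 indicator.
    """

    level1: str
    level2: tuple[str, ...] = ()


@dataclass(frozen=True)
class SurveillancePeriod:
    """A run of consecutive ISO weeks, e.g. 2022-W39 .. 2023-W38."""

    start_year: int = 2022
    start_week: int = 39
    n_weeks: int = 52

    def __post_init__(self):
        if self.n_weeks < 1:
            raise ValueError("period must contain at least one week")
        # validates the (year, week) pair
        dt.date.fromisocalendar(self.start_year, self.start_week, 1)

    def weeks(self) -> list[tuple[int, int]]:
        """The period's (iso_year, iso_week) pairs, in order."""
        monday = dt.date.fromisocalendar(self.start_year, self.start_week, 1)
        out = []
        for _ in range(self.n_weeks):
            out.append(iso_week_of(monday))
            monday += dt.timedelta(days=7)
        return out

    def monday_of(self, iso_year: int, iso_week: int) -> dt.date:
        return dt.date.fromisocalendar(iso_year, iso_week, 1)

    @property
    def start_date(self) -> dt.date:
        return dt.date.fromisocalendar(self.start_year, self.start_week, 1)

    @property
    def end_date(self) -> dt.date:
        """Sunday of the final week."""
        return self.start_date + dt.timedelta(days=7 * self.n_weeks - 1)

    def __contains__(self, date: dt.date) -> bool:
        return self.start_date <= date <= self.end_date


def filter_reliable_practices(
    practices: pd.DataFrame,
    period: SurveillancePeriod,
    max_relative_jump: float = 0.20,
) -> frozenset[str]:
    """Practice ids with a dependable denominator over the whole period.

    *practices* is the weekly register, columns
    ``practice_id, iso_year, iso_week, list_size``. A practice qualifies
    iff it has a positive list size for every week of *period* and no
    week-on-week relative change above *max_relative_jump*.
    """
    weeks = period.weeks()
    if not weeks:
        raise ValueError("empty surveillance period")
    week_index = {wk: i for i, wk in enumerate(weeks)}
    reliable: set[str] = set()
    for practice_id, grp in practices.groupby("practice_id"):
        sizes: dict[int, float] = {}
        for row in grp.itertuples():
            wk = (int(row.iso_year), int(row.iso_week))
            if wk in week_index:
                sizes[week_index[wk]] = float(row.list_size)
        if len(sizes) < len(weeks):
            continue
        series = [sizes[i] for i in range(len(weeks))]
        if any(s <= 0 for s in series):
            continue
        jumps = [
            abs(b - a) / a for a, b in zip(series, series[1:])
        ]
        if any(j > max_relative_jump for j in jumps):
            continue
        reliable.add(str(practice_id))
    return frozenset(reliable)


@dataclass
class WeeklyRateTable:
    """Per-week, per-indicator, per-stratum counts, denominators and rates.

    ``table`` columns: ``iso_year, iso_week, indicator, stratum, cases,
    denominator, rate_per_100k`` (rate is NaN where the denominator is 0).
    """

    table: pd.DataFrame
    included_practices: frozenset[str] = field(default_factory=frozenset)
    n_dropped_cases: int = 0

    def to_csv(self, path: Path | str) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Path | str) -> "WeeklyRateTable":
        return cls(table=pd.read_csv(path))


def weekly_rates(
    cases: Sequence[AriCase],
    practices: pd.DataFrame,
    patients: pd.DataFrame,
    hierarchy: IndicatorHierarchy,
    period: SurveillancePeriod,
    strata: Sequence[str] = ("all", "age", "risk"),
    max_relative_jump: float = 0.20,
) -> WeeklyRateTable:
    """Weekly incidence rates per 100,000 for level-1 and level-2 indicators.

    Cases from practices failing the reliability filter are dropped, as are
    cases whose practice or patient is absent from the registers (counted
    and logged). Each retained case contributes to the level-1 indicator
    and to its level-2 group, in the ``all`` stratum, its age band (age at
    the case index date) and its risk-group stratum.

    Denominators: the ``all`` stratum uses the summed weekly list size of
    reliable practices; age/risk strata use patient counts from the patient
    register of those practices (age taken at each week's Monday).
    """
    included = filter_reliable_practices(practices, period, max_relative_jump)
    weeks = period.weeks()
    indicators = [hierarchy.level1] + list(hierarchy.level2)

    strata_names: list[str] = []
    if "all" in strata:
        strata_names.append(ALL_STRATUM)
    if "age" in strata:
        strata_names.extend(AGE_BANDS)
    if "risk" in strata:
        strata_names.extend(RISK_STRATA)

    pat = patients.copy()
    pat["patient_id"] = pat["patient_id"].astype(str)
    pat["practice_id"] = pat["practice_id"].astype(str)
    pat["dob"] = pat["dob"].map(
        lambda v: v if isinstance(v, dt.date) else dt.date.fromisoformat(str(v))
    )
    pat = pat[pat["practice_id"].isin(included)]
    dob_by_patient = dict(zip(pat["patient_id"], pat["dob"]))
    risk_by_patient = dict(zip(pat["patient_id"], pat["risk_group"].astype(bool)))

    # ---- denominators ----------------------------------------------------
    prac = practices.copy()
    prac["practice_id"] = prac["practice_id"].astype(str)
    list_size_by_week: dict[tuple[int, int], float] = {wk: 0.0 for wk in weeks}
    for row in prac.itertuples():
        wk = (int(row.iso_year), int(row.iso_week))
        if wk in list_size_by_week and row.practice_id in included:
            list_size_by_week[wk] += float(row.list_size)

    denom: dict[tuple[tuple[int, int], str], float] = {}
    dobs = pat["dob"].to_numpy()
    risks = pat["risk_group"].astype(bool).to_numpy()
    for wk in weeks:
        monday = period.monday_of(*wk)
        denom[(wk, ALL_STRATUM)] = list_size_by_week[wk]
        if len(pat):
            bands = np.array([age_band_of(d, monday) for d in dobs])
        else:
            bands = np.array([], dtype=str)
        for band in AGE_BANDS:
            denom[(wk, band)] = float((bands == band).sum())
        denom[(wk, "risk")] = float(risks.sum())
        denom[(wk, "no-risk")] = float((~risks).sum())

    # ---- case counts -----------------------------------------------------
    counts: dict[tuple[tuple[int, int], str, str], int] = {}
    n_dropped = 0
    for case in cases:
        if case.practice_id not in included:
            continue
        wk = iso_week_of(case.index_date)
        if wk not in list_size_by_week:
            continue
        dob = dob_by_patient.get(case.patient_id)
        if dob is None:
            n_dropped += 1
            continue
        case_strata = [ALL_STRATUM, age_band_of(dob, case.index_date)]
        case_strata.append("risk" if risk_by_patient[case.patient_id] else "no-risk")
        for indicator in dict.fromkeys((hierarchy.level1, case.level2)):
            for stratum in case_strata:
                key = (wk, indicator, stratum)
                counts[key] = counts.get(key, 0) + 1
    if n_dropped:
        logger.warning(
            "dropped %d cases whose patient is absent from the register", n_dropped
        )

    rows = []
    for wk in weeks:
        for indicator in indicators:
            for stratum in strata_names:
                n = counts.get((wk, indicator, stratum), 0)
                d = denom[(wk, stratum)]
                rate = 100000.0 * n / d if d > 0 else np.nan
                rows.append((wk[0], wk[1], indicator, stratum, n, d, rate))
    table = pd.DataFrame(
        rows,
        columns=[
            "iso_year",
            "iso_week",
            "indicator",
            "stratum",
            "cases",
            "denominator",
            "rate_per_100k",
        ],
    )
    return WeeklyRateTable(
        table=table, included_practices=included, n_dropped_cases=n_dropped
    )


def median_weekly_rate(
    table: WeeklyRateTable | pd.DataFrame,
    indicator: str,
    stratum: str = ALL_STRATUM,
) -> float:
    """Median of the weekly rates for one indicator/stratum, one decimal.

    With an even number of weeks the mean of the two central values is
    taken; rounding is half-up, applied only to the returned value.
    """
    df = table.table if isinstance(table, WeeklyRateTable) else table
    rates = df.loc[
        (df["indicator"] == indicator) & (df["stratum"] == stratum), "rate_per_100k"
    ].dropna()
    if rates.empty:
        raise ValueError(
            f"no rate rows for indicator={indicator!r}, stratum={stratum!r}"
        )
    return round_half_up(float(np.median(rates.to_numpy())), 1)


# ---------------------------------------------------------------------------
# register CSVs
# ---------------------------------------------------------------------------


def read_practices_csv(path: Path | str) -> pd.DataFrame:
    """``practice_id,iso_year,iso_week,list_size`` weekly register."""
    df = pd.read_csv(path, dtype={"practice_id": str})
    missing = {"practice_id", "iso_year", "iso_week", "list_size"} - set(df.columns)
    if missing:
        raise ValueError(f"practices CSV missing columns: {sorted(missing)}")
    return df


def read_patients_csv(path: Path | str) -> pd.DataFrame:
    """``patient_id,practice_id,dob,risk_group`` patient register."""
    df = pd.read_csv(path, dtype={"patient_id": str, "practice_id": str})
    missing = {"patient_id", "practice_id", "dob", "risk_group"} - set(df.columns)
    if missing:
        raise ValueError(f"patients CSV missing columns: {sorted(missing)}")
    return df
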