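"""Synthetic terminology, population and event-stream generator.

Real sentinel-network medical records cannot be redistributed, so every
stage of the toolkit is exercised against generated data with known ground
truth. The generator emits:

* a small polyhierarchical respiratory terminology (~150 concepts, some
  with two parents) supporting all 16 level-3 ECL rules, plus *decoy*
  concepts — chronic, recurrent, non-infective and other non-ARI codes
  that a legacy extensional codelist would sweep in but the rule-based
  codelists exclude;
* a legacy ("old-style") flat level-1 codelist: the union of the resolved
  ILI/LRTI/URTI codes plus all decoy codes (mirroring a system whose old
  ARI list was the combination of its ILI, LRTI and URTI lists and which
  had no ECLD or ARI-NOS indicators);
* practice registers with weekly list sizes and per-patient demographics;
* a seasonal coded event stream: per-patient infection episodes drawn from
  a baseline-plus-winter-peak weekly intensity per level-2 indicator, each
  episode emitting one or more codings (geometric repeat count, uniform
  1–21 day gaps, so repeats stay inside a 28-day rolling window), plus
  independently injected decoy miscodes.

Episode onsets are separated by a floor gap (strictly more than the
deduplication window after the previous episode's last event) and decoy
events are kept clear of all true events, so the ground-truth episode
table maps one-to-one onto detectable cases when no miscoding is enabled,
and decoy-only legacy cases are exactly countable.

All randomness flows from one seeded :class:`numpy.random.Generator`;
identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .case_detection import ClinicalEvent
from .codelists import (
    CANONICAL_LEVEL2_GROUPS,
    Codelist,
    IndicatorHierarchy,
    Level3Indicator,
    resolve_codelists,
    write_codelists_csv,
)
from .surveillance import SurveillancePeriod
from .terminology import Concept, ConceptGraph, write_terminology

__all__ = [
    "SeasonalCurve",
    "SimulationConfig",
    "SyntheticTerminology",
    "generate_terminology",
    "generate_population",
    "generate_events",
    "simulate_to_dir",
]

DECOY_CLASSES = ("chronic", "non-infective", "recurrent", "other")
#: Share of injected miscodes per decoy class (chronic disease dominates,
#: then non-infective, recurrent and other non-ARI conditions).
DECOY_CLASS_WEIGHTS = (0.437, 0.300, 0.144, 0.119)


class SeasonalCurve(BaseModel):
    """Weekly intensity: baseline plus a Gaussian-shaped winter peak.

    rate(w) = baseline · (1 + (peak_multiplier − 1) ·
              exp(−(w − peak_week)² / (2 · peak_width²)))
    in cases per 100,000 registered patients per week; *w* is the 0-based
    week index within the surveillance period.
    """

    baseline_per_100k: float = Field(ge=0)
    peak_multiplier: float = Field(default=3.0, ge=1)
    peak_week: float = 15.0
    peak_width_weeks: float = Field(default=5.0, gt=0)

    def rate(self, week_index: int) -> float:
        bump = (self.peak_multiplier - 1.0) * float(
            np.exp(-((week_index - self.peak_week) ** 2) / (2 * self.peak_width_weeks**2))
        )
        return self.baseline_per_100k * (1.0 + bump)


def _default_curves() -> dict[str, SeasonalCurve]:
    # Baselines chosen so season medians land near typical English
    # primary-care ARI surveillance levels (URTI ~150/100k/week, LRTI ~80,
    # ECLD ~12, ILI ~3); winter peak centred mid-season (around ISO week 1).
    return {
        "URTI": SeasonalCurve(baseline_per_100k=140, peak_multiplier=3.0, peak_week=15, peak_width_weeks=5),
        "LRTI": SeasonalCurve(baseline_per_100k=67, peak_multiplier=3.0, peak_week=16, peak_width_weeks=5),
        "ILI": SeasonalCurve(baseline_per_100k=3, peak_multiplier=4.0, peak_week=14, peak_width_weeks=3),
        "ECLD": SeasonalCurve(baseline_per_100k=12, peak_multiplier=2.5, peak_week=16, peak_width_weeks=6),
        "ARI-NOS": SeasonalCurve(baseline_per_100k=20, peak_multiplier=2.5, peak_week=15, peak_width_weeks=5),
    }


class SimulationConfig(BaseModel):
    """All knobs of the generator; every random draw is governed by *seed*."""

    seed: int = 1
    n_practices: int = Field(default=20, ge=1)
    patients_per_practice: int = Field(default=500, ge=1)
    start_year: int = 2022
    start_week: int = 39
    n_weeks: int = Field(default=52, ge=1)
    level2_curves: dict[str, SeasonalCurve] = Field(default_factory=_default_curves)
    #: probability of emitting each successive repeat coding (geometric).
    repeat_coding_prob: float = Field(default=0.4, ge=0, lt=1)
    repeat_gap_min_days: int = Field(default=1, ge=1)
    repeat_gap_max_days: int = Field(default=21, ge=1)
    max_repeat_codings: int = Field(default=5, ge=0)
    #: per patient-week probability of an injected decoy miscode.
    miscode_weekly_prob: float = Field(default=0.001, ge=0, le=1)
    #: share of patients per age band 0-17 / 18-69 / 70+.
    age_band_weights: tuple[float, float, float] = (0.21, 0.65, 0.14)
    risk_group_prevalence: float = Field(default=0.25, ge=0, le=1)
    #: probability a practice drops register weeks (failing reliability).
    practice_dropout_prob: float = Field(default=0.1, ge=0, le=1)
    dedup_window_days: int = Field(default=28, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if set(self.level2_curves) != set(CANONICAL_LEVEL2_GROUPS):
            raise ValueError(
                f"level2_curves must cover exactly {CANONICAL_LEVEL2_GROUPS}"
            )
        if self.repeat_gap_max_days < self.repeat_gap_min_days:
            raise ValueError("repeat gap max must be >= min")
        if abs(sum(self.age_band_weights) - 1.0) > 1e-9:
            raise ValueError("age band weights must sum to 1")
        return self

    @property
    def period(self) -> SurveillancePeriod:
        return SurveillancePeriod(self.start_year, self.start_week, self.n_weeks)

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Path | str) -> "SimulationConfig":
        return cls.model_validate_json(Path(path).read_text())


@dataclass
class SyntheticTerminology:
    """Generated terminology bundle with ground-truth bookkeeping."""

    graph: ConceptGraph
    hierarchy: IndicatorHierarchy
    codelists: dict[str, Codelist]  # resolved new-algorithm codelists
    old_codelist: Codelist  # legacy flat level-1 list (includes decoys)
    decoy_codes: dict[str, frozenset[str]]  # decoy class -> codes
    code_weights: dict[str, list[tuple[str, float]]]  # level3 -> (code, w)

    @property
    def all_decoy_codes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for codes in self.decoy_codes.values():
            out |= codes
        return out


# level-3 indicator ids per level-2 group (1/3/4/6/2 split, 16 in total)
_LEVEL3_PLAN: dict[str, list[str]] = {
    "ILI": ["ili"],
    "ECLD": ["ecld-asthma", "ecld-copd", "ecld-bronchiectasis"],
    "LRTI": ["lrti-pneumonia", "lrti-acute-bronchitis", "lrti-bronchiolitis", "lrti-nos"],
    "URTI": [
        "urti-common-cold",
        "urti-pharyngitis",
        "urti-sinusitis",
        "urti-otitis-media",
        "urti-laryngitis",
        "urti-nos",
    ],
    "ARI-NOS": ["ari-nos-unspecified", "ari-covid-suspected"],
}

# decoy clusters: (cluster id, decoy class, host level-3 indicator)
_DECOY_PLAN: list[tuple[str, str, str]] = [
    ("chronic-bronchitis", "chronic", "lrti-acute-bronchitis"),
    ("chronic-sinusitis", "chronic", "urti-sinusitis"),
    ("allergic-rhinitis", "non-infective", "urti-common-cold"),
    ("recurrent-tonsillitis", "recurrent", "urti-pharyngitis"),
    ("pneumoconiosis", "other", "lrti-pneumonia"),
    ("non-infective-laryngitis", "non-infective", "urti-laryngitis"),
]


def generate_terminology(config: SimulationConfig) -> SyntheticTerminology:
    """Build the synthetic respiratory terminology and indicator hierarchy.

    Each level-3 indicator gets a subtree root plus a seeded number of
    descendant concepts (two levels deep in places); a handful of concepts
    receive a second parent to exercise the polyhierarchy. Decoy clusters
    are grafted *inside* host subtrees and carved back out of the level-3
    codelists with ``MINUS`` rules, so the legacy flat list (host subtree
    unions plus decoys) over-selects exactly the decoy codes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0DE]))
    graph = ConceptGraph()
    graph.add_concept(Concept("resp-disorder", "Disorder of respiratory system"))

    decoy_host: dict[str, list[str]] = {}
    for cluster, _cls, host in _DECOY_PLAN:
        decoy_host.setdefault(host, []).append(cluster)

    level3_codes: dict[str, list[str]] = {}
    decoy_codes: dict[str, set[str]] = {cls: set() for cls in DECOY_CLASSES}
    indicators: list[Level3Indicator] = []

    for group in CANONICAL_LEVEL2_GROUPS:
        group_root = f"{group.lower()}-group"
        graph.add_concept(Concept(group_root, f"{group} (disorder group)"))
        graph.add_edge(group_root, "resp-disorder")
        for l3 in _LEVEL3_PLAN[group]:
            root = f"{l3}-root"
            graph.add_concept(Concept(root, l3.replace("-", " ")))
            graph.add_edge(root, group_root)
            members = [root]
            n_children = int(rng.integers(3, 8))
            for i in range(1, n_children + 1):
                code = f"{l3}-{i:02d}"
                graph.add_concept(Concept(code, f"{l3.replace('-', ' ')} variant {i}"))
                graph.add_edge(code, root)
                members.append(code)
                # occasionally a grandchild
                if rng.random() < 0.3:
                    sub = f"{code}-a"
                    graph.add_concept(Concept(sub, f"{l3.replace('-', ' ')} variant {i}a"))
                    graph.add_edge(sub, code)
                    members.append(sub)
            rule = f"<<{root}"
            for cluster in decoy_host.get(l3, []):
                cls = next(c for (cid, c, _h) in _DECOY_PLAN if cid == cluster)
                croot = f"{cluster}-root"
                graph.add_concept(Concept(croot, cluster.replace("-", " ")))
                graph.add_edge(croot, root)
                cluster_codes = [croot]
                for j in range(1, int(rng.integers(2, 4)) + 1):
                    ccode = f"{cluster}-{j:02d}"
                    graph.add_concept(
                        Concept(ccode, f"{cluster.replace('-', ' ')} variant {j}")
                    )
                    graph.add_edge(ccode, croot)
                    cluster_codes.append(ccode)
                decoy_codes[cls].update(cluster_codes)
                rule = f"({rule} MINUS <<{croot})"
            level3_codes[l3] = members
            indicators.append(Level3Indicator(id=l3, level2_parent=group, ecl=rule))

    # polyhierarchy: give some non-root, non-decoy concepts a second parent
    # in another level-3 subtree (possibly under a different level-2 group).
    # Cross edges stay within the legacy-visible family (ILI/LRTI/URTI) or
    # the legacy-invisible one (ECLD/ARI-NOS) so a code's membership of the
    # legacy flat list is never changed by its second parent.
    group_of_l3 = {ind.id: ind.level2_parent for ind in indicators}
    legacy_visible = {"ILI", "LRTI", "URTI"}
    l3_ids = [ind.id for ind in indicators]
    candidates = sorted(
        (c, l3)
        for l3, members in level3_codes.items()
        for c in members
        if not c.endswith("-root")
    )
    for _ in range(8):
        child, child_l3 = candidates[int(rng.integers(len(candidates)))]
        other = l3_ids[int(rng.integers(len(l3_ids)))]
        target_root = f"{other}-root"
        if child.startswith(other) or (child, target_root) in graph.is_a_edges:
            continue
        if (group_of_l3[child_l3] in legacy_visible) != (
            group_of_l3[other] in legacy_visible
        ):
            continue
        try:
            graph.add_edge(child, target_root)
        except ValueError:
            continue  # would create a cycle; skip

    hierarchy = IndicatorHierarchy(
        level2=list(CANONICAL_LEVEL2_GROUPS), level3=indicators
    )
    hierarchy.validate_canonical()
    codelists = resolve_codelists(hierarchy, graph)

    # legacy flat list: resolved ILI+LRTI+URTI codes, plus every decoy code
    old_codes = (
        codelists["ILI"].codes | codelists["LRTI"].codes | codelists["URTI"].codes
    )
    for cls in DECOY_CLASSES:
        old_codes |= frozenset(decoy_codes[cls])
    old_codelist = Codelist("ARI-OLD", 1, frozenset(old_codes))

    # Zipf-like recording weights per level-3 list so that a few codes
    # dominate event recording (as real coding behaviour does).
    code_weights: dict[str, list[tuple[str, float]]] = {}
    for ind in indicators:
        ranked = sorted(codelists[ind.id].codes)
        rng.shuffle(ranked)
        weights = np.array([1.0 / (r + 1) ** 1.6 for r in range(len(ranked))])
        weights /= weights.sum()
        code_weights[ind.id] = list(zip(ranked, weights.tolist()))

    return SyntheticTerminology(
        graph=graph,
        hierarchy=hierarchy,
        codelists=codelists,
        old_codelist=old_codelist,
        decoy_codes={cls: frozenset(v) for cls, v in decoy_codes.items()},
        code_weights=code_weights,
    )


def generate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate weekly practice registers and a patient register.

    List sizes are constant per practice; a seeded fraction of practices
    drop one or more register weeks to exercise the reliability filter.
    Returns ``(practices, patients)`` data frames in the register CSV
    schemas.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB10C]))
    period = config.period
    weeks = period.weeks()
    ref = period.start_date

    practice_ids = [f"PR{i:03d}" for i in range(1, config.n_practices + 1)]
    patient_rows = []
    bands = ((0, 17), (18, 69), (70, 95))
    pid = 0
    for practice in practice_ids:
        for _ in range(config.patients_per_practice):
            pid += 1
            band = int(rng.choice(3, p=list(config.age_band_weights)))
            lo, hi = bands[band]
            age_days = int(rng.integers(lo * 365, (hi + 1) * 365))
            dob = ref - dt.timedelta(days=age_days)
            risk = bool(rng.random() < config.risk_group_prevalence)
            patient_rows.append((f"P{pid:06d}", practice, dob.isoformat(), risk))
    patients = pd.DataFrame(
        patient_rows, columns=["patient_id", "practice_id", "dob", "risk_group"]
    )

    practice_rows = []
    for practice in practice_ids:
        dropped: set[int] = set()
        if rng.random() < config.practice_dropout_prob:
            n_drop = int(rng.integers(1, 4))
            dropped = set(rng.choice(len(weeks), size=n_drop, replace=False).tolist())
        for i, (iso_year, iso_week) in enumerate(weeks):
            if i in dropped:
                continue
            practice_rows.append(
                (practice, iso_year, iso_week, config.patients_per_practice)
            )
    practices = pd.DataFrame(
        practice_rows, columns=["practice_id", "iso_year", "iso_week", "list_size"]
    )
    return practices, patients


def _weighted_code(rng: np.random.Generator, weighted: list[tuple[str, float]]) -> str:
    codes = [c for c, _ in weighted]
    probs = np.array([w for _, w in weighted])
    return codes[int(rng.choice(len(codes), p=probs / probs.sum()))]


def generate_events(
    config: SimulationConfig,
    terminology: SyntheticTerminology,
    patients: pd.DataFrame,
) -> tuple[list[ClinicalEvent], pd.DataFrame, pd.DataFrame]:
    """Generate the coded event stream with ground truth.

    Returns ``(events, true_episodes, decoy_events)``. ``true_episodes``
    has one row per genuine infection episode (patient, practice, onset
    date, level-2/3 label, event count); ``decoy_events`` one row per
    injected miscode. Episodes never overlap the deduplication window of
    the previous episode, and decoys are kept more than a window plus the
    maximum repeat gap away from every true event, so detection recovers
    the episode table exactly when miscoding is disabled and every decoy
    forms its own legacy-only case.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE4E7]))
    period = config.period
    weeks = period.weeks()
    mondays = [period.monday_of(*wk) for wk in weeks]
    hierarchy = terminology.hierarchy
    children = {g: [ind.id for ind in hierarchy.children_of(g)] for g in hierarchy.level2}
    groups = list(hierarchy.level2)

    # weekly per-patient onset probabilities per level-2 group
    p_week = np.array(
        [
            [config.level2_curves[g].rate(w) / 100000.0 for g in groups]
            for w in range(len(weeks))
        ]
    )
    p_total = p_week.sum(axis=1)

    guard = config.dedup_window_days + config.repeat_gap_max_days + 2

    events: list[ClinicalEvent] = []
    episode_rows = []
    decoy_rows = []
    decoy_classes = [cls for cls in DECOY_CLASSES if terminology.decoy_codes[cls]]
    decoy_weights = np.array(
        [DECOY_CLASS_WEIGHTS[DECOY_CLASSES.index(cls)] for cls in decoy_classes]
    )
    decoy_weights = decoy_weights / decoy_weights.sum() if len(decoy_classes) else decoy_weights
    decoy_pool = {cls: sorted(terminology.decoy_codes[cls]) for cls in decoy_classes}

    for row in patients.sort_values("patient_id").itertuples():
        patient_id, practice_id = row.patient_id, row.practice_id
        true_dates: list[dt.date] = []
        next_allowed = dt.date.min
        for w, monday in enumerate(mondays):
            if p_total[w] <= 0:
                continue
            if rng.random() >= p_total[w]:
                continue
            onset = monday + dt.timedelta(days=int(rng.integers(0, 7)))
            if onset < next_allowed:
                continue
            group = groups[int(rng.choice(len(groups), p=p_week[w] / p_total[w]))]
            level3 = children[group][int(rng.integers(len(children[group])))]
            date = onset
            ep_dates = [date]
            events.append(
                ClinicalEvent(
                    patient_id,
                    practice_id,
                    date,
                    _weighted_code(rng, terminology.code_weights[level3]),
                )
            )
            n_extra = 0
            while (
                n_extra < config.max_repeat_codings
                and rng.random() < config.repeat_coding_prob
            ):
                gap = int(
                    rng.integers(
                        config.repeat_gap_min_days, config.repeat_gap_max_days + 1
                    )
                )
                date = date + dt.timedelta(days=gap)
                events.append(
                    ClinicalEvent(
                        patient_id,
                        practice_id,
                        date,
                        _weighted_code(rng, terminology.code_weights[level3]),
                    )
                )
                ep_dates.append(date)
                n_extra += 1
            true_dates.extend(ep_dates)
            episode_rows.append(
                (
                    patient_id,
                    practice_id,
                    onset.isoformat(),
                    hierarchy.parent_of(level3),
                    level3,
                    1 + n_extra,
                )
            )
            # next onset must be strictly outside the rolling window of the
            # last coding of this episode
            next_allowed = date + dt.timedelta(days=config.dedup_window_days + 1)

        if config.miscode_weekly_prob > 0 and decoy_classes:
            decoy_dates: list[dt.date] = []
            for monday in mondays:
                if rng.random() >= config.miscode_weekly_prob:
                    continue
                date = monday + dt.timedelta(days=int(rng.integers(0, 7)))
                if any(abs((date - d).days) <= guard for d in true_dates):
                    continue
                if any(abs((date - d).days) <= guard for d in decoy_dates):
                    continue
                cls = decoy_classes[int(rng.choice(len(decoy_classes), p=decoy_weights))]
                pool = decoy_pool[cls]
                code = pool[int(rng.integers(len(pool)))]
                events.append(ClinicalEvent(patient_id, practice_id, date, code))
                decoy_dates.append(date)
                decoy_rows.append(
                    (patient_id, practice_id, date.isoformat(), code, cls)
                )

    events.sort(key=lambda e: (e.patient_id, e.date, e.code))
    true_episodes = pd.DataFrame(
        episode_rows,
        columns=["patient_id", "practice_id", "onset_date", "level2", "level3", "n_events"],
    )
    decoy_events = pd.DataFrame(
        decoy_rows,
        columns=["patient_id", "practice_id", "date", "code", "decoy_class"],
    )
    return events, true_episodes, decoy_events


def simulate_to_dir(config: SimulationConfig, outdir: Path | str) -> dict[str, str]:
    """Run the full generator and write all artefacts as CSV/JSON.

    Writes terminology (concepts/edges), indicator definitions, resolved
    codelists, the legacy codelist, registers, the event stream and both
    ground-truth tables, plus a manifest with a SHA-256 per file. Returns
    the manifest mapping (filename → digest).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    term = generate_terminology(config)
    practices, patients = generate_population(config)
    events, true_episodes, decoys = generate_events(config, term, patients)

    write_terminology(term.graph, outdir / "concepts.csv", outdir / "edges.csv")
    term.hierarchy.to_json(outdir / "indicators.json")
    write_codelists_csv(term.codelists, term.graph, outdir / "codelists.csv")
    pd.DataFrame(
        sorted(term.old_codelist.codes), columns=["code"]
    ).to_csv(outdir / "old_codelist.csv", index=False)
    practices.to_csv(outdir / "practices.csv", index=False)
    patients.to_csv(outdir / "patients.csv", index=False)
    pd.DataFrame(
        [
            (e.patient_id, e.practice_id, e.date.isoformat(), e.code)
            for e in events
        ],
        columns=["patient_id", "practice_id", "date", "code"],
    ).to_csv(outdir / "events.csv", index=False)
    true_episodes.to_csv(outdir / "true_episodes.csv", index=False)
    decoys.to_csv(outdir / "decoy_events.csv", index=False)
    config.to_json(outdir / "sim_config.json")

    manifest = {}
    for name in sorted(p.name for p in outdir.iterdir() if p.suffix in (".csv", ".json")):
        if name == "manifest.json":
            continue
        manifest[name] = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
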