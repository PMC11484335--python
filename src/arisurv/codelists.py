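"""The three-level ARI indicator hierarchy and codelist operations.

The acute respiratory infection (ARI) indicator is modelled hierarchically:
level 1 is ARI itself; level 2 comprises five surveillance groups —
influenza-like illness (ILI), exacerbation of chronic lung disease (ECLD),
lower and upper respiratory tract infection (LRTI, URTI) and a residual
"ARI not otherwise specified" (ARI-NOS) group; each level-2 group contains
one or more level-3 indicators, and each level-3 indicator carries an ECL
rule that resolves to a concrete codelist against a terminology graph.
Level-2 and level-1 codelists are unions of their children — they are never
authored directly.

This module also provides the validation set-analysis between two
codelists and the code-frequency coverage statistic ("how many codes
account for X% of recorded events").
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .terminology import ConceptGraph, evaluate_ecl, parse_ecl
from .util import percent_change as _percent_change

__all__ = [
    "CANONICAL_LEVEL2_GROUPS",
    "CANONICAL_LEVEL3_SPLIT",
    "Level3Indicator",
    "IndicatorHierarchy",
    "Codelist",
    "CodelistComparison",
    "resolve_codelists",
    "compare_codelists",
    "code_frequency_coverage",
    "write_codelists_csv",
]

LEVEL1_ID = "ARI"

#: The five level-2 surveillance groups, in default reporting order.
CANONICAL_LEVEL2_GROUPS: tuple[str, ...] = ("ILI", "ECLD", "LRTI", "URTI", "ARI-NOS")

#: Canonical number of level-3 indicators per level-2 group (16 in total).
CANONICAL_LEVEL3_SPLIT: dict[str, int] = {
    "ILI": 1,
    "ECLD": 3,
    "LRTI": 4,
    "URTI": 6,
    "ARI-NOS": 2,
}


class Level3Indicator(BaseModel):
    """A level-3 indicator: id, parent level-2 group, and its ECL rule."""

    id: str
    level2_parent: str
    ecl: str

    @field_validator("id", "level2_parent", "ecl")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("must be non-empty")
        return v


class IndicatorHierarchy(BaseModel):
    """The 3-level indicator model binding level-3 indicators to ECL rules.

    Structural invariants (checked on construction): level-3 ids are unique,
    every level-3 names a declared level-2 parent, and every level-2 group
    has at least one child. :meth:`validate_canonical` additionally checks
    the canonical shape (16 level-3 indicators split 1/3/4/6/2).
    """

    level1: str = LEVEL1_ID
    level2: Sequence[str] = Field(default=CANONICAL_LEVEL2_GROUPS)
    level3: Sequence[Level3Indicator]

    @model_validator(mode="after")
    def _check_structure(self) -> "IndicatorHierarchy":
        ids = [ind.id for ind in self.level3]
        if len(set(ids)) != len(ids):
            raise ValueError("level-3 indicator ids must be unique")
        if len(set(self.level2)) != len(self.level2):
            raise ValueError("level-2 group ids must be unique")
        groups = set(self.level2)
        for ind in self.level3:
            if ind.level2_parent not in groups:
                raise ValueError(
                    f"level-3 {ind.id!r} names unknown level-2 parent "
                    f"{ind.level2_parent!r}"
                )
        childless = groups - {ind.level2_parent for ind in self.level3}
        if childless:
            raise ValueError(f"level-2 groups without children: {sorted(childless)}")
        return self

    def validate_canonical(self) -> None:
        """Require the canonical 16-indicator, 1/3/4/6/2 shape."""
        split = {g: 0 for g in self.level2}
        for ind in self.level3:
            split[ind.level2_parent] += 1
        if tuple(self.level2) != CANONICAL_LEVEL2_GROUPS or split != CANONICAL_LEVEL3_SPLIT:
            raise ValueError(
                f"hierarchy is not canonical: groups={tuple(self.level2)}, split={split}"
            )

    def children_of(self, level2_id: str) -> list[Level3Indicator]:
        return [ind for ind in self.level3 if ind.level2_parent == level2_id]

    def parent_of(self, level3_id: str) -> str:
        for ind in self.level3:
            if ind.id == level3_id:
                return ind.level2_parent
        raise KeyError(f"unknown level-3 indicator {level3_id!r}")

    # -- JSON interchange --------------------------------------------------
    def to_json(self, path: Path | str) -> None:
        payload = {
            "level1": self.level1,
            "level2_groups": list(self.level2),
            "indicators": [ind.model_dump() for ind in self.level3],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Path | str) -> "IndicatorHierarchy":
        payload = json.loads(Path(path).read_text())
        return cls(
            level1=payload.get("level1", LEVEL1_ID),
            level2=payload["level2_groups"],
            level3=[Level3Indicator(**d) for d in payload["indicators"]],
        )


@dataclass(frozen=True)
class Codelist:
    """A resolved set of concept codes for one indicator."""

    indicator_id: str
    level: int
    codes: frozenset[str]

    def __post_init__(self):
        if self.level not in (1, 2, 3):
            raise ValueError(f"level must be 1, 2 or 3, got {self.level}")

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __len__(self) -> int:
        return len(self.codes)


def resolve_codelists(
    hierarchy: IndicatorHierarchy, graph: ConceptGraph
) -> dict[str, Codelist]:
    """Resolve every indicator in the hierarchy to a concrete codelist.

    Level-3 codelists come from evaluating each indicator's ECL rule
    against *graph*; level-2 codelists are the union of their children and
    the level-1 codelist the union of all level-3 lists. Deterministic.

    Raises
    ------
    ValueError
        If a rule fails to parse or references an unknown code; the message
        names the offending indicator.
    """
    resolved: dict[str, Codelist] = {}
    for ind in hierarchy.level3:
        try:
            codes = evaluate_ecl(graph, parse_ecl(ind.ecl))
        except Exception as exc:
            raise ValueError(
                f"cannot resolve rule for indicator {ind.id!r}: {exc}"
            ) from exc
        resolved[ind.id] = Codelist(ind.id, 3, codes)
    for group in hierarchy.level2:
        union: frozenset[str] = frozenset()
        for child in hierarchy.children_of(group):
            union |= resolved[child.id].codes
        resolved[group] = Codelist(group, 2, union)
    level1 = frozenset().union(
        *(resolved[ind.id].codes for ind in hierarchy.level3)
    )
    resolved[hierarchy.level1] = Codelist(hierarchy.level1, 1, level1)
    return resolved


@dataclass(frozen=True)
class CodelistComparison:
    """Set analysis of two codelists (the Part-1 validation report)."""

    size_a: int
    size_b: int
    intersection: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    percent_change: float | None  # None iff size_a == 0 (undefined, flagged)

    @property
    def undefined_change(self) -> bool:
        return self.percent_change is None

    def to_dict(self) -> dict:
        return {
            "size_a": self.size_a,
            "size_b": self.size_b,
            "n_intersection": len(self.intersection),
            "n_only_a": len(self.only_a),
            "n_only_b": len(self.only_b),
            "percent_change": self.percent_change,
        }


def compare_codelists(a: Codelist, b: Codelist) -> CodelistComparison:
    """Exact set arithmetic between two codelists.

    ``percent_change`` is the signed change from *a* to *b* in one-decimal
    half-up rounding; it is ``None`` (flagged undefined) when *a* is empty.
    """
    inter = a.codes & b.codes
    only_a = a.codes - b.codes
    only_b = b.codes - a.codes
    change = _percent_change(len(a.codes), len(b.codes)) if a.codes else None
    return CodelistComparison(
        size_a=len(a.codes),
        size_b=len(b.codes),
        intersection=inter,
        only_a=only_a,
        only_b=only_b,
        percent_change=change,
    )


def code_frequency_coverage(
    event_code_counts: Mapping[str, int], threshold: float
) -> tuple[int, float]:
    """Smallest number of codes accounting for *threshold* of all events.

    Codes are ranked by descending event count (ties broken by code,
    ascending). Returns ``(k, covered_fraction)`` where ``k`` is the
    shortest prefix of that ranking whose cumulative share of events is at
    least *threshold*, and ``covered_fraction`` is the prefix's share.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if any(v < 0 for v in event_code_counts.values()):
        raise ValueError("event counts must be non-negative")
    total = sum(event_code_counts.values())
    if total == 0:
        raise ValueError("all event counts are zero")
    ranked = sorted(event_code_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    cum = 0
    for k, (_, count) in enumerate(ranked, start=1):
        cum += count
        share = cum / total
        if share >= threshold:
            return k, share
    raise AssertionError("unreachable: cumulative share reaches 1.0")


def write_codelists_csv(
    codelists: Mapping[str, Codelist], graph: ConceptGraph, path: Path | str
) -> None:
    """Export resolved codelists as ``indicator_id,level,code,label`` CSV."""
    rows = [
        (cl.indicator_id, cl.level, code, graph.label_of(code))
        for cl in sorted(codelists.values(), key=lambda c: (c.level, c.indicator_id))
        for code in sorted(cl.codes)
    ]
    pd.DataFrame(rows, columns=["indicator_id", "level", "code", "label"]).to_csv(
        path, index=False
    )
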