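import datetime as dt
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from arisurv.codelists import IndicatorHierarchy, Level3Indicator
from arisurv.synthetic import (
    SimulationConfig,
    generate_events,
    generate_population,
    generate_terminology,
)
from arisurv.terminology import Concept, ConceptGraph


@pytest.fixture
def diamond_graph() -> ConceptGraph:
    """Small polyhierarchy: D has two parents (B, C), both children of A."""
    return ConceptGraph(
        concepts=[Concept(c, c.lower()) for c in "ABCDE"],
        is_a_edges=[("B", "A"), ("C", "A"), ("D", "B"), ("D", "C"), ("E", "D")],
    )


def random_dag(rng: np.random.Generator, n_nodes: int = 30, n_edges: int = 45):
    """Random DAG over string codes; edges only from higher to lower index
    (guaranteeing acyclicity). Returns (graph, edge set)."""
    codes = [f"n{i}" for i in range(n_nodes)]
    edges: set[tuple[str, str]] = set()
    while len(edges) < n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        child, parent = (codes[max(i, j)], codes[min(i, j)])
        edges.add((child, parent))
    return ConceptGraph(codes, sorted(edges)), edges


def random_ecl_ast(rng: np.random.Generator, codes: list[str], depth: int = 3):
    from arisurv.terminology import And, Desc, DescOrSelf, Minus, Or, Self

    if depth == 0 or rng.random() < 0.35:
        leaf = [Self, Desc, DescOrSelf][int(rng.integers(3))]
        return leaf(codes[int(rng.integers(len(codes)))])
    op = [And, Or, Minus][int(rng.integers(3))]
    return op(
        random_ecl_ast(rng, codes, depth - 1), random_ecl_ast(rng, codes, depth - 1)
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset (seeded, session-cached)."""
    cfg = SimulationConfig(
        seed=1, n_practices=5, patients_per_practice=100, miscode_weekly_prob=0.002
    )
    term = generate_terminology(cfg)
    practices, patients = generate_population(cfg)
    events, true_episodes, decoys = generate_events(cfg, term, patients)
    return {
        "config": cfg,
        "term": term,
        "practices": practices,
        "patients": patients,
        "events": events,
        "true_episodes": true_episodes,
        "decoys": decoys,
    }


@pytest.fixture
def tiny_hierarchy() -> IndicatorHierarchy:
    """Minimal two-group hierarchy for unit tests not needing 16 rules."""
    return IndicatorHierarchy(
        level2=["ILI", "URTI"],
        level3=[
            Level3Indicator(id="ili", level2_parent="ILI", ecl="<<ili-root"),
            Level3Indicator(id="urti-a", level2_parent="URTI", ecl="<<urti-a-root"),
            Level3Indicator(id="urti-b", level2_parent="URTI", ecl="<<urti-b-root"),
        ],
    )


@pytest.fixture
def tiny_graph() -> ConceptGraph:
    g = ConceptGraph()
    for code in [
        "root",
        "ili-root",
        "ili-1",
        "urti-a-root",
        "urti-a-1",
        "urti-b-root",
        "urti-b-1",
    ]:
        g.add_concept(Concept(code, code))
    g.add_edge("ili-root", "root")
    g.add_edge("urti-a-root", "root")
    g.add_edge("urti-b-root", "root")
    g.add_edge("ili-1", "ili-root")
    g.add_edge("urti-a-1", "urti-a-root")
    g.add_edge("urti-b-1", "urti-b-root")
    # shared code: urti-b-1 also sits under urti-a-root (polyhierarchy)
    g.add_edge("urti-b-1", "urti-a-root")
    return g


def make_event(patient="P1", practice="PR1", day=0, code="c", start=dt.date(2022, 9, 26)):
    from arisurv.case_detection import ClinicalEvent

    return ClinicalEvent(patient, practice, start + dt.timedelta(days=day), code)
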