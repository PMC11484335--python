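"""SNOMED-like polyhierarchical terminology and an ECL-subset evaluator.

A clinical terminology is modelled as a directed acyclic graph of *is-a*
edges (child → parent). A concept may have several parents (polyhierarchy).
Codelists are selected from the graph with a small subset of SNOMED CT's
Expression Constraint Language (ECL):

    ``C``      the concept itself
    ``<C``     strict descendants of ``C``
    ``<<C``    ``C`` and its descendants
    infix ``AND`` / ``OR`` / ``MINUS``  set intersection / union / difference
    parentheses

Unary constraints bind tightest; the three infix operators share one
precedence level and associate left-to-right, so explicit parentheses are
recommended for mixed expressions.  :func:`format_ecl` prints a fully
parenthesised canonical form that round-trips through :func:`parse_ecl`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import networkx as nx
import pandas as pd

__all__ = [
    "Concept",
    "ConceptGraph",
    "EclExpression",
    "Self",
    "Desc",
    "DescOrSelf",
    "And",
    "Or",
    "Minus",
    "EclSyntaxError",
    "parse_ecl",
    "format_ecl",
    "evaluate_ecl",
    "transitive_descendants",
    "read_terminology",
    "write_terminology",
]


class EclSyntaxError(ValueError):
    """Raised when an ECL string does not conform to the subset grammar."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnknownCodeError(KeyError):
    """Raised when an operation references a code absent from the graph."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg by default
        return f"unknown concept code: {self.code!r}"


@dataclass(frozen=True)
class Concept:
    """A terminology concept: an opaque code plus a human-readable label."""

    code: str
    label: str = ""

    def __post_init__(self):
        if not self.code:
            raise ValueError("concept code must be non-empty")


class ConceptGraph:
    """Polyhierarchical terminology with descendant/ancestor queries.

    Parameters
    ----------
    concepts
        Iterable of :class:`Concept` (or bare code strings).
    is_a_edges
        Iterable of ``(child_code, parent_code)`` pairs. Both endpoints must
        be declared concepts and the relation must be acyclic.

    Notes
    -----
    Descendant sets are computed once per graph state and cached; any
    mutation (``add_concept`` / ``add_edge``) invalidates the cache, so
    queries always reflect the current graph.
    """

    def __init__(
        self,
        concepts: Iterable[Union[Concept, str]] = (),
        is_a_edges: Iterable[tuple[str, str]] = (),
    ):
        self._labels: dict[str, str] = {}
        # edges stored child -> parent
        self._g = nx.DiGraph()
        self._closure: dict[str, frozenset[str]] | None = None
        for c in concepts:
            self.add_concept(c)
        for child, parent in is_a_edges:
            self.add_edge(child, parent)

    # -- construction -----------------------------------------------------
    def add_concept(self, concept: Union[Concept, str]) -> None:
        if isinstance(concept, str):
            concept = Concept(concept)
        if concept.code in self._labels:
            raise ValueError(f"duplicate concept code: {concept.code!r}")
        self._labels[concept.code] = concept.label
        self._g.add_node(concept.code)
        self._closure = None

    def add_edge(self, child: str, parent: str) -> None:
        for code in (child, parent):
            if code not in self._labels:
                raise UnknownCodeError(code)
        self._g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._g):
            self._g.remove_edge(child, parent)
            raise ValueError(
                f"is-a edge {child!r} -> {parent!r} would create a cycle"
            )
        self._closure = None

    # -- queries -----------------------------------------------------------
    def __contains__(self, code: str) -> bool:
        return code in self._labels

    def __len__(self) -> int:
        return len(self._labels)

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self._labels)

    def label_of(self, code: str) -> str:
        if code not in self._labels:
            raise UnknownCodeError(code)
        return self._labels[code]

    @property
    def is_a_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._g.edges())

    def parents(self, code: str) -> frozenset[str]:
        if code not in self._labels:
            raise UnknownCodeError(code)
        return frozenset(self._g.successors(code))

    def children(self, code: str) -> frozenset[str]:
        if code not in self._labels:
            raise UnknownCodeError(code)
        return frozenset(self._g.predecessors(code))

    def _descendant_closure(self) -> dict[str, frozenset[str]]:
        # Descendants of X are all nodes with a directed child->parent path
        # to X, i.e. nx.ancestors in the child->parent digraph.
        if self._closure is None:
            self._closure = {
                code: frozenset(nx.ancestors(self._g, code))
                for code in self._g.nodes()
            }
        return self._closure

    def descendants(self, code: str, include_self: bool = False) -> frozenset[str]:
        """All concepts whose ancestor set contains *code*."""
        if code not in self._labels:
            raise UnknownCodeError(code)
        desc = self._descendant_closure()[code]
        return desc | {code} if include_self else desc

    def ancestors(self, code: str) -> frozenset[str]:
        if code not in self._labels:
            raise UnknownCodeError(code)
        return frozenset(nx.descendants(self._g, code))


def transitive_descendants(
    graph: ConceptGraph, code: str, include_self: bool = False
) -> frozenset[str]:
    """Set of codes below *code* in the is-a hierarchy.

    Returns every concept from which *code* is reachable by following
    child→parent edges, plus *code* itself iff ``include_self``.
    """
    return graph.descendants(code, include_self=include_self)


# ---------------------------------------------------------------------------
# ECL abstract syntax tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Self:
    code: str


@dataclass(frozen=True)
class Desc:
    code: str


@dataclass(frozen=True)
class DescOrSelf:
    code: str


@dataclass(frozen=True)
class And:
    left: "EclExpression"
    right: "EclExpression"


@dataclass(frozen=True)
class Or:
    left: "EclExpression"
    right: "EclExpression"


@dataclass(frozen=True)
class Minus:
    left: "EclExpression"
    right: "EclExpression"


EclExpression = Union[Self, Desc, DescOrSelf, And, Or, Minus]

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<dlt><<)|(?P<lt><)|(?P<lpar>\()|(?P<rpar>\))"
    r"|(?P<word>[A-Za-z0-9_.\-]+))"
)
_KEYWORDS = {"AND", "OR", "MINUS"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise EclSyntaxError(
                f"unexpected character {stripped[0]!r}", len(text) - len(stripped)
            )
        kind = m.lastgroup
        value = m.group(kind)
        if kind == "word" and value.upper() in _KEYWORDS:
            tokens.append((value.upper(), value, m.start(kind)))
        else:
            tokens.append((kind, value, m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for the ECL subset.

    grammar:
        expr    := operand ((AND | OR | MINUS) operand)*   # left-assoc
        operand := '<<' code | '<' code | code | '(' expr ')'
    """

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        self.i += 1
        return tok

    def _fail(self, message: str):
        pos = self.tokens[self.i][2] if self.i < len(self.tokens) else len(self.text)
        raise EclSyntaxError(message, pos)

    def parse(self) -> EclExpression:
        if not self.tokens:
            raise EclSyntaxError("empty ECL expression", 0)
        expr = self._expr()
        if self._peek() is not None:
            self._fail(f"unexpected token {self._peek()[1]!r}")
        return expr

    def _expr(self) -> EclExpression:
        node = self._operand()
        while True:
            tok = self._peek()
            if tok is None or tok[0] not in _KEYWORDS:
                return node
            op = self._next()[0]
            rhs = self._operand()
            node = {"AND": And, "OR": Or, "MINUS": Minus}[op](node, rhs)

    def _operand(self) -> EclExpression:
        tok = self._peek()
        if tok is None:
            self._fail("expected a constraint, found end of input")
        kind, value, pos = tok
        if kind == "dlt":
            self._next()
            return DescOrSelf(self._code())
        if kind == "lt":
            self._next()
            return Desc(self._code())
        if kind == "word":
            self._next()
            return Self(value)
        if kind == "lpar":
            self._next()
            inner = self._expr()
            closing = self._next()
            if closing is None or closing[0] != "rpar":
                raise EclSyntaxError("expected ')'", pos)
            return inner
        self._fail(f"unexpected token {value!r}")

    def _code(self) -> str:
        tok = self._next()
        if tok is None or tok[0] != "word":
            self._fail("expected a concept code")
        return tok[1]


def parse_ecl(text: str) -> EclExpression:
    """Parse an ECL-subset string into its abstract syntax tree.

    Raises
    ------
    EclSyntaxError
        On empty input or any deviation from the subset grammar, naming
        the character position of the problem.
    """
    return _Parser(text).parse()


def format_ecl(expr: EclExpression) -> str:
    """Canonical, fully parenthesised rendering of an AST.

    ``parse_ecl(format_ecl(e)) == e`` for every expression ``e``.
    """
    if isinstance(expr, Self):
        return expr.code
    if isinstance(expr, Desc):
        return f"<{expr.code}"
    if isinstance(expr, DescOrSelf):
        return f"<<{expr.code}"
    op = {And: "AND", Or: "OR", Minus: "MINUS"}[type(expr)]
    return f"({format_ecl(expr.left)} {op} {format_ecl(expr.right)})"


def evaluate_ecl(graph: ConceptGraph, expr: Union[EclExpression, str]) -> frozenset[str]:
    """Resolve an ECL expression to the concrete set of matching codes.

    Accepts either an AST or a string (parsed first). Leaf codes must
    exist in *graph*; an unknown code raises :class:`UnknownCodeError`.
    """
    if isinstance(expr, str):
        expr = parse_ecl(expr)
    if isinstance(expr, Self):
        if expr.code not in graph:
            raise UnknownCodeError(expr.code)
        return frozenset({expr.code})
    if isinstance(expr, DescOrSelf):
        return graph.descendants(expr.code, include_self=True)
    if isinstance(expr, Desc):
        return graph.descendants(expr.code, include_self=False)
    left = evaluate_ecl(graph, expr.left)
    right = evaluate_ecl(graph, expr.right)
    if isinstance(expr, And):
        return left & right
    if isinstance(expr, Or):
        return left | right
    if isinstance(expr, Minus):
        return left - right
    raise TypeError(f"not an ECL expression: {expr!r}")


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def read_terminology(concepts_csv: Path | str, edges_csv: Path | str) -> ConceptGraph:
    """Load a terminology from ``code,label`` and ``child_code,parent_code`` CSVs."""
    concepts = pd.read_csv(concepts_csv, dtype=str).fillna("")
    edges = pd.read_csv(edges_csv, dtype=str)
    for col in ("code", "label"):
        if col not in concepts.columns:
            raise ValueError(f"concepts CSV missing column {col!r}")
    for col in ("child_code", "parent_code"):
        if col not in edges.columns:
            raise ValueError(f"edges CSV missing column {col!r}")
    graph = ConceptGraph(
        (Concept(row.code, row.label) for row in concepts.itertuples()),
        ((row.child_code, row.parent_code) for row in edges.itertuples()),
    )
    return graph


def write_terminology(
    graph: ConceptGraph, concepts_csv: Path | str, edges_csv: Path | str
) -> None:
    """Write a terminology as the CSV pair read by :func:`read_terminology`."""
    codes = sorted(graph.codes)
    pd.DataFrame(
        {"code": codes, "label": [graph.label_of(c) for c in codes]}
    ).to_csv(concepts_csv, index=False)
    edges = sorted(graph.is_a_edges)
    pd.DataFrame(edges, columns=["child_code", "parent_code"]).to_csv(
        edges_csv, index=False
    )
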