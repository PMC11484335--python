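"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (repeated edge expansion, straight
scans, exhaustive search) and shares no code with the package's own
algorithms.
"""

from __future__ import annotations

import datetime as dt


def reachability_descendants(
    edges: set[tuple[str, str]], code: str, include_self: bool
) -> set[str]:
    """Descendants by repeated edge expansion over (child, parent) pairs."""
    out: set[str] = set()
    frontier = {code}
    while frontier:
        nxt = {c for (c, p) in edges if p in frontier and c not in out}
        out |= nxt
        frontier = nxt
    return out | {code} if include_self else out


def ecl_eval_naive(expr, edges: set[tuple[str, str]]) -> set[str]:
    """Set-algebra evaluation of an ECL AST using the reachability oracle."""
    from arisurv.terminology import And, Desc, DescOrSelf, Minus, Or, Self

    if isinstance(expr, Self):
        return {expr.code}
    if isinstance(expr, Desc):
        return reachability_descendants(edges, expr.code, include_self=False)
    if isinstance(expr, DescOrSelf):
        return reachability_descendants(edges, expr.code, include_self=True)
    left = ecl_eval_naive(expr.left, edges)
    right = ecl_eval_naive(expr.right, edges)
    if isinstance(expr, And):
        return left & right
    if isinstance(expr, Or):
        return left | right
    if isinstance(expr, Minus):
        return left - right
    raise TypeError(expr)


def dedup_scan(dates: list[dt.date], window_days: int, mode: str) -> list[list[dt.date]]:
    """Straight-line episode grouping over sorted dates."""
    if not dates:
        return []
    episodes = [[dates[0]]]
    for d in dates[1:]:
        anchor = episodes[-1][-1] if mode == "rolling" else episodes[-1][0]
        if (d - anchor).days > window_days:
            episodes.append([d])
        else:
            episodes[-1].append(d)
    return episodes


def coverage_exhaustive(counts: dict[str, int], threshold: float) -> int:
    """Smallest prefix length over the descending-count ranking reaching
    *threshold*, found by trying every prefix length."""
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    for k in range(1, len(ranked) + 1):
        if sum(v for _, v in ranked[:k]) / total >= threshold:
            return k
    raise AssertionError("threshold unreachable")


def median_sort_and_pick(values: list[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2


def weekly_counts_double_loop(cases, weeks) -> dict[tuple, int]:
    """Naive double loop: for each week, count cases whose index date falls
    in that ISO week, per indicator (level 1 = every case)."""
    out: dict[tuple, int] = {}
    for wk in weeks:
        for case in cases:
            iso = case.index_date.isocalendar()
            if (iso.year, iso.week) == wk:
                for ind in {"ARI", case.level2}:
                    out[(wk, ind)] = out.get((wk, ind), 0) + 1
    return out
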