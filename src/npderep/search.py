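"""Tolerance-based ¹³C shift-list search against an annotated library.

A dereplication query is a list of observed delta_C values (possibly a
subset of a compound's carbons, e.g. the HSQC/HMBC-derived neighbourhood of
one diagnostic proton), a ppm tolerance, and optional multiplicity and
molecular-formula constraints.  A candidate matches when a one-to-one
assignment pairs every query shift with a distinct predicted shift within
tolerance; candidates are ranked by matched count, then by the mean
absolute deviation (MAD) over the assigned pairs.

Matching is an optimal-assignment problem: among maximum-cardinality
assignments the one with minimum total |Δδ| is chosen (Hungarian algorithm
on a penalized cost matrix).  The one-to-one discipline prevents a single
candidate resonance from absorbing several query shifts; symmetry-
equivalent carbons legitimately contribute one predicted value per atom,
so a benzene-like ring can still absorb several coincident query shifts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .formula import ElementRangeSpec, matches_element_spec

__all__ = [
    "QueryError",
    "ShiftQuery",
    "MatchResult",
    "SearchHit",
    "build_query",
    "match_shift_lists",
    "search_library",
    "write_hits_tsv",
]

_FORBIDDEN = 1.0e6


class QueryError(ValueError):
    """Raised for malformed query text."""


@dataclass(frozen=True)
class ShiftQuery:
    """A delta_C shift-list query.

    ``shifts`` is a sequence of (delta_C ppm, n_H or None); ``require_all``
    (default) demands that every query shift find a partner — the right
    semantics for subset queries drawn from a mixture fraction, where the
    candidate may have many unmatched carbons without penalty but the
    observed shifts must all be explained.
    """

    shifts: Tuple[Tuple[float, Optional[int]], ...]
    tolerance: float
    formula_spec: Optional[ElementRangeSpec] = None
    require_all: bool = True
    multiplicity_mode: str = "off"  # off | strict

    def __post_init__(self) -> None:
        if not self.shifts:
            raise QueryError("query has no shifts")
        if self.tolerance <= 0:
            raise QueryError("tolerance must be > 0")
        if self.multiplicity_mode not in ("off", "strict"):
            raise QueryError(f"unknown multiplicity mode {self.multiplicity_mode!r}")


@dataclass(frozen=True)
class MatchResult:
    matched: int
    mad: float
    assignment: Tuple[Tuple[int, int], ...]  # (query index, candidate index)


@dataclass(frozen=True)
class SearchHit:
    record: object  # CompoundRecord
    matched: int
    mad: float
    assignment: Tuple[Tuple[int, int], ...]  # (query index, predicted atom index)


_SHIFT_TOKEN = re.compile(r"^\s*(-?\d+(?:\.\d+)?)(?::([0-4]))?\s*$")


def build_query(
    text: str,
    tolerance: float,
    formula_spec: Optional[ElementRangeSpec] = None,
    require_all: bool = True,
    multiplicity_mode: str = "off",
) -> ShiftQuery:
    """Parse ``"shift[:nH][;...]"`` text into a :class:`ShiftQuery`.

    ``"151.83:1;100.36:1;122.82:0"`` gives three shifts with multiplicities;
    omitting ``:nH`` leaves the multiplicity unconstrained.  Order is
    preserved.
    """
    shifts = []
    for pos, token in enumerate(text.split(";"), start=1):
        m = _SHIFT_TOKEN.match(token)
        if not m:
            raise QueryError(f"malformed shift token {token!r} at position {pos}")
        shifts.append((float(m.group(1)), int(m.group(2)) if m.group(2) else None))
    return ShiftQuery(tuple(shifts), tolerance, formula_spec, require_all, multiplicity_mode)


def match_shift_lists(
    query: Sequence[Tuple[float, Optional[int]]],
    candidate: Sequence[Tuple[float, int]],
    tolerance: float,
    multiplicity_mode: str = "off",
    require_all: bool = True,
) -> Optional[MatchResult]:
    """Optimal one-to-one matching of query shifts to candidate shifts.

    Admissible pairs satisfy \\|Δδ| ≤ tolerance and, in strict multiplicity
    mode, equal attached-H counts (query shifts with ``None`` multiplicity
    are unconstrained).  The assignment maximizes the number of matched
    pairs and, among those, minimizes the total absolute deviation.
    Returns None when no pair matches, or when ``require_all`` is set and
    some query shift stays unmatched.
    """
    if not query or not candidate:
        raise ValueError("query and candidate shift lists must be non-empty")
    nq, nc = len(query), len(candidate)
    cost = np.full((nq, nc), _FORBIDDEN)
    for i, (qd, qh) in enumerate(query):
        for j, (cd, ch) in enumerate(candidate):
            if abs(qd - cd) <= tolerance and (
                multiplicity_mode == "off" or qh is None or qh == ch
            ):
                cost[i, j] = abs(qd - cd)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < _FORBIDDEN / 2]
    if not pairs:
        return None
    if require_all and len(pairs) < nq:
        return None
    mad = float(np.mean([cost[i, j] for i, j in pairs]))
    return MatchResult(len(pairs), mad, tuple(pairs))


def search_library(library: Sequence, query: ShiftQuery) -> List[SearchHit]:
    """Rank library records against a shift query.

    The molecular-formula filter is applied first; each surviving record's
    predicted shift list is then matched.  Hits are sorted by matched count
    (descending), MAD (ascending), then InChIKey — a total order, so the
    ranking is identical across runs and platforms.
    """
    hits = []
    for rec in library:
        if query.formula_spec is not None and not matches_element_spec(
            rec.formula, query.formula_spec
        ):
            continue
        preds = list(rec.predictions)
        if not preds:
            continue
        cand = [(p.delta_c, p.n_h) for p in preds]
        res = match_shift_lists(
            list(query.shifts),
            cand,
            query.tolerance,
            query.multiplicity_mode,
            query.require_all,
        )
        if res is None:
            continue
        assignment = tuple((qi, preds[cj].atom_index) for qi, cj in res.assignment)
        hits.append(SearchHit(rec, res.matched, res.mad, assignment))
    hits.sort(key=lambda h: (-h.matched, h.mad, h.record.structure.inchikey))
    return hits


def write_hits_tsv(path, hits: Sequence[SearchHit]) -> None:
    """Hit table: rank, inchikey, name, matched, mad, assignment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tinchikey\tname\tmatched\tmad\tassignment\n")
        for rank, h in enumerate(hits, start=1):
            name = h.record.names[0] if h.record.names else ""
            asg = ";".join(f"{qi}:{ai}" for qi, ai in h.assignment)
            fh.write(
                f"{rank}\t{h.record.structure.inchikey}\t{name}\t"
                f"{h.matched}\t{h.mad:.4f}\t{asg}\n"
            )
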