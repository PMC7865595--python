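"""Shift-list matching, query parsing and library search."""

import itertools
import random

import pytest

from npderep.formula import parse_element_spec
from npderep.search import (
    QueryError,
    ShiftQuery,
    build_query,
    match_shift_lists,
    search_library,
)

A2_TEXT = "151.83:1;100.36:1;105.40:1;122.82:0;124.03:0;129.6:0;143.74:0"


def brute_force_match(query, candidate, tolerance, multiplicity_mode="off"):
    """Exhaustive search over all one-to-one assignments (oracle)."""

    def admissible(q, c):
        qd, qh = q
        cd, ch = c
        return abs(qd - cd) <= tolerance and (
            multiplicity_mode == "off" or qh is None or qh == ch
        )

    best = (0, float("inf"))
    nq = len(query)
    for perm in itertools.permutations(range(len(candidate)), min(nq, len(candidate))):
        matched, total = 0, 0.0
        for qi, cj in enumerate(perm):
            if admissible(query[qi], candidate[cj]):
                matched += 1
                total += abs(query[qi][0] - candidate[cj][0])
        best = min(best, (-matched, total))
    matched = -best[0]
    if matched == 0:
        return None
    return matched, best[1] / matched


class TestMatchShiftLists:
    def test_identical_lists_match_exactly(self):
        shifts = [151.83, 100.36, 105.40, 122.82, 124.03, 129.6, 143.74]
        q = [(s, None) for s in shifts]
        c = [(s, 1) for s in shifts]
        res = match_shift_lists(q, c, 1.0)
        assert res.matched == 7
        assert res.mad == 0.0

    def test_single_pair_deviation(self):
        res = match_shift_lists([(100.0, None)], [(101.5, 1)], 2.0)
        assert res.matched == 1
        assert res.mad == pytest.approx(1.5)

    def test_one_to_one_exhaustion(self):
        """Two query shifts cannot share one candidate resonance."""
        res = match_shift_lists([(100.0, None), (100.2, None)], [(100.1, 1)], 2.0)
        assert res is None  # require_all: second query shift has no partner
        res = match_shift_lists(
            [(100.0, None), (100.2, None)], [(100.1, 1)], 2.0, require_all=False
        )
        assert res.matched == 1

    def test_equivalent_carbons_absorb_multiple_shifts(self):
        """Symmetry-duplicated predicted values are distinct partners."""
        res = match_shift_lists(
            [(128.4, None), (128.6, None)], [(128.5, 1), (128.5, 1)], 1.0
        )
        assert res.matched == 2

    def test_strict_multiplicity(self):
        q = [(100.0, 1)]
        assert match_shift_lists(q, [(100.1, 0)], 1.0, multiplicity_mode="strict") is None
        assert match_shift_lists(q, [(100.1, 1)], 1.0, multiplicity_mode="strict").matched == 1
        # unconstrained query multiplicity matches anything
        assert (
            match_shift_lists([(100.0, None)], [(100.1, 0)], 1.0, multiplicity_mode="strict").matched
            == 1
        )

    def test_minimum_deviation_among_max_cardinality(self):
        # both candidates within tolerance of both queries; optimal pairing
        # is the diagonal with total |dd| 0.2, not the crossed 2*1.1
        res = match_shift_lists(
            [(100.0, None), (101.0, None)], [(100.1, 2), (101.1, 2)], 2.0
        )
        assert res.mad == pytest.approx(0.1)
        assert dict(res.assignment) == {0: 0, 1: 1}

    def test_agrees_with_bruteforce_on_random_instances(self):
        rng = random.Random(2024)
        for _ in range(500):
            nq = rng.randint(1, 5)
            nc = rng.randint(nq, 8)
            query = [
                (round(rng.uniform(0, 200), 2), rng.choice([None, 0, 1, 2, 3]))
                for _ in range(nq)
            ]
            candidate = [
                (round(rng.uniform(0, 200), 2), rng.randint(0, 3)) for _ in range(nc)
            ]
            tol = rng.choice([1.0, 2.0, 5.0, 20.0, 80.0])
            mode = rng.choice(["off", "strict"])
            expected = brute_force_match(query, candidate, tol, mode)
            got = match_shift_lists(query, candidate, tol, mode, require_all=False)
            if expected is None:
                assert got is None
            else:
                assert got.matched == expected[0]
                assert got.mad == pytest.approx(expected[1], abs=1e-9)


class TestBuildQuery:
    def test_seven_shift_query_with_multiplicities(self):
        q = build_query(A2_TEXT, 2.0)
        assert len(q.shifts) == 7
        assert q.shifts[0] == (151.83, 1)
        assert q.shifts[3] == (122.82, 0)

    def test_bare_shift_unconstrained(self):
        q = build_query("100", 1.0)
        assert q.shifts == ((100.0, None),)

    def test_malformed_token_position(self):
        with pytest.raises(QueryError, match="position 1"):
            build_query("abc", 1.0)
        with pytest.raises(QueryError, match="position 2"):
            build_query("100.0;x", 1.0)

    def test_invalid_tolerance(self):
        with pytest.raises(QueryError):
            build_query("100", 0.0)


class TestSearchLibrary:
    def test_empty_library(self, bundle):
        assert search_library([], bundle.queries["A2_tol2"]) == []

    def test_tolerance_monotonicity(self, bundle):
        keys1 = {h.record.structure.inchikey for h in search_library(list(bundle.records), bundle.queries["A2_tol1"])}
        keys2 = {h.record.structure.inchikey for h in search_library(list(bundle.records), bundle.queries["A2_tol2"])}
        keys5 = {h.record.structure.inchikey for h in search_library(list(bundle.records), bundle.queries["A2_tol5"])}
        assert keys1 <= keys2 <= keys5
        assert keys1 < keys5  # the widening is non-vacuous

    def test_formula_constraint_never_adds_hits(self, bundle):
        q = bundle.queries["A2_tol5"]
        unconstrained = ShiftQuery(q.shifts, q.tolerance, None, q.require_all)
        with_f = {h.record.structure.inchikey for h in search_library(list(bundle.records), q)}
        without_f = {h.record.structure.inchikey for h in search_library(list(bundle.records), unconstrained)}
        assert with_f <= without_f

    def test_self_retrieval(self, bundle):
        """Each record's own full shift list retrieves it first, MAD 0."""
        for rec in bundle.records[::5]:
            q = ShiftQuery(tuple((p.delta_c, None) for p in rec.predictions), 0.01)
            hits = search_library(list(bundle.records), q)
            assert hits[0].record.structure.inchikey == rec.structure.inchikey
            assert hits[0].mad == 0.0

    def test_ranking_deterministic(self, bundle):
        q = bundle.queries["A2_tol5"]
        a = [(h.record.structure.inchikey, h.matched, h.mad) for h in search_library(list(bundle.records), q)]
        b = [(h.record.structure.inchikey, h.matched, h.mad) for h in search_library(list(bundle.records), q)]
        assert a == b
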