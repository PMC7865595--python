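"""Molecular-formula arithmetic.

A :class:`MolecularFormula` is an element→count map plus an integer charge.
It is the unit of all formula comparison and filtering in the toolkit:
reconciling a library formula against the one computed from a structure,
stripping an [M+H]+ adduct observed in positive-mode ESI down to its neutral
formula, and range-filtering candidate hits (e.g. keeping only plausible
alkaloids with ``C(12-100) H(1-100) N(1-2) O(1-100)``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

from rdkit import Chem

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "ElementRangeSpec",
    "parse_formula",
    "parse_element_spec",
    "neutral_from_protonated",
    "matches_element_spec",
]


class FormulaError(ValueError):
    """Raised for malformed formula or element-range text."""


_PT = Chem.GetPeriodicTable()


def _is_element(symbol: str) -> bool:
    try:
        return _PT.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition with a net charge.

    ``counts`` maps element symbols to strictly positive integers; an absent
    element means count zero.  Rendering follows the Hill convention
    (C first, then H, then all other elements alphabetically) with the
    charge appended as a trailing sign, magnitude first for \\|charge| > 1.
    """

    counts: Tuple[Tuple[str, int], ...]
    charge: int = 0

    def __post_init__(self) -> None:
        for sym, n in self.counts:
            if not _is_element(sym):
                raise FormulaError(f"unknown element symbol {sym!r}")
            if n < 1:
                raise FormulaError(f"count for {sym} must be >= 1, got {n}")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], charge: int = 0) -> "MolecularFormula":
        items = tuple(sorted((s, n) for s, n in counts.items() if n))
        return cls(items, charge)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def count(self, symbol: str) -> int:
        return self.as_dict().get(symbol, 0)

    @property
    def total_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    def __str__(self) -> str:
        d = self.as_dict()
        parts = []
        for sym in _hill_order(d):
            n = d[sym]
            parts.append(sym + (str(n) if n > 1 else ""))
        body = "".join(parts)
        if self.charge == 0:
            return body
        sign = "+" if self.charge > 0 else "-"
        mag = abs(self.charge)
        return body + (sign if mag == 1 else f"{mag}{sign}")


def _hill_order(d: Mapping[str, int]) -> Iterable[str]:
    rest = sorted(s for s in d if s not in ("C", "H"))
    if "C" in d:
        order = ["C"] + (["H"] if "H" in d else []) + rest
    else:
        # no carbon: plain alphabetical, H included
        order = sorted(d)
    return order


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse formula text, including bracketed ion notation.

    Accepts plain Hill formulas (``C18H21NO5``, implicit count 1) and
    bracketed ions with a trailing charge (``[C16H18NO3]+``, ``[SO4]2-``).
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    s = text.strip()
    charge = 0
    if s.startswith("["):
        m = re.fullmatch(r"\[([^\[\]]+)\](\d*)([+-])", s)
        if not m:
            raise FormulaError(f"malformed ion notation: {text!r}")
        s = m.group(1)
        mag = int(m.group(2)) if m.group(2) else 1
        charge = mag if m.group(3) == "+" else -mag
    elif s and s[-1] in "+-":
        # bare trailing sign means |charge| = 1; a magnitude digit before
        # the sign is ambiguous with an atom count outside brackets, so
        # multiply-charged ions must use the bracketed notation
        charge = 1 if s[-1] == "+" else -1
        s = s[:-1]
        if not s:
            raise FormulaError(f"charge sign without formula in {text!r}")

    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m or not m.group(1):
            raise FormulaError(f"unparsable token at {s[pos:]!r} in {text!r}")
        sym, num = m.group(1), m.group(2)
        if not _is_element(sym):
            # retry one-letter symbol if a two-letter guess failed (e.g. "NO")
            if len(sym) == 2 and _is_element(sym[0]):
                sym, num = sym[0], ""
                pos += 1
            else:
                raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        else:
            pos = m.end()
        n = int(num) if num else 1
        if n < 1:
            raise FormulaError(f"count 0 for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
    return MolecularFormula.from_counts(counts, charge)


def neutral_from_protonated(ion: MolecularFormula) -> MolecularFormula:
    """Neutral formula of an [M+H]+ ion: remove one H and the +1 charge."""
    if ion.charge != 1:
        raise ValueError(f"expected charge +1, got {ion.charge:+d}")
    d = ion.as_dict()
    if d.get("H", 0) < 1:
        raise ValueError("ion has no hydrogen to remove")
    d["H"] -= 1
    if d["H"] == 0:
        del d["H"]
    return MolecularFormula.from_counts(d, 0)


@dataclass(frozen=True)
class ElementRangeSpec:
    """Per-element count windows, e.g. ``C(12-100) H(1-100) N(1-2) O(1-100)``.

    ``closed_world=True`` additionally rejects formulas containing any
    element not listed in the spec (the right reading for an alkaloid
    filter written as C/H/N/O only).
    """

    ranges: Tuple[Tuple[str, int, int], ...]
    closed_world: bool = False

    def __post_init__(self) -> None:
        for sym, lo, hi in self.ranges:
            if not _is_element(sym):
                raise FormulaError(f"unknown element symbol {sym!r}")
            if lo < 0 or lo > hi:
                raise FormulaError(f"bad range {lo}-{hi} for {sym}")

    @classmethod
    def from_dict(cls, ranges: Mapping[str, Tuple[int, int]], closed_world: bool = False) -> "ElementRangeSpec":
        return cls(tuple(sorted((s, lo, hi) for s, (lo, hi) in ranges.items())), closed_world)


_SPEC_ITEM = re.compile(r"([A-Z][a-z]?)\((\d+)-(\d+)\)")


def parse_element_spec(text: str, closed_world: bool = False) -> ElementRangeSpec:
    """Parse spec text of the form ``C(12-100)H(1-100)N(1-2)O(1-100)``."""
    s = text.replace(" ", "")
    if not s:
        raise FormulaError("empty element-range spec")
    items = []
    pos = 0
    while pos < len(s):
        m = _SPEC_ITEM.match(s, pos)
        if not m:
            raise FormulaError(f"unparsable range at {s[pos:]!r}")
        items.append((m.group(1), int(m.group(2)), int(m.group(3))))
        pos = m.end()
    return ElementRangeSpec(tuple(sorted(items)), closed_world)


def matches_element_spec(f: MolecularFormula, spec: ElementRangeSpec) -> bool:
    """True iff every listed element count lies in its window (and, in
    closed-world mode, no unlisted element is present)."""
    d = f.as_dict()
    listed = {sym for sym, _, _ in spec.ranges}
    for sym, lo, hi in spec.ranges:
        if not lo <= d.get(sym, 0) <= hi:
            return False
    if spec.closed_world and any(sym not in listed for sym in d):
        return False
    return True
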