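"""HOSE-code nearest-neighbour prediction of ¹³C chemical shifts.

A HOSE code (Hierarchically Ordered Spherical Environment) describes an
atom's neighbourhood sphere by sphere as a canonical string: sphere 1 lists
the direct neighbours, sphere 2 their neighbours, and so on, with a
deterministic ordering that makes the code independent of input atom
numbering.  Carbons with identical codes sit in (near-)identical chemical
environments and resonate at (near-)identical frequencies, which turns
shift prediction into a table lookup: store the mean observed shift per
code at each sphere depth, and predict a query carbon from the deepest
sphere at which its code has been seen, falling back sphere by sphere and
finally to the table-wide mean.

Stereochemistry is deliberately ignored: the prediction is meant for
constitution-level dereplication, where enantiomers (crinine/vittatine
style pairs) are indistinguishable by their carbon shifts anyway.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from rdkit import Chem

log = logging.getLogger(__name__)

__all__ = [
    "MAX_SPHERE",
    "SHIFT_RANGE",
    "HoseCode",
    "hose_code",
    "ShiftPrediction",
    "ReferenceTable",
    "build_reference_table",
    "predict_carbon_shifts",
]

MAX_SPHERE = 4
#: Physically plausible delta_C window; entries outside it are rejected.
SHIFT_RANGE = (-20.0, 250.0)

_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: "*",
}


def _atom_symbol(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    if atom.GetIsAromatic():
        sym = sym.lower()
    q = atom.GetFormalCharge()
    if q:
        sym += ("+" if q > 0 else "-") * abs(q)
    return sym + f"H{atom.GetTotalNumHs()}"


def _token(bond: Chem.Bond, atom: Chem.Atom) -> str:
    return _BOND_SYMBOL.get(bond.GetBondType(), "~") + _atom_symbol(atom)


class _Node:
    __slots__ = ("token", "children", "canon")

    def __init__(self, token: str, children: List["_Node"]):
        self.token = token
        self.children = children
        if children:
            self.canon = token + "(" + ",".join(sorted(c.canon for c in children)) + ")"
        else:
            self.canon = token
        self.children.sort(key=lambda c: c.canon)


def _expand(mol: Chem.Mol, atom: Chem.Atom, parent_idx: int, depth: int) -> List["_Node"]:
    if depth == 0:
        return []
    children = []
    for bond in atom.GetBonds():
        nbr = bond.GetOtherAtom(atom)
        if nbr.GetIdx() == parent_idx:
            continue
        sub = _expand(mol, nbr, atom.GetIdx(), depth - 1)
        children.append(_Node(_token(bond, nbr), sub))
    return children


@dataclass(frozen=True)
class HoseCode:
    """Canonical spherical environment of one atom.

    ``spheres[k-1]`` is the sphere-k segment; the cumulative code at depth
    d (:meth:`prefix`) is the center descriptor plus the first d segments,
    so each depth's code string is a prefix of the next.  Child ordering is
    fixed once from the full-depth canonical subtree strings, which keeps
    the per-depth prefixes mutually consistent.
    """

    center_element: str
    center: str
    spheres: Tuple[str, ...]

    def prefix(self, depth: int) -> str:
        return self.center + "|" + "/".join(self.spheres[:depth])

    @property
    def code(self) -> str:
        return self.prefix(len(self.spheres))


def hose_code(mol: Chem.Mol, atom_index: int, max_sphere: int = MAX_SPHERE) -> HoseCode:
    """Canonical HOSE code of an atom, to ``max_sphere`` spheres.

    Symmetry-equivalent atoms of a molecule yield identical codes and the
    code is invariant under renumbering of the input atoms.  Ring systems
    are unrolled: an atom reachable along two bond paths contributes to
    both branches (rings re-converge, as in the classic scheme).
    """
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    atom = mol.GetAtomWithIdx(atom_index)
    root_children = _expand(mol, atom, -1, max_sphere)
    root = _Node(_atom_symbol(atom), root_children)

    spheres = []
    frontier = [root]
    for _ in range(max_sphere):
        groups = []
        nxt = []
        for node in frontier:
            groups.append(",".join(c.token for c in node.children))
            nxt.extend(node.children)
        spheres.append(";".join(groups))
        frontier = nxt
    return HoseCode(atom.GetSymbol(), root.token, tuple(spheres))


@dataclass(frozen=True)
class ShiftPrediction:
    """Predicted delta_C for one carbon.

    ``n_h`` is the multiplicity in the DEPT/edited-HSQC sense (number of
    attached hydrogens); ``sphere_used`` is the HOSE sphere depth of the
    matching table entry, 0 for the global fallback.
    """

    atom_index: int
    delta_c: float
    n_h: int
    sphere_used: int


class ReferenceTable:
    """Per-sphere map HOSE code → (mean shift, count, spread).

    Built once by :func:`build_reference_table`; treated as immutable
    afterwards.  ``spread`` is the population standard deviation of the
    shifts pooled under one code.
    """

    def __init__(self) -> None:
        # (sphere, code) -> [mean, count, M2]
        self._entries: Dict[Tuple[int, str], List[float]] = {}
        self._sum = 0.0
        self._n = 0
        self.provenance: List[str] = []

    def _add(self, sphere: int, code: str, shift: float) -> None:
        e = self._entries.setdefault((sphere, code), [0.0, 0, 0.0])
        e[1] += 1
        d = shift - e[0]
        e[0] += d / e[1]
        e[2] += d * (shift - e[0])

    def lookup(self, sphere: int, code: str) -> Optional[Tuple[float, int, float]]:
        e = self._entries.get((sphere, code))
        if e is None:
            return None
        mean, n, m2 = e
        return mean, n, math.sqrt(m2 / n) if n else 0.0

    @property
    def global_mean(self) -> float:
        if self._n == 0:
            log.warning("empty reference table; using 100.0 ppm fallback")
            return 100.0
        return self._sum / self._n

    def __len__(self) -> int:
        return len(self._entries)

    def to_tsv(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sphere\tcode\tmean\tcount\tspread\n")
            for (sphere, code), (mean, n, m2) in sorted(self._entries.items()):
                spread = math.sqrt(m2 / n) if n else 0.0
                fh.write(f"{sphere}\t{code}\t{mean:.6f}\t{n}\t{spread:.6f}\n")

    @classmethod
    def from_tsv(cls, path: Path) -> "ReferenceTable":
        table = cls()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("sphere\t"):
                raise ValueError(f"{path}: not a reference-table TSV")
            for line in fh:
                sphere, code, mean, n, spread = line.rstrip("\n").split("\t")
                n_i, mean_f, spread_f = int(n), float(mean), float(spread)
                table._entries[(int(sphere), code)] = [
                    mean_f,
                    n_i,
                    spread_f**2 * n_i,
                ]
                if int(sphere) == 1:
                    table._sum += mean_f * n_i
                    table._n += n_i
        return table


def build_reference_table(
    structures: Iterable[Tuple[Chem.Mol, Mapping[int, float]]],
    max_sphere: int = MAX_SPHERE,
) -> ReferenceTable:
    """Accumulate a reference table from structures with per-carbon shifts.

    ``structures`` yields (molecule, {carbon atom index: delta_C}); every
    carbon of each molecule must have a shift.  Shifts outside the
    physically plausible window are skipped with a log message.
    """
    table = ReferenceTable()
    for mol, shifts in structures:
        carbons = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
        missing = [i for i in carbons if i not in shifts]
        if missing:
            raise ValueError(f"carbons without shifts: {missing}")
        for idx in carbons:
            shift = float(shifts[idx])
            if not SHIFT_RANGE[0] <= shift <= SHIFT_RANGE[1]:
                log.warning("skipping out-of-range shift %.2f at atom %d", shift, idx)
                continue
            hc = hose_code(mol, idx, max_sphere)
            for d in range(1, max_sphere + 1):
                table._add(d, hc.prefix(d), shift)
            table._sum += shift
            table._n += 1
        table.provenance.append(Chem.MolToSmiles(mol))
    return table


def predict_carbon_shifts(
    mol: Chem.Mol,
    table: ReferenceTable,
    max_sphere: int = MAX_SPHERE,
) -> List[ShiftPrediction]:
    """One prediction per carbon: deepest matching sphere wins (4→3→2→1),
    then the table-wide mean with ``sphere_used=0``."""
    out = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        hc = hose_code(mol, atom.GetIdx(), MAX_SPHERE)
        pred = None
        for d in range(min(max_sphere, MAX_SPHERE), 0, -1):
            hit = table.lookup(d, hc.prefix(d))
            if hit is not None:
                pred = ShiftPrediction(atom.GetIdx(), hit[0], atom.GetTotalNumHs(), d)
                break
        if pred is None:
            pred = ShiftPrediction(atom.GetIdx(), table.global_mean, atom.GetTotalNumHs(), 0)
        out.append(pred)
    return out


def stable_unit(text: str) -> float:
    """Deterministic pseudo-uniform value in [-1, 1) derived from text.

    Used by the fixture generator to synthesize reproducible shifts; kept
    here so shift synthesis and HOSE hashing stay in one place.
    """
    h = hashlib.sha1(text.encode("utf-8")).digest()
    return int.from_bytes(h[:8], "big") / 2**63 - 1.0
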