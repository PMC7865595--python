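"""Hierarchical substructure-based chemical classification.

Chemical classes are organized in a four-level hierarchy of dotted decimal
identifiers: level 1 separates compounds derived from primary metabolites
(``01``) from specifically secondary metabolites (``02``); deeper levels
refine into families (sugars, terpenes, ...), skeletal classes and specific
substructures, so that menthol comes out as a secondary metabolite, a
terpene, a monoterpene and a menthane compound.  Each node carries
substructure patterns; a molecule is assigned a node when any pattern
matches, and assignment of a node implies assignment of all its ancestors.

The per-molecule result records the atoms covered by each detected
substructure, which downstream consumers use for sugar detection and for
restricting shift searches to skeleton atoms.

Classification here plays the role of a half-pillar: when biological
taxonomy is unavailable for a compound library, chemical taxonomy still
narrows the search space of a dereplication query.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

log = logging.getLogger(__name__)

__all__ = [
    "CatalogError",
    "ClassNode",
    "ClassAssignment",
    "Catalog",
    "compile_pattern",
    "load_catalog",
    "load_skeletons",
    "classify",
    "enumerate_stereoisomers",
    "hexopyranose_smiles",
    "skeleton_filter",
    "HEXOPYRANOSE_SCAFFOLD",
]

#: Achiral hexopyranose scaffold: five assignable tetrahedral centres, hence
#: 32 fully stereo-specified isomers (alpha/beta anomers of the 16 aldohexoses).
HEXOPYRANOSE_SCAFFOLD = "OCC1OC(O)C(O)C(O)C1O"


class CatalogError(ValueError):
    """Raised when a class catalog file is inconsistent."""


def compile_pattern(pattern: str, mode: str = "smarts") -> Chem.Mol:
    """Compile a catalog pattern into an RDKit query molecule.

    ``smarts``   — the text (SMILES or SMARTS) is compiled as SMARTS.
    ``scaffold`` — the text is parsed as SMILES, reduced to its Murcko
    scaffold, and all bonds are made generic; atom aromaticity still
    constrains the match.  This is the right tool for ring skeletons whose
    members differ in unsaturation or oxidation level.
    """
    if mode == "smarts":
        q = Chem.MolFromSmarts(pattern)
        if q is None:
            raise CatalogError(f"bad SMARTS pattern: {pattern!r}")
        return q
    if mode == "scaffold":
        m = Chem.MolFromSmiles(pattern)
        if m is None:
            raise CatalogError(f"bad scaffold SMILES: {pattern!r}")
        scaf = MurckoScaffold.GetScaffoldForMol(m)
        if scaf.GetNumAtoms() == 0:
            raise CatalogError(f"scaffold pattern has no ring system: {pattern!r}")
        params = Chem.AdjustQueryParameters.NoAdjustments()
        params.makeBondsGeneric = True
        return Chem.AdjustQueryProperties(scaf, params)
    raise CatalogError(f"unknown pattern mode {mode!r}")


@dataclass(frozen=True)
class ClassNode:
    """One node of the class hierarchy.

    ``class_id`` is a dotted decimal ID of 1-4 levels (``02-02-01-001``);
    ``patterns`` hold the raw pattern texts with their compile modes.
    Branch nodes may be pattern-free (assigned only through descendants).
    """

    class_id: str
    label: str
    parent: Optional[str] = None
    patterns: Tuple[Tuple[str, str], ...] = ()  # (mode, pattern text)

    @property
    def level(self) -> int:
        return len(self.class_id.split("-"))


@dataclass(frozen=True)
class ClassAssignment:
    """A per-molecule class hit with the atoms each match covers.

    ``pattern_used`` indexes the node's pattern list; ``-1`` marks an
    assignment inherited from a descendant through hierarchy closure, in
    which case ``matched_atoms`` carries the descendant's matches.
    Atom indices are 0-based.
    """

    class_id: str
    matched_atoms: Tuple[Tuple[int, ...], ...]
    pattern_used: int


class Catalog:
    """A loaded, hierarchy-checked class catalog with compiled patterns."""

    def __init__(self, nodes: Sequence[ClassNode]):
        self.nodes: Dict[str, ClassNode] = {}
        for node in nodes:
            if node.class_id in self.nodes:
                raise CatalogError(f"duplicate class ID {node.class_id}")
            self.nodes[node.class_id] = node
        for node in nodes:
            if node.level > 4:
                raise CatalogError(f"class ID {node.class_id} exceeds four levels")
            if node.level == 1:
                if node.parent:
                    raise CatalogError(f"top-level node {node.class_id} has a parent")
            else:
                expected = "-".join(node.class_id.split("-")[:-1])
                if node.parent != expected:
                    raise CatalogError(
                        f"node {node.class_id}: parent must be {expected}, got {node.parent!r}"
                    )
                if expected not in self.nodes:
                    raise CatalogError(f"orphan node {node.class_id}: no parent {expected}")
        self._queries: Dict[str, List[Chem.Mol]] = {
            node.class_id: [compile_pattern(p, mode) for mode, p in node.patterns]
            for node in nodes
        }

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes.values())

    def queries(self, class_id: str) -> List[Chem.Mol]:
        return self._queries[class_id]

    def ancestors(self, class_id: str) -> List[str]:
        parts = class_id.split("-")
        return ["-".join(parts[:k]) for k in range(1, len(parts))]


def _read_tsv(path: Optional[Path], default_resource: str) -> List[Tuple[int, List[str]]]:
    if path is None:
        text = resources.files("npderep.data").joinpath(default_resource).read_text()
    else:
        text = Path(path).read_text()
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append((lineno, line.rstrip("\n").split("\t")))
    return rows


def load_catalog(path: Optional[Path] = None) -> Catalog:
    """Load a catalog TSV (class_id, label, parent_id, mode, patterns).

    Patterns are pipe-separated; mode applies to all patterns of the row.
    Raises :class:`CatalogError` naming the offending row for duplicate
    IDs, orphans or uncompilable patterns; an empty file yields an empty
    catalog with a warning.
    """
    rows = _read_tsv(path, "class_catalog.tsv")
    if not rows:
        warnings.warn("class catalog is empty")
        return Catalog([])
    nodes = []
    for lineno, parts in rows:
        try:
            class_id = parts[0]
            label = parts[1] if len(parts) > 1 else ""
            parent = parts[2] if len(parts) > 2 and parts[2] else None
            mode = parts[3] if len(parts) > 3 and parts[3] else "smarts"
            pats = tuple(
                (mode, p) for p in (parts[4].split("|") if len(parts) > 4 and parts[4] else [])
            )
            for m, p in pats:
                compile_pattern(p, m)
            nodes.append(ClassNode(class_id, label, parent, pats))
        except CatalogError as exc:
            raise CatalogError(f"row {lineno}: {exc}") from exc
    try:
        return Catalog(nodes)
    except CatalogError as exc:
        raise CatalogError(f"{path or 'packaged catalog'}: {exc}") from exc


def classify(mol: Chem.Mol, catalog: Catalog) -> List[ClassAssignment]:
    """All class assignments of a molecule, with hierarchy closure.

    A node is hit when any of its patterns matches (stereo-aware, so the
    alpha- and beta-glucopyranose patterns are distinguished); every
    ancestor of a hit node is reported as well.  Output is sorted by
    class ID; matched atom index lists are recorded per pattern match.
    """
    direct: Dict[str, ClassAssignment] = {}
    for node in catalog:
        for pi, query in enumerate(catalog.queries(node.class_id)):
            matches = mol.GetSubstructMatches(query, useChirality=True)
            if matches:
                direct[node.class_id] = ClassAssignment(
                    node.class_id, tuple(tuple(m) for m in matches), pi
                )
                break
    assigned: Dict[str, ClassAssignment] = dict(direct)
    for class_id, hit in direct.items():
        for anc in catalog.ancestors(class_id):
            if anc not in assigned:
                assigned[anc] = ClassAssignment(anc, hit.matched_atoms, -1)
    return [assigned[cid] for cid in sorted(assigned)]


def enumerate_stereoisomers(scaffold: str) -> List[str]:
    """All fully stereo-assigned canonical isomeric SMILES of a scaffold.

    Every assignable tetrahedral centre (as found by RDKit's stereo
    perception) is set to each parity; the resulting isomeric SMILES are
    canonicalized and deduplicated, which collapses meso forms and other
    symmetry-equivalent assignments.  Double-bond stereochemistry is left
    untouched.  Output is lexicographically sorted.
    """
    mol = Chem.MolFromSmiles(scaffold)
    if mol is None:
        raise ValueError(f"bad scaffold SMILES: {scaffold!r}")
    centers = [
        si.centeredOn
        for si in Chem.FindPotentialStereo(mol)
        if si.type == Chem.StereoType.Atom_Tetrahedral
    ]
    if not centers:
        return [Chem.MolToSmiles(mol)]
    out = set()
    tags = (Chem.ChiralType.CHI_TETRAHEDRAL_CW, Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
    for combo in itertools.product(tags, repeat=len(centers)):
        m = Chem.Mol(mol)
        for idx, tag in zip(centers, combo):
            m.GetAtomWithIdx(idx).SetChiralTag(tag)
        Chem.AssignStereochemistry(m, cleanIt=True, force=True)
        out.add(Chem.MolToSmiles(m))
    return sorted(out)


def hexopyranose_smiles() -> List[str]:
    """The 32 stereo-specified hexopyranose SMILES (alpha/beta anomers of
    the sixteen aldohexoses), reconstructed from the achiral scaffold."""
    return enumerate_stereoisomers(HEXOPYRANOSE_SCAFFOLD)


def load_skeletons(path: Optional[Path] = None) -> List[Tuple[str, Chem.Mol]]:
    """Load the skeleton pattern table (name, mode, pattern, comment)."""
    rows = _read_tsv(path, "amaryllidaceae_skeletons.tsv")
    out = []
    for lineno, parts in rows:
        if len(parts) < 3:
            raise CatalogError(f"row {lineno}: expected name/mode/pattern")
        name, mode, pattern = parts[0], parts[1], parts[2]
        try:
            out.append((name, compile_pattern(pattern, mode)))
        except CatalogError as exc:
            raise CatalogError(f"row {lineno} ({name}): {exc}") from exc
    return out


def skeleton_filter(mol: Chem.Mol, skeletons: Sequence[Tuple[str, Chem.Mol]]) -> bool:
    """True iff the molecule contains at least one of the skeletons."""
    return any(mol.HasSubstructMatch(q) for _, q in skeletons)
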