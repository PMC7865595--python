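"""Structure descriptors, round-trip validation, standardization, dedup.

Linear notations (SMILES, InChI) are the exchange currency of natural-product
libraries, but decoding them is not loss-free: the InChI layer model cannot
represent axial chirality of allenes or spiro compounds, and InChI decoding
may reconstruct a molecule as an unlikely tautomer (amides come back as
iminols).  The routines here detect the first problem (the InChI
"round-trip" check), repair the second with an ordered catalog of reaction
SMARTS rewrites, and merge records whose recalculated InChIKeys collide.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "Status",
    "ValidationStatus",
    "StructureDescriptor",
    "descriptor_from_mol",
    "roundtrip_validate",
    "StandardizationRule",
    "load_standardization_rules",
    "apply_standardization_rules",
    "merge_by_inchikey",
    "read_compound_csv",
    "write_rejection_report",
]


class Status(str, Enum):
    VALID = "valid"
    PROTONATED_ADJUSTED = "protonated_adjusted"
    TAUTOMER_FIXED = "tautomer_fixed"
    ROUNDTRIP_FAILED = "roundtrip_failed"
    MALFORMED = "malformed"


@dataclass(frozen=True)
class ValidationStatus:
    status: Status
    detail: str = ""


@dataclass(frozen=True)
class StructureDescriptor:
    """SMILES/InChI/InChIKey/MOL-block views of one structure.

    The MOL block carries 2D coordinates only.  When the descriptor is
    built through :func:`descriptor_from_mol` the four views are mutually
    consistent by construction.
    """

    inchi: str
    inchikey: str
    smiles: Optional[str] = None
    molblock: Optional[str] = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromMolBlock(self.molblock) if self.molblock else None
        if m is None:
            m = Chem.MolFromInchi(self.inchi)
        if m is None:
            raise ValueError(f"descriptor does not decode: {self.inchi!r}")
        return m


def descriptor_from_mol(mol: Chem.Mol) -> StructureDescriptor:
    """Canonical descriptor for a molecule: isomeric SMILES, InChI,
    InChIKey and a 2D MOL block that all describe the same graph."""
    m = Chem.Mol(mol)
    AllChem.Compute2DCoords(m)
    inchi = Chem.MolToInchi(m)
    return StructureDescriptor(
        inchi=inchi,
        inchikey=Chem.InchiToInchiKey(inchi),
        smiles=Chem.MolToSmiles(m),
        molblock=Chem.MolToMolBlock(m),
    )


def roundtrip_validate(d: StructureDescriptor) -> ValidationStatus:
    """Decode the InChI and re-encode it; statuses instead of exceptions.

    ``valid`` requires character-for-character identity of the regenerated
    InChI.  Stereo descriptors the decoder cannot represent (axial chirality
    of allenes/spirans) surface here as ``roundtrip_failed``.
    """
    if not d.inchi:
        return ValidationStatus(Status.MALFORMED, "no InChI")
    try:
        mol = Chem.MolFromInchi(d.inchi, treatWarningAsError=False)
    except Exception as exc:  # pragma: no cover - rdkit raises rarely here
        return ValidationStatus(Status.MALFORMED, f"decode error: {exc}")
    if mol is None:
        return ValidationStatus(Status.MALFORMED, "InChI does not decode")
    back = Chem.MolToInchi(mol)
    if back == d.inchi:
        return ValidationStatus(Status.VALID)
    return ValidationStatus(
        Status.ROUNDTRIP_FAILED, f"regenerated InChI differs: {back!r}"
    )


@dataclass(frozen=True)
class StandardizationRule:
    rule_id: str
    smirks: str
    comment: str = ""

    def reaction(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.smirks)
        if rxn is None:
            raise ValueError(f"rule {self.rule_id}: bad SMIRKS {self.smirks!r}")
        return rxn


def load_standardization_rules(path: Optional[Path] = None) -> List[StandardizationRule]:
    """Load the rule catalog (TSV: rule_id, smirks, comment), file order."""
    if path is None:
        text = resources.files("npderep.data").joinpath("standardization_rules.tsv").read_text()
    else:
        text = Path(path).read_text()
    rules = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed rule line: {line!r}")
        rule = StandardizationRule(parts[0], parts[1], parts[2] if len(parts) > 2 else "")
        rule.reaction()  # validate eagerly
        rules.append(rule)
    return rules


_MAX_PASSES = 20


def apply_standardization_rules(
    mol: Chem.Mol, rules: Sequence[StandardizationRule]
) -> Tuple[Chem.Mol, List[str]]:
    """Apply each rule in order, to exhaustion; idempotent overall.

    A rule whose product fails sanitization is reported by ID and skipped,
    leaving the input unchanged by that rule.
    """
    current = Chem.Mol(mol)
    applied: List[str] = []
    for rule in rules:
        rxn = rule.reaction()
        fired = False
        for _ in range(_MAX_PASSES):
            products = rxn.RunReactants((current,))
            if not products:
                break
            candidate = products[0][0]
            try:
                Chem.SanitizeMol(candidate)
            except Exception as exc:
                log.warning("rule %s produced invalid molecule: %s", rule.rule_id, exc)
                break
            current = candidate
            fired = True
        if fired:
            applied.append(rule.rule_id)
    return current, applied


def merge_by_inchikey(records: List) -> List:
    """Merge records sharing a (recalculated) full 27-character InChIKey.

    List-valued attributes (identifiers, names, CAS numbers, organisms,
    genera) are unioned preserving first-seen order; scalar attributes come
    from the first record of each collision group, conflicts are logged.
    Output order follows the first occurrence of each key.
    """
    by_key: Dict[str, List] = {}
    order: List[str] = []
    for rec in records:
        key = rec.structure.inchikey
        if key not in by_key:
            by_key[key] = []
            order.append(key)
        by_key[key].append(rec)

    out = []
    for key in order:
        group = by_key[key]
        head = group[0]
        if len(group) == 1:
            out.append(head)
            continue
        merged = head
        for other in group[1:]:
            if other.structure.inchi != head.structure.inchi:
                log.info(
                    "InChIKey collision %s with differing InChI; keeping first", key
                )
            merged = replace(
                merged,
                c_ids=_union(merged.c_ids, other.c_ids),
                names=_union(merged.names, other.names),
                cas=_union(merged.cas, other.cas),
                organisms=tuple(sorted(set(merged.organisms) | set(other.organisms))),
                genera=tuple(sorted(set(merged.genera) | set(other.genera))),
            )
        out.append(merged)
    return out


def _union(a: Sequence[str], b: Sequence[str]) -> Tuple[str, ...]:
    seen = dict.fromkeys(list(a) + list(b))
    return tuple(seen)


def read_compound_csv(path, delimiter: str = ",") -> List[Dict[str, str]]:
    """Read a simple compound table CSV (columns id, name, smiles, inchi)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"id", "name", "smiles", "inchi"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"compound CSV must have columns {sorted(required)}, got {reader.fieldnames}"
            )
        return [dict(row) for row in reader]


def write_rejection_report(path, rejected: Iterable[Tuple[str, ValidationStatus]]) -> None:
    """Tab-separated rejection report: record ID, status, detail."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec_id, vs in rejected:
            fh.write(f"{rec_id}\t{vs.status.value}\t{vs.detail}\n")
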