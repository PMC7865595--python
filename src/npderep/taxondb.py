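"""Taxonomy-focused compound-library construction.

Given a list of genera and a snapshot of a taxonomic compound database
(compound identifiers keyed by organism binomials, with names, formulas and
structure descriptors), this module assembles a validated, deduplicated,
organism-annotated library and writes it as an SDF file: the standard
workflow for building a chemotaxonomically focused dereplication database.

Each record is validated structurally (SMILES/InChI agreement, InChI
round-trip) and compositionally: the snapshot's formula text may lack the
charge indication or may be the [M+H]+ ion formula of the structure, and
both reconciliations are accepted, the latter storing the deduced neutral
formula.  Records with the same recalculated InChIKey are merged, pooling
their identifiers, names and source organisms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Protocol, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .chemclass import Catalog, ClassAssignment, classify
from .formula import MolecularFormula, neutral_from_protonated, parse_formula
from .nmr import ReferenceTable, ShiftPrediction, predict_carbon_shifts
from .structures import (
    Status,
    StructureDescriptor,
    ValidationStatus,
    descriptor_from_mol,
    merge_by_inchikey,
    write_rejection_report,
)

log = logging.getLogger(__name__)

__all__ = [
    "ProviderError",
    "TaxonSnapshot",
    "RawCompound",
    "CompoundRecord",
    "collect_genus",
    "validate_record",
    "build_library",
    "nitrogen_filter",
    "load_synonym_mapping",
    "attach_synonyms",
    "emit_library_sdf",
    "read_library_sdf",
    "read_genus_list",
]

_CID_RE = re.compile(r"^C\d{8}$")


class ProviderError(RuntimeError):
    """A retryable provider failure, naming the genus being queried."""


class TaxonSnapshot(Protocol):
    """Provider contract for a taxonomic compound database snapshot.

    Implementations must be deterministic for a fixed snapshot and must
    return an empty list (never raise) for an unknown genus.
    """

    def query_genus(self, genus: str) -> List[Tuple[str, str]]:
        """All (C_ID, organism binomial) pairs for a genus."""
        ...

    def fetch(self, c_id: str) -> "RawCompound":
        """The raw compound record for a compound identifier."""
        ...


@dataclass(frozen=True)
class RawCompound:
    """One unvalidated compound row as delivered by the provider."""

    c_id: str
    name: str
    formula_text: str
    mol_weight: float
    inchi: str
    inchikey: str
    smiles: str
    cas: Optional[str] = None

    def __post_init__(self) -> None:
        if not _CID_RE.match(self.c_id):
            raise ValueError(f"compound ID must match C########, got {self.c_id!r}")


@dataclass(frozen=True)
class CompoundRecord:
    """A validated library record: structure + identifiers + annotations."""

    structure: StructureDescriptor
    formula: MolecularFormula
    c_ids: Tuple[str, ...] = ()
    names: Tuple[str, ...] = ()
    cas: Tuple[str, ...] = ()
    organisms: Tuple[str, ...] = ()  # sorted unique binomials
    genera: Tuple[str, ...] = ()
    predictions: Tuple[ShiftPrediction, ...] = ()
    classes: Tuple[ClassAssignment, ...] = ()
    validation: ValidationStatus = ValidationStatus(Status.VALID)


def collect_genus(provider: TaxonSnapshot, genus: str) -> List[Tuple[str, str]]:
    """All (C_ID, binomial) pairs for one genus, duplicates preserved."""
    if not genus:
        raise ValueError("genus must be non-empty")
    try:
        return list(provider.query_genus(genus))
    except Exception as exc:
        raise ProviderError(f"provider failed for genus {genus!r}: {exc}") from exc


def _formula_from_mol(mol: Chem.Mol) -> MolecularFormula:
    return parse_formula(rdMolDescriptors.CalcMolFormula(mol))


def validate_record(raw: RawCompound) -> Tuple[Optional[CompoundRecord], ValidationStatus]:
    """Validate one raw compound into a library record.

    The structure is decoded from SMILES (InChI as fallback); the
    recalculated InChI must equal the given one, the InChI round-trip must
    be consistent, and the formula text must reconcile with the structure
    either exactly, ignoring a missing charge sign, or as the [M+H]+ ion
    formula (accepted with status ``protonated_adjusted`` and the neutral
    formula stored).  Failures return (None, status-with-reason).
    """
    mol = Chem.MolFromSmiles(raw.smiles) if raw.smiles else None
    if mol is None and raw.inchi:
        mol = Chem.MolFromInchi(raw.inchi)
    if mol is None:
        return None, ValidationStatus(Status.MALFORMED, "no decodable structure")

    desc = descriptor_from_mol(mol)
    if raw.inchi and desc.inchi != raw.inchi:
        return None, ValidationStatus(
            Status.ROUNDTRIP_FAILED,
            f"inchi_mismatch: recalculated {desc.inchi!r}",
        )
    # round-trip through the MOL block
    back = Chem.MolFromMolBlock(desc.molblock)
    if back is None or Chem.MolToInchi(back) != desc.inchi:
        return None, ValidationStatus(Status.ROUNDTRIP_FAILED, "MOL-block round trip failed")

    computed = _formula_from_mol(mol)
    try:
        given = parse_formula(raw.formula_text)
    except Exception as exc:
        return None, ValidationStatus(Status.MALFORMED, f"formula unparsable: {exc}")

    status = ValidationStatus(Status.VALID)
    stored = computed
    if given.counts == computed.counts and given.charge == computed.charge:
        pass
    elif given.counts == computed.counts:
        status = ValidationStatus(Status.VALID, "charge indication missing in source formula")
    else:
        # [M+H]+ reconciliation: the source formula is the protonated ion
        ion = MolecularFormula.from_counts(
            {**given.as_dict()}, charge=1 if given.charge == 0 else given.charge
        )
        try:
            neutral = neutral_from_protonated(ion)
        except ValueError:
            neutral = None
        if neutral is not None and neutral.counts == computed.counts:
            status = ValidationStatus(
                Status.PROTONATED_ADJUSTED,
                f"source formula {raw.formula_text} read as [M+H]+; neutral {computed} stored",
            )
        else:
            return None, ValidationStatus(
                Status.MALFORMED,
                f"formula_mismatch: source {raw.formula_text}, computed {computed}",
            )

    record = CompoundRecord(
        structure=desc,
        formula=stored,
        c_ids=(raw.c_id,),
        names=(raw.name,) if raw.name else (),
        cas=(raw.cas,) if raw.cas else (),
        validation=status,
    )
    return record, status


def build_library(
    provider: TaxonSnapshot,
    genera: Sequence[str],
    table: Optional[ReferenceTable] = None,
    catalog: Optional[Catalog] = None,
    rejection_path: Optional[Path] = None,
) -> List[CompoundRecord]:
    """The full library workflow for a list of genera.

    collect → fetch → validate → merge by InChIKey → attach organisms and
    genera → attach predicted shifts (when a reference table is given) →
    attach class assignments (when a catalog is given).  Output is sorted
    by InChIKey, making the build a pure function of (snapshot, genera).
    An all-rejected input yields an empty library and a populated
    rejection report, not an exception.
    """
    if not genera:
        raise ValueError("genera list must be non-empty")

    organisms_by_cid: Dict[str, List[str]] = {}
    genera_by_cid: Dict[str, List[str]] = {}
    order: List[str] = []
    for genus in genera:
        for c_id, binomial in collect_genus(provider, genus):
            organisms_by_cid.setdefault(c_id, []).append(binomial)
            genera_by_cid.setdefault(c_id, []).append(genus)
            if c_id not in order:
                order.append(c_id)

    records: List[CompoundRecord] = []
    rejected: List[Tuple[str, ValidationStatus]] = []
    for c_id in order:
        raw = provider.fetch(c_id)
        rec, status = validate_record(raw)
        if rec is None:
            rejected.append((c_id, status))
            continue
        rec = replace(
            rec,
            organisms=tuple(sorted(set(organisms_by_cid[c_id]))),
            genera=tuple(sorted(set(genera_by_cid[c_id]))),
        )
        records.append(rec)

    records = merge_by_inchikey(records)
    records.sort(key=lambda r: r.structure.inchikey)

    if table is not None:
        records = [
            replace(
                rec,
                predictions=tuple(
                    replace(p, delta_c=round(p.delta_c, 2))
                    for p in predict_carbon_shifts(rec.structure.mol(), table)
                ),
            )
            for rec in records
        ]
    if catalog is not None:
        records = [
            replace(rec, classes=tuple(classify(rec.structure.mol(), catalog)))
            for rec in records
        ]

    if rejection_path is not None:
        write_rejection_report(rejection_path, rejected)
    elif rejected:
        for c_id, status in rejected:
            log.info("rejected %s: %s %s", c_id, status.status.value, status.detail)
    return records


def nitrogen_filter(records: Sequence[CompoundRecord]) -> List[CompoundRecord]:
    """Keep records with at least one nitrogen (possible alkaloids)."""
    return [r for r in records if r.formula.count("N") >= 1]


def load_synonym_mapping(path: Path) -> Dict[str, List[str]]:
    """Two-column file (InChIKey TAB synonym); duplicate keys union."""
    mapping: Dict[str, List[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                log.warning("skipping malformed synonym line %d: %r", lineno, line)
                continue
            bucket = mapping.setdefault(parts[0], [])
            if parts[1] not in bucket:
                bucket.append(parts[1])
    return mapping


def attach_synonyms(
    records: Sequence[CompoundRecord], mapping: Mapping[str, List[str]]
) -> List[CompoundRecord]:
    """Extend record names with synonyms, original names kept first."""
    out = []
    for rec in records:
        syns = mapping.get(rec.structure.inchikey)
        if syns:
            names = list(dict.fromkeys(list(rec.names) + list(syns)))
            rec = replace(rec, names=tuple(names))
        out.append(rec)
    return out


# --- SDF serialization -----------------------------------------------------

_LIST_SEP = ";"


def _serialize_predictions(preds: Sequence[ShiftPrediction]) -> Tuple[str, str]:
    triplets = _LIST_SEP.join(f"{p.atom_index}:{p.delta_c:.2f}:{p.n_h}" for p in preds)
    spheres = _LIST_SEP.join(f"{p.atom_index}:{p.sphere_used}" for p in preds)
    return triplets, spheres


def _parse_predictions(triplets: str, spheres: str) -> Tuple[ShiftPrediction, ...]:
    if not triplets:
        return ()
    sphere_map = {}
    if spheres:
        for tok in spheres.split(_LIST_SEP):
            i, s = tok.split(":")
            sphere_map[int(i)] = int(s)
    preds = []
    for tok in triplets.split(_LIST_SEP):
        i, d, h = tok.split(":")
        preds.append(ShiftPrediction(int(i), float(d), int(h), sphere_map.get(int(i), 0)))
    return tuple(preds)


def _serialize_classes(classes: Sequence[ClassAssignment]) -> str:
    items = []
    for c in classes:
        atoms = "|".join(".".join(str(a) for a in m) for m in c.matched_atoms)
        items.append(f"{c.class_id}@{c.pattern_used}:{atoms}")
    return _LIST_SEP.join(items)


def _parse_classes(text: str) -> Tuple[ClassAssignment, ...]:
    if not text:
        return ()
    out = []
    for item in text.split(_LIST_SEP):
        head, atoms = item.split(":", 1)
        class_id, pat = head.rsplit("@", 1)
        matched = tuple(
            tuple(int(a) for a in m.split(".") if a) for m in atoms.split("|") if m
        )
        out.append(ClassAssignment(class_id, matched, int(pat)))
    return tuple(out)


def emit_library_sdf(records: Sequence[CompoundRecord], path: Path) -> None:
    """Write the library as a V2000 SDF with the tag schema of the toolkit.

    Tags: KS_CID, NAME, CAS, ORGANISMS, GENERA, MOLECULAR_FORMULA, INCHI,
    INCHIKEY, PREDICTED_13C (``atomIndex:shift:nH`` triplets, 0-based
    indices, 2-decimal shifts), PREDICTED_13C_SPHERES, CLASSES, VALIDATION.
    ``read_library_sdf(emit_library_sdf(x)) == x`` field for field.
    """
    path = Path(path)
    if not records:
        path.write_text("")  # empty library: empty SDF
        return
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.MolFromMolBlock(rec.structure.molblock)
            if mol is None:  # pragma: no cover - emitted records always decode
                raise ValueError(f"record {rec.structure.inchikey} has a bad MOL block")
            mol.SetProp("_Name", rec.names[0] if rec.names else rec.structure.inchikey)
            mol.SetProp("KS_CID", _LIST_SEP.join(rec.c_ids))
            mol.SetProp("NAME", _LIST_SEP.join(rec.names))
            mol.SetProp("CAS", _LIST_SEP.join(rec.cas))
            mol.SetProp("ORGANISMS", _LIST_SEP.join(rec.organisms))
            mol.SetProp("GENERA", _LIST_SEP.join(rec.genera))
            mol.SetProp("MOLECULAR_FORMULA", str(rec.formula))
            mol.SetProp("INCHI", rec.structure.inchi)
            mol.SetProp("INCHIKEY", rec.structure.inchikey)
            triplets, spheres = _serialize_predictions(rec.predictions)
            mol.SetProp("PREDICTED_13C", triplets)
            mol.SetProp("PREDICTED_13C_SPHERES", spheres)
            mol.SetProp("CLASSES", _serialize_classes(rec.classes))
            mol.SetProp(
                "VALIDATION", f"{rec.validation.status.value}:{rec.validation.detail}"
            )
            writer.write(mol)
    finally:
        writer.close()


def read_library_sdf(path: Path) -> List[CompoundRecord]:
    """Read a library SDF written by :func:`emit_library_sdf`."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for mol in supplier:
        if mol is None:
            raise ValueError(f"{path}: unreadable SDF record")

        def tag(name: str) -> str:
            return mol.GetProp(name) if mol.HasProp(name) else ""

        def taglist(name: str) -> Tuple[str, ...]:
            t = tag(name)
            return tuple(t.split(_LIST_SEP)) if t else ()

        status_text = tag("VALIDATION")
        status, _, detail = status_text.partition(":")
        inchi = tag("INCHI")
        # the SDF title line carries the display name; the descriptor's MOL
        # block is name-free, so strip it before regenerating
        if mol.HasProp("_Name"):
            mol.ClearProp("_Name")
        desc = StructureDescriptor(
            inchi=inchi,
            inchikey=tag("INCHIKEY"),
            smiles=Chem.MolToSmiles(mol),
            molblock=Chem.MolToMolBlock(mol),
        )
        out.append(
            CompoundRecord(
                structure=desc,
                formula=parse_formula(tag("MOLECULAR_FORMULA")),
                c_ids=taglist("KS_CID"),
                names=taglist("NAME"),
                cas=taglist("CAS"),
                organisms=taglist("ORGANISMS"),
                genera=taglist("GENERA"),
                predictions=_parse_predictions(
                    tag("PREDICTED_13C"), tag("PREDICTED_13C_SPHERES")
                ),
                classes=_parse_classes(tag("CLASSES")),
                validation=ValidationStatus(Status(status), detail)
                if status
                else ValidationStatus(Status.VALID),
            )
        )
    return out


def read_genus_list(path: Path) -> List[str]:
    """Genus-list config: one genus per line, '#' comments allowed."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out
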