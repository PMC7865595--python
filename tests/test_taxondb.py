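"""Library building: collection, validation, merging, SDF round trips."""

from dataclasses import replace

import pytest
from rdkit import Chem

from conftest import mol
from npderep.fixtures import (
    ALKALOIDS,
    FixtureSpec,
    SnapshotFixture,
    generate_snapshot,
    worked_example_snapshot,
)
from npderep.structures import Status
from npderep.taxondb import (
    ProviderError,
    RawCompound,
    attach_synonyms,
    build_library,
    collect_genus,
    emit_library_sdf,
    load_synonym_mapping,
    nitrogen_filter,
    read_library_sdf,
    validate_record,
)


@pytest.fixture(scope="module")
def snapshot():
    return worked_example_snapshot()


@pytest.fixture(scope="module")
def small_spec():
    return FixtureSpec(
        n_genera=3, species_per_genus=1, compounds_per_species=3,
        collision_count=1, protonated_count=2, seed=42,
        include_reference_genera=False,
    )


def _raw(smiles: str, name="thing", c_id="C00000001", formula=None, inchi=None):
    m = mol(smiles)
    from rdkit.Chem import Descriptors, rdMolDescriptors

    real_inchi = Chem.MolToInchi(m)
    return RawCompound(
        c_id=c_id,
        name=name,
        formula_text=formula or rdMolDescriptors.CalcMolFormula(m),
        mol_weight=round(Descriptors.MolWt(m), 2),
        inchi=inchi or real_inchi,
        inchikey=Chem.InchiToInchiKey(real_inchi),
        smiles=smiles,
    )


class TestCollectGenus:
    def test_galanthus_pairs(self, snapshot):
        pairs = collect_genus(snapshot, "Galanthus")
        assert len(pairs) >= 5
        assert any(cid == "C00001570" for cid, _ in pairs)
        assert all(binomial.startswith("Galanthus ") for _, binomial in pairs)

    def test_unknown_genus_empty(self, snapshot):
        assert collect_genus(snapshot, "Nosuchus") == []

    def test_compound_in_two_species_gives_two_pairs(self, snapshot):
        pairs = collect_genus(snapshot, "Galanthus")
        galanthamine = [p for p in pairs if p[0] == "C00001570"]
        assert len(galanthamine) == 2
        assert len({sp for _, sp in galanthamine}) == 2

    def test_provider_failure_names_genus(self):
        class Broken:
            def query_genus(self, genus):
                raise OSError("boom")

        with pytest.raises(ProviderError, match="Galanthus"):
            collect_genus(Broken(), "Galanthus")

    def test_empty_genus_rejected(self, snapshot):
        with pytest.raises(ValueError):
            collect_genus(snapshot, "")


class TestValidateRecord:
    def test_consistent_record_is_valid(self):
        rec, status = validate_record(_raw("CCO", "ethanol"))
        assert rec is not None
        assert status.status is Status.VALID
        assert str(rec.formula) == "C2H6O"

    def test_protonated_formula_adjusted(self):
        # source formula is the [M+H]+ ion formula, charge sign left out
        rec, status = validate_record(_raw("c1ccccc1", "benzene", formula="C6H7"))
        assert rec is not None
        assert status.status is Status.PROTONATED_ADJUSTED
        assert str(rec.formula) == "C6H6"  # neutral deduced and stored

    def test_inchi_mismatch_rejected(self):
        wrong = Chem.MolToInchi(mol("CCN"))
        rec, status = validate_record(_raw("CCO", inchi=wrong))
        assert rec is None
        assert "inchi_mismatch" in status.detail

    def test_irreconcilable_formula_rejected(self):
        rec, status = validate_record(_raw("CCO", formula="C5H5N5"))
        assert rec is None
        assert "formula_mismatch" in status.detail

    def test_undecodable_structure_rejected(self):
        raw = RawCompound(
            c_id="C00000009", name="junk", formula_text="C2H6O",
            mol_weight=46.07, inchi="", inchikey="", smiles="not_a_smiles",
        )
        rec, status = validate_record(raw)
        assert rec is None
        assert status.status is Status.MALFORMED


class TestBuildLibrary:
    def test_collision_merges_to_nine_records(self, small_spec):
        snap = generate_snapshot(small_spec)
        records = build_library(snap, snap.genera)
        assert len(records) == 9  # 10 rows, one forced InChIKey collision
        assert len({r.structure.inchikey for r in records}) == 9

    def test_deterministic_sdf_bytes(self, small_spec, tmp_path):
        snap = generate_snapshot(small_spec)
        p1, p2 = tmp_path / "a.sdf", tmp_path / "b.sdf"
        emit_library_sdf(build_library(snap, snap.genera), p1)
        emit_library_sdf(build_library(snap, snap.genera), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_genus_empty_library_and_report(self, snapshot, tmp_path):
        report = tmp_path / "rejects.tsv"
        records = build_library(snapshot, ["Nosuchus"], rejection_path=report)
        assert records == []
        assert report.read_text() == ""

    def test_emitted_records_internally_consistent(self, bundle):
        keys = [r.structure.inchikey for r in bundle.records]
        assert len(set(keys)) == len(keys)
        assert keys == sorted(keys)
        for rec in bundle.records[::7]:
            back = Chem.MolFromMolBlock(rec.structure.molblock)
            assert Chem.MolToInchi(back) == rec.structure.inchi
            assert rec.organisms  # taxon-built records always carry organisms
            for org in rec.organisms:
                assert org.split()[0] in rec.genera

    def test_empty_genera_rejected(self, snapshot):
        with pytest.raises(ValueError):
            build_library(snapshot, [])


class TestNitrogenFilter:
    def test_keeps_possible_alkaloids(self, bundle):
        kept = nitrogen_filter(list(bundle.records))
        names = {n for r in kept for n in r.names}
        assert "crinine" in names
        assert "menthol" not in names

    def test_subset_order_preserving_idempotent(self, bundle):
        records = list(bundle.records)
        kept = nitrogen_filter(records)
        assert [r.structure.inchikey for r in kept] == [
            r.structure.inchikey for r in records if r in kept
        ]
        assert nitrogen_filter(kept) == kept
        assert nitrogen_filter([]) == []


class TestSynonyms:
    def test_attach_and_union(self, tmp_path, bundle):
        rec = bundle.records[0]
        key = rec.structure.inchikey
        mapping_file = tmp_path / "syn.tsv"
        mapping_file.write_text(
            f"{key}\tfirst synonym\n"
            f"{key}\tsecond synonym\n"
            f"{key}\tfirst synonym\n"  # duplicate line unions away
            "BADLINE\n"
        )
        mapping = load_synonym_mapping(mapping_file)
        assert mapping[key] == ["first synonym", "second synonym"]
        out = attach_synonyms([rec], mapping)
        assert out[0].names[: len(rec.names)] == rec.names
        assert "first synonym" in out[0].names

    def test_empty_mapping_is_identity(self, bundle):
        records = list(bundle.records[:3])
        assert attach_synonyms(records, {}) == records


class TestSdfRoundTrip:
    def test_full_library_roundtrip(self, bundle, tmp_path):
        path = tmp_path / "lib.sdf"
        emit_library_sdf(list(bundle.records), path)
        assert read_library_sdf(path) == list(bundle.records)

    def test_empty_library(self, tmp_path):
        path = tmp_path / "empty.sdf"
        emit_library_sdf([], path)
        assert read_library_sdf(path) == []

    def test_expected_tags_present(self, bundle, tmp_path):
        path = tmp_path / "lib.sdf"
        emit_library_sdf(list(bundle.records)[:1], path)
        text = path.read_text()
        for tag in ("KS_CID", "NAME", "ORGANISMS", "GENERA", "MOLECULAR_FORMULA",
                    "INCHI", "INCHIKEY", "PREDICTED_13C", "CLASSES"):
            assert f"<{tag}>" in text


class TestSnapshotSerialization:
    def test_json_roundtrip(self, small_spec, tmp_path):
        snap = generate_snapshot(small_spec)
        path = tmp_path / "snap.json"
        snap.to_json(path)
        back = SnapshotFixture.from_json(path)
        assert back.genera == snap.genera
        for genus in snap.genera:
            assert back.query_genus(genus) == snap.query_genus(genus)
            for cid, _ in snap.query_genus(genus):
                assert back.fetch(cid) == snap.fetch(cid)
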