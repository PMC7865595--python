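import pytest
from rdkit import Chem

from npderep.chemclass import load_catalog, load_skeletons
from npderep.fixtures import worked_example_bundle
from npderep.structures import load_standardization_rules


@pytest.fixture(scope="session")
def bundle():
    return worked_example_bundle()


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def skeletons():
    return load_skeletons()


@pytest.fixture(scope="session")
def rules():
    return load_standardization_rules()


def mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, f"fixture SMILES failed to parse: {smiles}"
    return m
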