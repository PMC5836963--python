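import pytest

from fragspace import MoleculeRecord, builtin_ruleset
from fragspace.fixtures import drug_like_library, worked_examples


@pytest.fixture(scope="session")
def recap():
    return builtin_ruleset("RECAP")


@pytest.fixture(scope="session")
def brics():
    return builtin_ruleset("BRICS")


@pytest.fixture(scope="session")
def ccq():
    return builtin_ruleset("CCQ")


@pytest.fixture(scope="session")
def extended_recap():
    return builtin_ruleset("extendedRECAP")


@pytest.fixture(scope="session")
def examples():
    fx = worked_examples()
    return {cid: MoleculeRecord.from_smiles(smi, cid) for cid, smi in fx.molecules}


@pytest.fixture(scope="session")
def library_records():
    fx = drug_like_library()
    return [MoleculeRecord.from_smiles(smi, cid) for cid, smi in fx.molecules]
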