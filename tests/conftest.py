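import pytest
from rdkit import Chem

from somrx import database, fixtures
from somrx.som_annotation import annotate_dataset


@pytest.fixture(scope="session")
def manifest():
    """Small deterministic fixture corpus shared across the suite."""
    return fixtures.generate_dataset(seed=7, n_per_class=10)


@pytest.fixture(scope="session")
def fixture_db(manifest):
    """Databases built on the fixture training split."""
    train = manifest.training_records
    annotations, _ = annotate_dataset(train, manifest.patterns)
    return database.build_databases(train, annotations, manifest.patterns)


@pytest.fixture(scope="session")
def holdout(manifest):
    """(molecules, truth SOM sets) for the fixture holdout split."""
    mols, truth = {}, {}
    for rec in manifest.holdout_records:
        mols[rec.record_id] = Chem.MolFromSmiles(
            rec.reaction_smiles.split(">>")[0])
        truth[rec.record_id] = set(rec.som_atoms)
    return mols, truth


@pytest.fixture
def anisole():
    return Chem.MolFromSmiles("COc1ccccc1")
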