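import io
import random

import pytest

from minitox.chemgraph import canonical_smiles, parse_smiles
from minitox.datastore.csvio import ingest_training_csv
from minitox.datastore.store import DataStore
from minitox.fixtures import FixtureSpec, generate_classification_fixture


@pytest.fixture
def store():
    return DataStore()


@pytest.fixture
def small_csv_result():
    csv = (
        "smiles,activity\n"
        "CCO,active\n"
        "CCC,inactive\n"
        "CCCC,inactive\n"
        "CC(C)O,active\n"
        "CCCCC,inactive\n"
        "CCOC,active\n"
    )
    return ingest_training_csv(io.StringIO(csv), dataset_uri="urn:test:dataset/1")


@pytest.fixture(scope="session")
def cls_fixture_60():
    """Noise-free planted-signal dataset, reused across tests (read-only)."""
    return generate_classification_fixture(FixtureSpec(n=60, seed=11))


def random_subset_smiles(rng: random.Random, max_heavy: int = 12) -> str:
    """Small random molecule from the same grammar family the parser accepts."""
    parts = []
    if rng.random() < 0.3:
        parts.append("c1ccccc1")
    n = rng.randint(1, max(1, max_heavy - 6 * len(parts)))
    for i in range(n):
        parts.append(rng.choice(["C", "C", "C", "O", "N", "S"]))
        if parts[-1] == "C" and rng.random() < 0.25:
            parts.append(rng.choice(["(C)", "(CC)", "(=O)", "(Cl)", "(Br)"]))
    smiles = "".join(parts)
    # guarantee parseability by construction; canonicalize defensively
    return canonical_smiles(parse_smiles(smiles))
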