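import numpy as np
import pytest

from oculotox.descriptors import compute_block
from oculotox.fixtures import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def planted_dataset():
    """Balanced planted-toxophore set, n=400, 10% label noise, seeded."""
    records, manifest = generate_fixture(
        FixtureConfig(n_compounds=400, noise_rate=0.1, rng_seed=7))
    return records, manifest


@pytest.fixture(scope="session")
def planted_blocks(planted_dataset):
    records, _ = planted_dataset
    labels = [r.label for r in records]
    blocks = {s: compute_block(records, s) for s in ("MORGAN", "KEYS166")}
    return blocks, labels


@pytest.fixture
def rng():
    return np.random.default_rng(42)
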