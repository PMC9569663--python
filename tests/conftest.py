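import numpy as np
import pytest

import kinogen as kg
from kinogen.molecules import Family


@pytest.fixture(scope="session")
def scaffold_library():
    """Three scaffold families, 30 molecules each: the decoder's candidate pool."""
    return kg.synthetic_data.make_scaffold_families(n_families=3, per_family_n=30, seed=0)


@pytest.fixture(scope="session")
def seed_sets(scaffold_library):
    """Per-family seed molecules: the first 10 of each family."""
    return {fam: recs[:10] for fam, recs in scaffold_library.items()}


@pytest.fixture(scope="session")
def library_records(scaffold_library):
    return [r for recs in scaffold_library.values() for r in recs]


@pytest.fixture(scope="session")
def surrogate(library_records):
    """Session-wide surrogate embedder over the full scaffold library."""
    return kg.SurrogateEmbedder(library_records)


@pytest.fixture(scope="session")
def library_latent(surrogate, library_records):
    return surrogate.encode(library_records)


class FixedDecoder:
    """Stub decoder that always returns one fixed string."""

    d = 196

    def __init__(self, smiles: str):
        self.smiles = smiles

    def decode_attempt(self, z, rng):
        return self.smiles


class BernoulliDecoder:
    """Stub decoder: valid fixed 12-char SMILES with probability p, else garbage."""

    d = 196

    def __init__(self, p: float, smiles: str = "CCCCCCCCCCCC"):
        assert len(smiles) == 12
        self.p = p
        self.smiles = smiles

    def decode_attempt(self, z, rng):
        return self.smiles if rng.random() < self.p else "C1CC"


@pytest.fixture
def fixed_decoder():
    return FixedDecoder("CCCCCCCCCCCC")


@pytest.fixture
def garbage_decoder():
    return FixedDecoder("not-a-smiles(((")


@pytest.fixture
def bernoulli_decoder():
    return BernoulliDecoder(0.21)
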