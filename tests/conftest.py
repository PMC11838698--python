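import itertools

import numpy as np
import pytest

from coscreen.featurizers import (
    EmbeddingProvider,
    ToyEmbedder,
    embed_residues,
    unregister_provider,
)
from coscreen.model import DTICoEmbedder, ModelConfig

_counter = itertools.count()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def fresh_provider_name():
    """A provider name unique to this test, cleaned up afterwards."""
    name = f"test_provider_{next(_counter)}"
    yield name
    unregister_provider(name)


@pytest.fixture(scope="session")
def toy_embedder():
    """Unregistered toy embedder instance (E=32, k=3, seed=0)."""
    return ToyEmbedder(width=32, k=3, seed=0)


@pytest.fixture(scope="session")
def toy_provider(toy_embedder):
    return EmbeddingProvider(name="toy_session", fn=toy_embedder, width=32)


@pytest.fixture
def small_model():
    config = ModelConfig(
        alpha=5.0,
        n_heads=4,
        d=32,
        drug_depth=3,
        target_depth=3,
        n_bits=64,
        embed_width=32,
        key_width=8,
        value_width=8,
        seed=0,
    )
    return DTICoEmbedder(config)


def embed_sequences(sequences, provider):
    """Helper: target_id -> residue-embedding matrix for plain sequences."""
    from coscreen.featurizers import TargetRecord

    out = {}
    for i, seq in enumerate(sequences):
        rec = TargetRecord(target_id=f"t{i}", sequence=seq)
        out[rec.target_id] = embed_residues(rec, provider).values
    return out
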