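"""Shared fixtures: small synthetic corpora and trained embedding models.

Heavy artefacts (generated corpus, trained models, the full recovery report)
are session-scoped so the suite trains each model exactly once.
"""

import numpy as np
import pytest

from pwas.corpus import build_vocabulary
from pwas.synthetic import SyntheticConfig, generate_corpus
from pwas.word2vec import EmbeddingHyperparams, EmbeddingModel, train_embeddings


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def default_corpus(default_cfg):
    return generate_corpus(default_cfg)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A reduced corpus for unit tests that only need plausible structure."""
    return SyntheticConfig(seed=3, n_genes=60, n_diseases=3, n_compounds=6,
                           year_start=2002, year_end=2010, docs_per_year=150,
                           n_planted_associations=3,
                           emergence_years=(2008, 2009, 2010),
                           model_years=(2006, 2007, 2008),
                           ppi_eras=(2006, 2008, 2010),
                           n_pathways=4, pathway_size=5,
                           background_vocab_size=2000)


@pytest.fixture(scope="session")
def small_corpus(small_cfg):
    return generate_corpus(small_cfg)


@pytest.fixture(scope="session")
def topic_model() -> EmbeddingModel:
    """CBOW model over two disjoint topic blocks (a*, b*), 20 tokens."""
    rng = np.random.default_rng(11)
    blocks = [[f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)]]
    docs = [list(rng.choice(blocks[rng.integers(0, 2)], 12)) for _ in range(400)]
    vocab = build_vocabulary(docs, min_count=10)
    hp = EmbeddingHyperparams(dim=32, window=5, epochs=20, seed=5,
                              subsample_threshold=1e-2)
    return train_embeddings(docs, vocab, hp)


@pytest.fixture()
def constructed_model() -> EmbeddingModel:
    """Hand-built vectors for exact similarity/analogy arithmetic."""
    vocab = ["a", "b", "c", "d", "e", "f"]
    vecs = np.array([
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, 0.0],
        [-1.0, 1.0, 1.0, 0.0],  # = b - a + c
        [0.5, 0.5, 0.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ])
    return EmbeddingModel(cutoff_year=2000, vocabulary=vocab, vectors=vecs,
                          hyperparams=EmbeddingHyperparams(dim=4))
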