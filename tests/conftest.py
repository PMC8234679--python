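import numpy as np
import pytest

from archeq import (
    Archetype,
    ArchetypeIndex,
    EmbeddingModel,
    MaxMatchTokenizer,
    default_synonym_spec,
    generate_corpus,
    generate_index,
    lexicon_for,
    train_embeddings,
)


@pytest.fixture(scope="session")
def synonym_spec():
    """The standard planted-synonym study conditions (2,000 sentences)."""
    return default_synonym_spec(seed=7)


@pytest.fixture(scope="session")
def planted_corpus(synonym_spec):
    return generate_corpus(synonym_spec)


@pytest.fixture(scope="session")
def trained_model(planted_corpus):
    """One skip-gram model at the default training conditions, shared
    across tests (training is the expensive step)."""
    return train_embeddings(planted_corpus, seed=7)


@pytest.fixture(scope="session")
def synthetic_index(synonym_spec):
    return generate_index(synonym_spec.base_vocabulary, 50, seed=11)


@pytest.fixture(scope="session")
def synthetic_tokenizer(synonym_spec):
    return MaxMatchTokenizer(lexicon_for(synonym_spec))


@pytest.fixture
def toy_index():
    """A small handcrafted English index, including the classic lay-term
    miss: an archetype named 'fetal heartrate' that the query 'fetal
    heartbeat' cannot reach by substring match."""
    return ArchetypeIndex.from_records(
        [
            Archetype(
                "openEHR-EHR-OBSERVATION.fetal_heart.v1",
                "Fetal heartrate",
                language="en",
                description="Monitoring of the fetal heart",
            ),
            Archetype(
                "openEHR-EHR-COMPOSITION.health_summary.v1",
                "Health summary",
                language="en",
                keywords=("summary", "overview"),
            ),
            Archetype(
                "openEHR-EHR-EVALUATION.adverse_reaction.v1",
                "Adverse reaction risk",
                language="en",
            ),
        ]
    )


def make_random_model(n_vocab: int, dim: int, seed: int) -> EmbeddingModel:
    """A model with random Gaussian vectors, for oracle comparisons."""
    rng = np.random.default_rng(seed)
    tokens = [f"w{i:03d}" for i in range(n_vocab)]
    return EmbeddingModel(
        vocabulary={t: i for i, t in enumerate(tokens)},
        vectors=rng.normal(size=(n_vocab, dim)),
    )
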