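import numpy as np
import pytest

from litmap import SyntheticSpec, generate_cluster_embeddings, generate_corpus


@pytest.fixture(scope="session")
def default_generated():
    """A 3-topic, 600-record synthetic corpus with planted metadata and a
    handful of invalid records for the curation filters."""
    return generate_corpus(
        SyntheticSpec(n_topics=3, docs_per_topic=200, seed=1,
                      n_invalid_records=6)
    )


@pytest.fixture(scope="session")
def default_corpus(default_generated):
    return default_generated.corpus


@pytest.fixture(scope="session")
def default_ledger(default_generated):
    return default_generated.ledger


@pytest.fixture(scope="session")
def cluster_embeddings_matrix(default_ledger):
    """Planted 768-d Gaussian cluster embeddings aligned to the corpus."""
    return generate_cluster_embeddings(
        default_ledger, d=768, separation=10.0, seed=2
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
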