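import numpy as np
import pytest

import litaxis as lx


@pytest.fixture(scope="session")
def default_corpus():
    """Reference simulated corpus: 3 disjoint-pool topics x 20 docs, seed 7."""
    records, truth = lx.generate_corpus(lx.default_corpus_config(seed=7))
    return records, truth


@pytest.fixture(scope="session")
def default_docs(default_corpus):
    records, _ = default_corpus
    docs = lx.clean_corpus(records)
    vocab, docs = lx.build_vocabulary(docs, min_count=2)
    return docs, vocab


@pytest.fixture(scope="session")
def default_assignment(default_docs):
    docs, _ = default_docs
    E = lx.embed_documents(docs, dim=16, seed=0)
    assignment = lx.cluster_documents(E, K=3, noise_quantile=0.0, seed=0)
    return E, assignment


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
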