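import numpy as np
import pytest

from prip import embed, simdata


@pytest.fixture(scope="session")
def small_chains():
    """A small labeled synthetic dataset shared across tests."""
    return simdata.generate(
        simdata.SimConfig(n_chains=30, length_range=(40, 60), seed=42)
    )


@pytest.fixture(scope="session")
def tiny_dictionary(small_chains):
    """A quickly trained low-dimensional semantic dictionary."""
    corpus = embed.tokenize_corpus(small_chains)
    return embed.train(corpus, embed.EmbeddingParams(dim=8, epochs=20, seed=7))
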