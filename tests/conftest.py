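import numpy as np
import pytest

from readrank.corpus_io import Document, EasyWordList, RatingRecord
from readrank.embeddings import EmbeddingModel
from readrank.text_features import tokenize
from readrank import synthetic_data as sd


def make_doc(text, doc_id="d0", source="wikipedia", topic="cancer", tokenized=True):
    doc = Document(doc_id=doc_id, text=text, source=source, topic=topic)
    return tokenize(doc) if tokenized else doc


@pytest.fixture
def easy_list():
    return EasyWordList(frozenset({"the", "cat", "sat", "on", "mat", "window", "a"}))


@pytest.fixture(scope="session")
def tiny_study():
    """Shared noiseless tiny study: (docs, latent, ratings, split)."""
    return sd.generate_study(sd.preset("tiny", seed=11))


@pytest.fixture(scope="session")
def default_study():
    """Default-preset study with mild noise, shared across tests."""
    return sd.generate_study(sd.preset("default", seed=7, noise_sd=0.3))


@pytest.fixture
def stub_embedding():
    """Deterministic toy embedding model factory."""

    def build(tokens, dim=4, source_tag="wikipedia", seed=0):
        rng = np.random.default_rng(seed)
        return EmbeddingModel(
            source_tag=source_tag,
            dim=dim,
            vectors={t: rng.normal(size=dim) for t in tokens},
        )

    return build


def ratings_from(rows):
    """rows: (rater, pair, doc, rating) tuples -> RatingRecord list."""
    return [RatingRecord(*r) for r in rows]
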