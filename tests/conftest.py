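"""Shared fixtures: tiny deterministic corpora, embeddings, and a small synthetic spec."""

import numpy as np
import pytest

from semiada import (
    Corpus,
    Document,
    EmbeddingTable,
    ReferenceClassifier,
    StopWordList,
    SyntheticSpec,
    TrainingConfig,
    train_reference,
)
from semiada.synthetic import geometric_sizes


@pytest.fixture
def tiny_corpus() -> Corpus:
    docs = (
        Document("d1", ("stomach", "pain", "severe"), "gastro"),
        Document("d2", ("stomach", "ache", "mild"), "gastro"),
        Document("d3", ("foot", "pain", "severe"), "podiatry"),
        Document("d4", ("foot", "sprain", "mild"), "podiatry"),
    )
    return Corpus(docs, ("gastro", "podiatry"), name="tiny")


@pytest.fixture
def stoplist() -> StopWordList:
    return StopWordList(frozenset({"the", "then", "a"}), source_tag="test")


def _separable_embeddings(dim: int = 6) -> EmbeddingTable:
    rng = np.random.default_rng(7)
    vectors = {w: rng.standard_normal(dim) * 0.1 for w in
               ("pain", "severe", "mild", "ache", "sprain")}
    vectors["stomach"] = np.eye(dim)[0] * 3.0
    vectors["foot"] = np.eye(dim)[1] * 3.0
    return EmbeddingTable(vectors, mask_vector=np.zeros(dim))


@pytest.fixture
def separable_embeddings() -> EmbeddingTable:
    return _separable_embeddings()


@pytest.fixture
def separable_model(tiny_corpus, separable_embeddings) -> ReferenceClassifier:
    """Trained on a linearly separable toy: one signature token per class."""
    return train_reference(
        tiny_corpus, separable_embeddings, TrainingConfig(learning_rate=2.0, epochs=300, seed=0)
    )


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A fast, scaled-down version of the synthetic study conditions."""
    return SyntheticSpec(
        n_classes=5,
        class_sizes=geometric_sizes(5, 40, 10),
        vocab_size=400,
        signature_words_per_class=8,
        n_background_groups=20,
        doc_length_range=(10, 25),
        embedding_dim=20,
        seed=11,
    )
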