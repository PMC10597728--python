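"""Differentiable-classifier surface: embeddings and a closed-form reference model.

The augmentation machinery only needs three things from a victim model:
class probabilities for a document, the gradient of the training loss with
respect to each token's embedding, and an embedding lookup (including a
``[MASK]`` vector).  That surface is the :class:`ClassifierContract`
protocol.

:class:`ReferenceClassifier` is a desk-scale implementation: a document is
represented as the arithmetic mean of its token embeddings and classified
by a linear softmax layer trained with cross-entropy.  Every gradient the
contract requires then exists in closed form — for token position ``i`` in
a document of ``m`` tokens,

    dJ/dV_{w_i} = (1/m) * W^T (p - onehot(y)),

where ``p`` is the softmax output.  No autodiff dependency is needed, and
the gradient is verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus import Corpus, Document

__all__ = [
    "EmbeddingTable",
    "ClassifierContract",
    "ReferenceClassifier",
    "TrainingConfig",
    "train_reference",
    "read_word2vec_text",
    "write_word2vec_text",
    "save_checkpoint",
    "load_checkpoint",
]

MASK_TOKEN = "[MASK]"


class EmbeddingTable:
    """Word -> dense vector map with a dedicated ``[MASK]`` vector.

    Out-of-vocabulary words map to a deterministic pseudo-random unit-scale
    vector keyed by a hash of the token string and ``oov_seed``, so that the
    pipeline is reproducible without a fixed vocabulary.
    """

    def __init__(
        self,
        vectors: dict[str, np.ndarray],
        mask_vector: np.ndarray | None = None,
        oov_seed: int = 0,
    ) -> None:
        if not vectors and mask_vector is None:
            raise ValueError("empty embedding table and no mask vector")
        dims = {len(v) for v in vectors.values()}
        if mask_vector is not None:
            dims.add(len(mask_vector))
        if len(dims) != 1:
            raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
        self.dimension = dims.pop()
        self.vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        if mask_vector is None:
            # No [MASK] row in the source file: fall back to the zero vector,
            # which reduces the importance score to -V_w . grad.
            mask_vector = self.vectors.get(MASK_TOKEN, np.zeros(self.dimension))
        self.mask_vector = np.asarray(mask_vector, dtype=float)
        self.oov_seed = oov_seed
        self._oov_cache: dict[str, np.ndarray] = {}

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def lookup(self, word: str) -> np.ndarray:
        """Vector for ``word``; OOV words get a deterministic hashed vector."""
        vec = self.vectors.get(word)
        if vec is not None:
            return vec
        vec = self._oov_cache.get(word)
        if vec is None:
            h = hash_token(word, self.oov_seed)
            vec = np.random.default_rng(h).standard_normal(self.dimension)
            self._oov_cache[word] = vec
        return vec

    def matrix(self, tokens: Sequence[str]) -> np.ndarray:
        return np.stack([self.lookup(t) for t in tokens])


def hash_token(word: str, seed: int) -> int:
    """Stable 31-bit hash of a token (Python's ``hash`` is salted per process)."""
    h = 2166136261
    for b in word.encode("utf-8"):
        h = ((h ^ b) * 16777619) & 0xFFFFFFFF
    return (h ^ (seed * 0x9E3779B1)) & 0x7FFFFFFF


@runtime_checkable
class ClassifierContract(Protocol):
    """What the augmentation stack requires of a victim model."""

    label_set: tuple[str, ...]
    embeddings: EmbeddingTable

    def predict_proba(self, doc: Document) -> np.ndarray: ...

    def loss_gradient(self, doc: Document, label: str) -> np.ndarray: ...


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 2.0
    epochs: int = 500
    seed: int = 0
    init_scale: float = 0.0  # 0 => zero init (uniform initial predictions)


class ReferenceClassifier:
    """Mean-of-embeddings + linear softmax classifier.

    Serves as the base model the attack queries and the model retrained on
    the augmented corpus.  Predictions are invariant to token order (mean
    pooling) — a property of this stand-in, not of sequence models.
    """

    def __init__(
        self,
        embeddings: EmbeddingTable,
        label_set: Sequence[str],
        weights: np.ndarray | None = None,
        bias: np.ndarray | None = None,
    ) -> None:
        self.embeddings = embeddings
        self.label_set = tuple(label_set)
        c, d = len(self.label_set), embeddings.dimension
        self.weights = np.zeros((c, d)) if weights is None else np.asarray(weights, float)
        self.bias = np.zeros(c) if bias is None else np.asarray(bias, float)
        if self.weights.shape != (c, d) or self.bias.shape != (c,):
            raise ValueError("weight/bias shapes inconsistent with labels and dimension")
        self._label_index = {lb: i for i, lb in enumerate(self.label_set)}

    # -- contract surface ---------------------------------------------------

    def predict_proba(self, doc: Document) -> np.ndarray:
        return self._proba_from_mean(self.doc_mean(doc.tokens))

    def predict_proba_batch(self, means: np.ndarray) -> np.ndarray:
        """Softmax rows for a batch of document mean-embeddings (n, d)."""
        logits = means @ self.weights.T + self.bias
        logits -= logits.max(axis=1, keepdims=True)
        np.exp(logits, out=logits)
        logits /= logits.sum(axis=1, keepdims=True)
        return logits

    def loss_gradient(self, doc: Document, label: str, use_predicted_label: bool = False) -> np.ndarray:
        """Per-token-position gradients of cross-entropy loss, shape (m, d).

        With mean pooling every position shares (1/m) W^T (p - onehot(y)).
        ``use_predicted_label`` takes y = argmax p instead of the gold label.
        """
        p = self.predict_proba(doc)
        y = int(np.argmax(p)) if use_predicted_label else self._label_index[label]
        delta = p.copy()
        delta[y] -= 1.0
        g = (self.weights.T @ delta) / len(doc.tokens)
        return np.tile(g, (len(doc.tokens), 1))

    # -- helpers ------------------------------------------------------------

    def doc_mean(self, tokens: Sequence[str]) -> np.ndarray:
        return self.embeddings.matrix(tokens).mean(axis=0)

    def _proba_from_mean(self, mean: np.ndarray) -> np.ndarray:
        logits = self.weights @ mean + self.bias
        logits = logits - logits.max()
        e = np.exp(logits)
        return e / e.sum()

    def predict(self, doc: Document) -> str:
        return self.label_set[int(np.argmax(self.predict_proba(doc)))]


def train_reference(
    corpus: Corpus,
    embeddings: EmbeddingTable,
    config: TrainingConfig = TrainingConfig(),
    seed: int | None = None,
) -> ReferenceClassifier:
    """Full-batch gradient-descent training of the reference classifier.

    Deterministic given (corpus, embeddings, config, seed); the training
    loss is non-increasing for the default step size at this scale.
    """
    if len(corpus) == 0:
        raise ValueError("cannot train on an empty corpus")
    if seed is None:
        seed = config.seed
    labels = corpus.labels
    c, d, n = len(labels), embeddings.dimension, len(corpus)
    idx = {lb: i for i, lb in enumerate(labels)}

    X = np.stack([embeddings.matrix(doc.tokens).mean(axis=0) for doc in corpus])
    Y = np.zeros((n, c))
    for i, doc in enumerate(corpus):
        Y[i, idx[doc.label]] = 1.0

    rng = np.random.default_rng(seed)
    W = config.init_scale * rng.standard_normal((c, d))
    b = np.zeros(c)
    for _ in range(config.epochs):
        logits = X @ W.T + b
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        delta = (P - Y) / n
        W -= config.learning_rate * (delta.T @ X)
        b -= config.learning_rate * delta.sum(axis=0)
    return ReferenceClassifier(embeddings, labels, W, b)


# -- I/O ---------------------------------------------------------------------


def read_word2vec_text(path, oov_seed: int = 0) -> EmbeddingTable:
    """Read embeddings in word2vec text format.

    The first line may be a ``count dim`` header; every other line is
    ``word v1 ... vd``.  A literal ``[MASK]`` row, if present, becomes the
    mask vector.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(str(path), encoding="utf-8") as fh:
        first = fh.readline().split()
        if len(first) == 2 and all(p.lstrip("-").isdigit() for p in first):
            pass  # header line
        elif first:
            vectors[first[0]] = np.array([float(x) for x in first[1:]])
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    mask = vectors.pop(MASK_TOKEN, None)
    return EmbeddingTable(vectors, mask_vector=mask, oov_seed=oov_seed)


def write_word2vec_text(table: EmbeddingTable, path, header: bool = True) -> None:
    words = sorted(table.vectors)
    with open(str(path), "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(words) + 1} {table.dimension}\n")
        for w in words:
            fh.write(w + " " + " ".join(repr(float(x)) for x in table.vectors[w]) + "\n")
        fh.write(MASK_TOKEN + " " + " ".join(repr(float(x)) for x in table.mask_vector) + "\n")


def save_checkpoint(model: ReferenceClassifier, path, embeddings_path: str | None = None) -> None:
    """JSON checkpoint of weights, bias, and label order; exact round-trip."""
    payload = {
        "label_set": list(model.label_set),
        "weights": [[float(x) for x in row] for row in model.weights],
        "bias": [float(x) for x in model.bias],
        "embeddings_path": embeddings_path,
    }
    with open(str(path), "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_checkpoint(path, embeddings: EmbeddingTable) -> ReferenceClassifier:
    with open(str(path), encoding="utf-8") as fh:
        payload = json.load(fh)
    return ReferenceClassifier(
        embeddings,
        payload["label_set"],
        np.array(payload["weights"], dtype=float),
        np.array(payload["bias"], dtype=float),
    )
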