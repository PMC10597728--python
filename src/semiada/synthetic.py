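"""Synthetic corpora, embeddings, and lexicons with the structure the method assumes.

The generator emulates the statistical shape of a severely imbalanced
clinical-notes dataset at desk scale: many classes with geometrically
decaying sizes, a shared Zipf-like background vocabulary, a small set of
class-exclusive "signature" words whose within-class frequency is boosted
(the class-discriminative noun vocabulary), and synonym groups whose
members receive correlated — but not identical — embeddings, the way
synonym pairs relate in pretrained word-vector spaces.

Synonymy mostly lives *within* a class's signature vocabulary (a specialty
term's synonyms are same-specialty terms), so substitution is
label-preserving yet genuinely moves a document in embedding space — the
invariance that augmentation can teach.  One signature word per class is
additionally placed in a *cross-class bridge* group linking neighbouring
classes, so substitution can push a document over a decision boundary and
the attack can succeed outright.  With ``cross_class_bridges=False``
synonym groups touch background vocabulary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Document
from .models import EmbeddingTable
from .synonyms import RawLexicon

__all__ = ["SyntheticSpec", "geometric_sizes", "generate_corpus", "generate_embeddings", "generate_lexicon"]


def geometric_sizes(n_classes: int, largest: int, smallest: int) -> tuple[int, ...]:
    """Geometrically decaying class sizes from ``largest`` down to ``smallest``."""
    if n_classes == 1:
        return (largest,)
    ratio = (smallest / largest) ** (1.0 / (n_classes - 1))
    return tuple(max(1, round(largest * ratio**i)) for i in range(n_classes))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults: 18 classes sized geometrically from 320 down to 20 documents
    (largest/smallest = 16, ~2,000 documents total), 2,000-word vocabulary,
    12 signature words per class boosted 16x within the owning class
    (which puts the plain-trained reference classifier near the base
    operating point the method assumes), document lengths 20-60 tokens,
    synonym groups of 4 built from each class's own signature words plus
    one cross-class bridge word per class, and 50-d embeddings whose
    within-group cosine (~0.65 at jitter 0.7) matches typical
    pretrained-embedding synonym pairs.
    """

    n_classes: int = 18
    class_sizes: tuple[int, ...] = field(default_factory=lambda: geometric_sizes(18, 320, 20))
    vocab_size: int = 2000
    signature_words_per_class: int = 12
    signature_boost: float = 16.0
    doc_length_range: tuple[int, int] = (20, 60)
    synonym_group_size: int = 4
    n_background_groups: int = 100
    bridged_signatures_per_class: int = 1
    cross_class_bridges: bool = True
    embedding_dim: int = 50
    group_jitter: float = 0.7
    zipf_exponent: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_sizes) != self.n_classes:
            raise ValueError("class_sizes length must equal n_classes")
        if any(s <= 0 for s in self.class_sizes):
            raise ValueError("class sizes must be positive")
        if self.doc_length_range[0] < 1 or self.doc_length_range[0] > self.doc_length_range[1]:
            raise ValueError("invalid doc_length_range")
        if self.signature_words_per_class * self.n_classes > self.vocab_size // 2:
            raise ValueError("signature words would consume over half the vocabulary")
        if self.bridged_signatures_per_class > self.signature_words_per_class:
            raise ValueError("cannot bridge more signature words than exist")

    # -- vocabulary layout (deterministic, derived from the spec alone) ----

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"spec{c:02d}" for c in range(self.n_classes))

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return tuple(f"w{i:04d}" for i in range(self.vocab_size))

    def signature_words(self, class_index: int) -> tuple[str, ...]:
        """Class-exclusive signature words; blocks start at rank 50."""
        start = 50 + class_index * self.signature_words_per_class
        return tuple(f"w{i:04d}" for i in range(start, start + self.signature_words_per_class))

    def synonym_groups(self) -> tuple[tuple[str, ...], ...]:
        """Partition of a designated vocabulary subset into synonym groups.

        Three kinds of group, mirroring how lexicon synonymy relates to
        class vocabulary in real specialty text:

        * within-class groups — signature words of the *same* class are
          synonyms of each other (specialty terms have same-specialty
          synonyms); substitution is label-preserving but moves the
          document in embedding space;
        * cross-class bridge groups (optional, default on) — the first
          ``bridged_signatures_per_class`` signature words of consecutive
          classes share a group, so substitution can genuinely push a
          document toward a neighbouring class and attacks can succeed;
        * background groups — class-neutral vocabulary partitioned into
          consecutive runs.
        """
        groups: list[tuple[str, ...]] = []
        n_bridged = self.bridged_signatures_per_class if self.cross_class_bridges else 0
        if self.cross_class_bridges:
            # the j-th bridged signature word of consecutive classes share
            # a group, linking each class to its neighbours
            for j in range(n_bridged):
                for c0 in range(0, self.n_classes, self.synonym_group_size):
                    members = tuple(
                        self.signature_words(c)[j]
                        for c in range(c0, min(c0 + self.synonym_group_size, self.n_classes))
                    )
                    if len(members) >= 2:
                        groups.append(members)
        for c in range(self.n_classes):
            rest = self.signature_words(c)[n_bridged:]
            for g0 in range(0, len(rest), self.synonym_group_size):
                members = rest[g0 : g0 + self.synonym_group_size]
                if len(members) >= 2:
                    groups.append(members)
        bg_start = 50 + self.n_classes * self.signature_words_per_class
        word = bg_start
        for _ in range(self.n_background_groups):
            if word + self.synonym_group_size > self.vocab_size:
                break
            groups.append(tuple(f"w{i:04d}" for i in range(word, word + self.synonym_group_size)))
            word += self.synonym_group_size
        return tuple(groups)


def _class_distributions(spec: SyntheticSpec) -> np.ndarray:
    """Class-conditional unigram distributions: Zipf background + boosted signatures."""
    ranks = np.arange(1, spec.vocab_size + 1, dtype=float)
    base = ranks ** (-spec.zipf_exponent)
    base /= base.sum()
    dists = np.tile(base, (spec.n_classes, 1))
    for c in range(spec.n_classes):
        for w in spec.signature_words(c):
            dists[c, int(w[1:])] *= spec.signature_boost
        dists[c] /= dists[c].sum()
    return dists


def generate_corpus(spec: SyntheticSpec) -> Corpus:
    """Draw documents from class-conditional unigram mixtures; deterministic under seed."""
    rng = np.random.default_rng([spec.seed, 1])
    vocab = np.array(spec.vocabulary)
    dists = _class_distributions(spec)
    lo, hi = spec.doc_length_range
    docs: list[Document] = []
    for c, (label, size) in enumerate(zip(spec.labels, spec.class_sizes)):
        for i in range(size):
            m = int(rng.integers(lo, hi + 1))
            tokens = tuple(vocab[rng.choice(spec.vocab_size, size=m, p=dists[c])])
            docs.append(Document(f"{label}_{i:04d}", tokens, label))
    return Corpus(tuple(docs), spec.labels, name=f"synthetic-seed{spec.seed}")


def generate_embeddings(spec: SyntheticSpec) -> EmbeddingTable:
    """I.i.d. Gaussian vectors; synonym-group members share a base vector plus jitter.

    The shared base makes within-group cosine similarity much higher than
    between-group similarity (with jitter 0 they coincide exactly).  The
    mask vector is the zero vector, modeling the absence of a word.
    """
    rng = np.random.default_rng([spec.seed, 2])
    d = spec.embedding_dim
    vectors: dict[str, np.ndarray] = {}
    for w in spec.vocabulary:
        vectors[w] = rng.standard_normal(d)
    for group in spec.synonym_groups():
        base = rng.standard_normal(d)
        for w in group:
            vectors[w] = base + spec.group_jitter * rng.standard_normal(d)
    return EmbeddingTable(vectors, mask_vector=np.zeros(d), oov_seed=spec.seed)


def generate_lexicon(spec: SyntheticSpec) -> RawLexicon:
    """Each grouped word's synonyms are the rest of its group; others have none."""
    entries: dict[str, frozenset[str]] = {}
    for group in spec.synonym_groups():
        for w in group:
            entries[w] = frozenset(s for s in group if s != w)
    return RawLexicon(entries)
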