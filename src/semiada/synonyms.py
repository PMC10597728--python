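"""Candidate substitution sets: raw synonym lexicon + cosine ranking.

A :class:`RawLexicon` maps each word to its unranked candidate synonyms
(e.g. converted offline from WordNet synsets, or generated synthetically).
:func:`build_synonym_sets` turns it into per-word :class:`SynonymSet`
objects holding the ``k`` candidates closest in embedding cosine
similarity — the substitution pool the attack samples from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import EmbeddingTable

__all__ = [
    "RawLexicon",
    "SynonymSet",
    "cosine",
    "build_synonym_sets",
    "read_lexicon_tsv",
    "write_lexicon_tsv",
]

# Beyond k = 20, larger candidate pools add little diversity relative to cost.
DEFAULT_K = 20


@dataclass(frozen=True)
class RawLexicon:
    """word -> set of single-token lowercase synonym candidates."""

    entries: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for word, syns in self.entries.items():
            # single-token replacement only; a word is never its own synonym
            kept = frozenset(
                s for s in syns if s != word and " " not in s and s
            )
            clean[word] = kept
        object.__setattr__(self, "entries", clean)

    def get(self, word: str) -> frozenset[str]:
        return self.entries.get(word, frozenset())


@dataclass(frozen=True)
class SynonymSet:
    """Ranked substitution candidates for one word.

    ``candidates`` is sorted by descending cosine similarity, ties broken
    lexicographically, and never exceeds the ``k`` it was built with.
    """

    word: str
    candidates: tuple[tuple[str, float], ...]

    def words(self) -> tuple[str, ...]:
        return tuple(w for w, _ in self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two non-zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def build_synonym_sets(
    lexicon: RawLexicon, embeddings: EmbeddingTable, k: int = DEFAULT_K
) -> dict[str, SynonymSet]:
    """Rank each word's lexicon synonyms by embedding cosine and keep the top k.

    Candidates without an embedding are dropped (their cosine is undefined);
    a word whose candidates all lack embeddings gets an empty set.  Because
    ranking is a stable sort on (-cosine, word), enlarging k only appends
    candidates — it never changes the existing prefix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, SynonymSet] = {}
    for word, syns in lexicon.entries.items():
        if word not in embeddings:
            out[word] = SynonymSet(word, ())
            continue
        base = embeddings.lookup(word)
        scored = [
            (s, cosine(base, embeddings.lookup(s))) for s in sorted(syns) if s in embeddings
        ]
        scored.sort(key=lambda pair: (-pair[1], pair[0]))
        out[word] = SynonymSet(word, tuple(scored[:k]))
    return out


def read_lexicon_tsv(path) -> RawLexicon:
    """Read a lexicon TSV: each line is ``word<TAB>syn1<TAB>syn2...``."""
    entries: dict[str, frozenset[str]] = {}
    with open(str(path), encoding="utf-8") as fh:
        for line in fh:
            parts = [p.strip().lower() for p in line.rstrip("\n").split("\t") if p.strip()]
            if not parts:
                continue
            entries[parts[0]] = frozenset(parts[1:])
    return RawLexicon(entries)


def write_lexicon_tsv(lexicon: RawLexicon, path) -> None:
    with open(str(path), "w", encoding="utf-8") as fh:
        for word in sorted(lexicon.entries):
            syns = sorted(lexicon.entries[word])
            fh.write("\t".join([word, *syns]) + "\n")
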