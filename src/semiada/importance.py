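"""Gradient-projection word importance ranking.

For a document x = [w_1 ... w_m] the importance of word w_i is the
projection of the mask-replacement direction onto the loss gradient:

    I(w_i, x) = (V_[MASK] - V_{w_i}) . dJ/dV_{w_i}

a first-order estimate of how much the loss would rise if w_i were masked
out.  A single gradient query scores every position at once, which is what
makes the attack linear in document length; the deletion-based alternative
needs one model query per word and is kept only as a test oracle.

Stop words and out-of-vocabulary words are excluded from the ranking; ties
are broken by ascending original position so the ordering is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Document, StopWordList
from .models import ClassifierContract

__all__ = ["ImportanceEntry", "ImportanceRanking", "word_importance", "write_ranking_tsv"]


@dataclass(frozen=True)
class ImportanceEntry:
    position: int
    word: str
    score: float


@dataclass(frozen=True)
class ImportanceRanking:
    """Positions of a document sorted by descending importance score."""

    doc_id: str
    entries: tuple[ImportanceEntry, ...]
    gradient_queries: int = 1

    def __len__(self) -> int:
        return len(self.entries)

    def positions(self) -> tuple[int, ...]:
        return tuple(e.position for e in self.entries)


def word_importance(
    model: ClassifierContract,
    doc: Document,
    stoplist: StopWordList | None = None,
    use_abs: bool = False,
) -> ImportanceRanking:
    """Score and rank every non-stop-word, in-vocabulary token position.

    Exactly one ``loss_gradient`` call is made regardless of document
    length; the count is exposed on the returned ranking.  ``use_abs``
    ranks by |I| instead of the signed score (default signed, descending).
    """
    grads = model.loss_gradient(doc, doc.label)
    mask_vec = model.embeddings.mask_vector
    entries: list[ImportanceEntry] = []
    for pos, word in enumerate(doc.tokens):
        if stoplist is not None and word in stoplist:
            continue
        if word not in model.embeddings:
            continue
        diff = mask_vec - model.embeddings.lookup(word)
        entries.append(ImportanceEntry(pos, word, float(np.dot(diff, grads[pos]))))
    key = (lambda e: (-abs(e.score), e.position)) if use_abs else (lambda e: (-e.score, e.position))
    entries.sort(key=key)
    return ImportanceRanking(doc.doc_id, tuple(entries), gradient_queries=1)


def write_ranking_tsv(rankings, path) -> None:
    """Dump rankings for inspection: doc_id, position, word, score."""
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("doc_id\tposition\tword\tscore\n")
        for ranking in rankings:
            for e in ranking.entries:
                fh.write(f"{ranking.doc_id}\t{e.position}\t{e.word}\t{e.score!r}\n")
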