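"""Labeled text corpora: reading, writing, tokenization, and filtering.

A :class:`Corpus` is an ordered collection of :class:`Document` objects,
each a lowercase token sequence with a class label drawn from the corpus
label set.  Labels are opaque strings; their first-appearance order fixes
the class-index assignment used by every downstream component (classifier
output vectors, confusion matrices, category-importance tables).
"""

from __future__ import annotations

import csv
import json
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "Document",
    "Corpus",
    "StopWordList",
    "CorpusFormatError",
    "EmptyDocumentError",
    "tokenize",
    "read_corpus",
    "write_corpus",
    "filter_small_classes",
    "remove_stopwords",
    "load_default_stopwords",
]


class CorpusFormatError(ValueError):
    """A corpus file violates the expected record structure."""


class EmptyDocumentError(ValueError):
    """Tokenization produced no tokens."""


@dataclass(frozen=True)
class Document:
    """One labeled text: an ordered lowercase token sequence plus a class label."""

    doc_id: str
    tokens: tuple[str, ...]
    label: str
    raw_text: str | None = None

    def __post_init__(self) -> None:
        if not self.tokens:
            raise EmptyDocumentError(f"document {self.doc_id!r} has no tokens")
        object.__setattr__(self, "tokens", tuple(self.tokens))


@dataclass(frozen=True)
class Corpus:
    """An ordered document collection with its label set in first-appearance order."""

    documents: tuple[Document, ...]
    labels: tuple[str, ...]
    name: str = "corpus"

    def __post_init__(self) -> None:
        object.__setattr__(self, "documents", tuple(self.documents))
        object.__setattr__(self, "labels", tuple(self.labels))
        if not self.documents:
            raise ValueError("corpus must contain at least one document")
        if not self.labels:
            raise ValueError("corpus label set is empty")
        label_set = set(self.labels)
        for doc in self.documents:
            if doc.label not in label_set:
                raise ValueError(
                    f"document {doc.doc_id!r} has label {doc.label!r} "
                    "outside the corpus label set"
                )

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in self.labels}
        for doc in self.documents:
            counts[doc.label] += 1
        return counts


@dataclass(frozen=True)
class StopWordList:
    """An immutable stop-word snapshot packaged with the library (no downloads)."""

    words: frozenset[str]
    source_tag: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "words", frozenset(self.words))

    def __contains__(self, word: str) -> bool:
        return word in self.words


_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def tokenize(raw_text: str) -> tuple[str, ...]:
    """Lowercase, strip ASCII punctuation, and split on whitespace.

    Raises :class:`EmptyDocumentError` if nothing survives.
    """
    tokens = tuple(raw_text.lower().translate(_PUNCT_TABLE).split())
    if not tokens:
        raise EmptyDocumentError("tokenization produced an empty document")
    return tokens


def _labels_in_order(documents: Iterable[Document]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for doc in documents:
        seen.setdefault(doc.label, None)
    return tuple(seen)


def read_corpus(path, format: str = "jsonl", name: str | None = None) -> Corpus:
    """Read a labeled corpus from JSONL ({"id","text","label"}) or CSV (text,label).

    Record order is preserved; labels are collected in first-appearance order.
    Records already tokenized (JSONL ``tokens`` key) are taken verbatim.
    """
    path = str(path)
    docs: list[Document] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                if "label" not in rec:
                    raise CorpusFormatError(f"{path}:{lineno}: missing 'label' field")
                if "tokens" in rec:
                    tokens = tuple(rec["tokens"])
                    raw = rec.get("text")
                elif "text" in rec:
                    tokens = tokenize(rec["text"])
                    raw = rec["text"]
                else:
                    raise CorpusFormatError(f"{path}:{lineno}: missing 'text' field")
                docs.append(
                    Document(
                        doc_id=str(rec.get("id", f"doc{lineno}")),
                        tokens=tokens,
                        label=str(rec["label"]),
                        raw_text=raw,
                    )
                )
    elif format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"text", "label"} <= set(reader.fieldnames):
                raise CorpusFormatError(f"{path}: CSV header must contain 'text' and 'label'")
            for lineno, rec in enumerate(reader, start=2):
                if rec.get("text") is None or rec.get("label") is None:
                    raise CorpusFormatError(f"{path}:{lineno}: missing text/label value")
                docs.append(
                    Document(
                        doc_id=str(rec.get("id") or f"doc{lineno - 1}"),
                        tokens=tokenize(rec["text"]),
                        label=rec["label"],
                        raw_text=rec["text"],
                    )
                )
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    if not docs:
        raise CorpusFormatError(f"{path}: no records")
    return Corpus(tuple(docs), _labels_in_order(docs), name=name or path)


def write_corpus(corpus: Corpus, path, extra_fields: dict[str, dict] | None = None) -> None:
    """Write a corpus as JSONL, one ``{"id","tokens","label"}`` object per line.

    ``extra_fields`` maps doc_id to provenance fields merged into the record.
    """
    with open(str(path), "w", encoding="utf-8") as fh:
        for doc in corpus:
            rec: dict = {"id": doc.doc_id, "tokens": list(doc.tokens), "label": doc.label}
            if doc.raw_text is not None:
                rec["text"] = doc.raw_text
            if extra_fields and doc.doc_id in extra_fields:
                rec.update(extra_fields[doc.doc_id])
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def filter_small_classes(corpus: Corpus, min_count: int = 30) -> Corpus:
    """Drop every class with fewer than ``min_count`` documents (and its documents).

    Mirrors the common preprocessing step of removing classes too small to
    train on.  Idempotent.  Raises if nothing survives.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = corpus.class_counts()
    kept_labels = tuple(lb for lb in corpus.labels if counts[lb] >= min_count)
    if not kept_labels:
        raise ValueError("filter_small_classes removed every class")
    kept_set = set(kept_labels)
    docs = tuple(d for d in corpus if d.label in kept_set)
    return Corpus(docs, kept_labels, name=corpus.name)


def remove_stopwords(
    tokens: Sequence[str], stoplist: StopWordList
) -> tuple[tuple[str, ...], tuple[int, ...]]:
    """Filter stop words, returning survivors and their original positions.

    Relative order is preserved; positions index into the input sequence and
    are what importance ranking and the attack use to address tokens.
    """
    survivors: list[str] = []
    positions: list[int] = []
    for i, tok in enumerate(tokens):
        if tok not in stoplist:
            survivors.append(tok)
            positions.append(i)
    return tuple(survivors), tuple(positions)


def load_default_stopwords() -> StopWordList:
    """Load the packaged English stop-word snapshot (NLTK-style list + symbols)."""
    text = resources.files("semiada").joinpath("data/stopwords.txt").read_text("utf-8")
    words = {w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")}
    return StopWordList(frozenset(words), source_tag="packaged-english-snapshot")
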