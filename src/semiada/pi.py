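"""Word-category importance (WCI) and the probabilistic-information layer.

Classes in a heavily imbalanced clinical corpus differ sharply in their
high-frequency vocabulary, so simple counting statistics carry real
class signal that a small softmax classifier under-uses.  WCI scores how
strongly a word indicates a class with a BM25-style weighting:

    WCI(w, y) = IDF'(w, y) * (k1 + 1) * TF'(w, y)
                / ( k1 * (1 - b + b * |D_y| / avg|D_Y|) + TF'(w, y) )

    IDF'(w, y) = log(|D| / (|D_w| - |D_{y,w}| + 1) + 1)
                 + (1 - a) * |D_{y,w}| / |D_y|

    TF'(w, y)  = C_{y,w} / C_y

where |D| counts all documents, |D_w| those containing w, |D_{y,w}| those
of class y containing w, |D_y| the class size, C_{y,w} the token
occurrences of w in class y, and C_y the class's token total.  The damping
factor ``a`` in (0, 1) restrains the |D_{y,w}|/|D_y| contribution; ``k1``
and ``b`` play their usual BM25 saturation and length-normalization roles,
with class size standing in for document length.

A document's propensity for class y is the mean squared WCI of its tokens
(Score), and the PI layer re-normalizes the classifier's softmax output z
through a fresh, max-shifted softmax of z_i * Score_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Document, StopWordList
from .models import ClassifierContract

__all__ = [
    "CorpusStatistics",
    "WCIParams",
    "WCITable",
    "count_statistics",
    "tf_prime",
    "idf_prime",
    "wci",
    "category_score",
    "softmax_pi",
    "classify_with_pi",
    "write_wci_tsv",
    "read_wci_tsv",
]


@dataclass(frozen=True)
class CorpusStatistics:
    """Exact integer counting statistics of a labeled corpus.

    Document-level counts (``d_w``, ``d_yw``) count a word once per
    document; occurrence counts (``c_yw``, ``c_y``) count every token.
    """

    d_total: int
    d_w: dict[str, int]
    d_y: dict[str, int]
    d_yw: dict[tuple[str, str], int]
    c_yw: dict[tuple[str, str], int]
    c_y: dict[str, int]
    labels: tuple[str, ...]

    @property
    def avg_dy(self) -> float:
        return sum(self.d_y.values()) / len(self.d_y)


@dataclass(frozen=True)
class WCIParams:
    """BM25-style weighting constants.

    a: damping factor in (0,1) on the class-coverage term of IDF'.
    k1: term-frequency saturation; b: extra class-size normalization
    strength.  Because TF' is already a ratio over the class token total
    (unlike raw BM25 term counts), any b > 0 double-normalizes and acts as
    a pure class-size prior — roughly 1/(1-b+b|D_y|/avg) per class,
    squared in the document score — that can override word content
    entirely.  The default b = 0 therefore disables it; it remains
    available for corpora whose statistics are not already size-normalized.
    """

    a: float = 0.5
    k1: float = 1.2
    b: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.a < 1.0):
            raise ValueError("damping factor a must lie in (0, 1)")
        if self.k1 <= 0:
            raise ValueError("k1 must be positive")
        if not (0.0 <= self.b <= 1.0):
            raise ValueError("b must lie in [0, 1]")


def count_statistics(corpus: Corpus) -> CorpusStatistics:
    """Count document- and token-level statistics exactly as stored."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    d_w: dict[str, int] = {}
    d_y: dict[str, int] = {lb: 0 for lb in corpus.labels}
    d_yw: dict[tuple[str, str], int] = {}
    c_yw: dict[tuple[str, str], int] = {}
    c_y: dict[str, int] = {lb: 0 for lb in corpus.labels}
    for doc in corpus:
        y = doc.label
        d_y[y] += 1
        c_y[y] += len(doc.tokens)
        for tok in doc.tokens:
            key = (y, tok)
            c_yw[key] = c_yw.get(key, 0) + 1
        for tok in set(doc.tokens):
            d_w[tok] = d_w.get(tok, 0) + 1
            key = (y, tok)
            d_yw[key] = d_yw.get(key, 0) + 1
    return CorpusStatistics(len(corpus), d_w, d_y, d_yw, c_yw, c_y, corpus.labels)


def tf_prime(stats: CorpusStatistics, word: str, label: str) -> float:
    """Category frequency of a word: occurrences in class / class token total."""
    if label not in stats.c_y:
        raise KeyError(f"unknown class {label!r}")
    total = stats.c_y[label]
    if total == 0:
        raise ValueError(f"class {label!r} has no tokens")
    return stats.c_yw.get((label, word), 0) / total


def idf_prime(stats: CorpusStatistics, params: WCIParams, word: str, label: str) -> float:
    """Class-aware inverse document frequency variant (natural log)."""
    if label not in stats.d_y:
        raise KeyError(f"unknown class {label!r}")
    dy = stats.d_y[label]
    if dy == 0:
        raise ValueError(f"class {label!r} is empty")
    dw = stats.d_w.get(word, 0)
    dyw = stats.d_yw.get((label, word), 0)
    return math.log(stats.d_total / (dw - dyw + 1) + 1) + (1.0 - params.a) * dyw / dy


def wci(stats: CorpusStatistics, params: WCIParams, word: str, label: str) -> float:
    """BM25-variant word-category importance; 0 iff the word never occurs in the class."""
    tf = tf_prime(stats, word, label)
    if tf == 0.0:
        return 0.0
    idf = idf_prime(stats, params, word, label)
    norm = params.k1 * (1.0 - params.b + params.b * stats.d_y[label] / stats.avg_dy)
    return idf * (params.k1 + 1.0) * tf / (norm + tf)


@dataclass
class WCITable:
    """Lazily materialized (word, class) -> WCI map over fixed statistics."""

    statistics: CorpusStatistics
    params: WCIParams = field(default_factory=WCIParams)
    _cache: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    def value(self, word: str, label: str) -> float:
        key = (word, label)
        v = self._cache.get(key)
        if v is None:
            v = wci(self.statistics, self.params, word, label)
            self._cache[key] = v
        return v

    @property
    def labels(self) -> tuple[str, ...]:
        return self.statistics.labels


def category_score(
    table: WCITable,
    doc: Document,
    label: str,
    stoplist: StopWordList | None = None,
    rms: bool = False,
) -> float:
    """Document propensity for a class: mean squared WCI over considered tokens.

    Stop words are dropped before scoring; words unseen in the statistics
    contribute 0 to the sum but still count toward n.  ``rms`` switches to
    the root-mean-square alternate.  An empty post-filter document scores 0.
    """
    tokens = [t for t in doc.tokens if stoplist is None or t not in stoplist]
    if not tokens:
        return 0.0
    total = sum(table.value(t, label) ** 2 for t in tokens)
    mean_sq = total / len(tokens)
    return math.sqrt(mean_sq) if rms else mean_sq


def softmax_pi(z: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Re-normalize softmax output z through exp(z_i * Score_i - M).

    M = max_j z_j * Score_j guards against overflow without changing the
    result.  Output is strictly positive and sums to 1.
    """
    z = np.asarray(z, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if z.shape != scores.shape:
        raise ValueError(f"shape mismatch: z {z.shape} vs scores {scores.shape}")
    v = z * scores
    e = np.exp(v - v.max())
    return e / e.sum()


def classify_with_pi(
    model: ClassifierContract,
    table: WCITable,
    doc: Document,
    stoplist: StopWordList | None = None,
) -> tuple[str, np.ndarray]:
    """Predict with the PI layer: argmax of softmax_pi(z, per-class Score)."""
    z = model.predict_proba(doc)
    scores = np.array(
        [category_score(table, doc, lb, stoplist=stoplist) for lb in model.label_set]
    )
    out = softmax_pi(z, scores)
    return model.label_set[int(np.argmax(out))], out


# -- serialization ----------------------------------------------------------


def write_wci_tsv(table: WCITable, path) -> None:
    """Materialize all (word, class) values with nonzero TF' to a TSV.

    The header block records the weighting parameters and corpus checksums
    so a reload can verify provenance; float values use ``repr`` for a
    bit-exact round-trip.
    """
    stats = table.statistics
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write(f"# a={table.params.a!r}\tk1={table.params.k1!r}\tb={table.params.b!r}\n")
        fh.write(f"# d_total={stats.d_total}\tn_classes={len(stats.labels)}\n")
        fh.write("word\tclass\twci\n")
        for (y, w) in sorted(stats.c_yw):
            fh.write(f"{w}\t{y}\t{table.value(w, y)!r}\n")


def read_wci_tsv(path) -> dict[tuple[str, str], float]:
    values: dict[tuple[str, str], float] = {}
    with open(str(path), encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("word\t"):
                continue
            w, y, v = line.rstrip("\n").split("\t")
            values[(w, y)] = float(v)
    return values
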