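"""Multiple-step adversarial attack (MSAA) and semiadversarial augmentation.

The attack walks a document's importance ranking in chunks of ``t`` words
per action.  Each action samples ``r = k * t`` random synonym-combination
candidates, evaluates them all with probability queries, harvests every
candidate that lowers the model's confidence in the true label *without*
flipping the predicted label (a semiadversarial example), and greedily
commits the candidate with the lowest confidence as the new state.  The
walk stops as soon as the best candidate flips the label — that final
adversarial example is discarded, because examples that cross the decision
boundary drag it away from the truth when trained on.

Retained examples keep the source label and are unioned with the original
corpus (capped per class) to form the augmented training set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, Document, StopWordList
from .models import ClassifierContract, ReferenceClassifier
from .importance import word_importance
from .synonyms import RawLexicon, SynonymSet

# Minimum confidence drop for retention/commit decisions.  Guards against
# floating-point ties: under mean pooling a candidate that merely transposes
# two tokens has an identical document representation, and batched vs
# per-document evaluation can disagree at the 1e-16 level on such ties.
MIN_CONFIDENCE_DROP = 1e-12

__all__ = [
    "AttackConfig",
    "AugmentationRecord",
    "QueryLedger",
    "AttackOutcome",
    "AugmentationResult",
    "candidate_combinations",
    "attack_document",
    "augment_corpus",
    "sra_baseline",
]


@dataclass(frozen=True)
class AttackConfig:
    """Knobs of the multiple-step attack.

    ``t`` words are perturbed per action and ``r = k * t`` random
    combinations are sampled per action (the exponential k^t candidate
    space cut down to a constant per action).  Defaults t=3 and k=20 are
    the settings at which the method saturates; ``per_class_cap`` bounds
    how many augmented examples each class may contribute.
    """

    t: int = 3
    k: int = 20
    r: int | None = None
    max_actions: int | None = None
    seed: int = 0
    per_class_cap: int = 100
    use_abs_importance: bool = False

    def __post_init__(self) -> None:
        if self.t < 1 or self.k < 1:
            raise ValueError("t and k must be >= 1")
        if self.r is None:
            object.__setattr__(self, "r", self.k * self.t)
        if self.r < 1:
            raise ValueError("r must be >= 1")


@dataclass(frozen=True)
class AugmentationRecord:
    """A retained semiadversarial example with its provenance."""

    tokens: tuple[str, ...]
    label: str
    source_doc_id: str
    f_y: float
    f_y_orig: float
    action_index: int
    replaced: tuple[tuple[int, str, str], ...]  # (position, original, substitute)


@dataclass
class QueryLedger:
    """Monotone counters of model accesses made by the attack."""

    gradient_queries: int = 0
    probability_queries: int = 0

    def merge(self, other: "QueryLedger") -> None:
        self.gradient_queries += other.gradient_queries
        self.probability_queries += other.probability_queries


@dataclass(frozen=True)
class AttackOutcome:
    """Per-document attack trace summary."""

    doc_id: str
    flag: str  # "success" | "exhausted" | "max_actions" | "no-op"
    actions: int
    ranking_size: int


@dataclass(frozen=True)
class AugmentationResult:
    corpus: Corpus
    records: tuple[AugmentationRecord, ...]
    ledger: QueryLedger
    outcomes: tuple[AttackOutcome, ...]


def candidate_combinations(
    perset: list[tuple[int, str]],
    synsets: dict[str, SynonymSet],
    r: int,
    rng: np.random.Generator,
) -> list[dict[int, str]]:
    """Sample ``r`` substitution maps, one uniform synonym per perturbed word.

    Every map assigns each position in ``perset`` a synonym drawn uniformly
    from that word's set; duplicates are permitted (sampling with
    replacement over the k^t combination space).
    """
    if r <= 0:
        raise ValueError("r must be positive")
    pools = []
    for pos, word in perset:
        words = synsets[word].words()
        if not words:
            raise ValueError(f"word {word!r} has an empty synonym set")
        pools.append((pos, words))
    maps: list[dict[int, str]] = []
    for _ in range(r):
        maps.append({pos: words[rng.integers(len(words))] for pos, words in pools})
    return maps


def _batch_proba(model: ClassifierContract, docs_tokens: list[tuple[str, ...]]) -> np.ndarray:
    """Probability rows for candidate token sequences (one query counted each)."""
    if isinstance(model, ReferenceClassifier):
        means = np.stack([model.doc_mean(toks) for toks in docs_tokens])
        return model.predict_proba_batch(means)
    return np.stack(
        [model.predict_proba(Document("cand", toks, "?")) for toks in docs_tokens]
    )


def attack_document(
    model: ClassifierContract,
    doc: Document,
    synsets: dict[str, SynonymSet],
    config: AttackConfig,
    stoplist: StopWordList | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[AugmentationRecord], QueryLedger, AttackOutcome]:
    """Run the multiple-step attack on one document.

    Per action the next ``t`` rankable words with non-empty synonym sets
    form the perturbed set; ``r`` sampled combinations are each evaluated
    with one probability query against the *original* document's
    confidence.  Candidates that reduce confidence while preserving the
    predicted label are harvested; the confidence-minimizing candidate is
    committed.  The loop ends on label flip (the flipping example is
    discarded), ranking exhaustion, or the action cap.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ledger = QueryLedger()

    ranking = word_importance(model, doc, stoplist=stoplist, use_abs=config.use_abs_importance)
    ledger.gradient_queries += ranking.gradient_queries
    # Only words with substitution candidates can be perturbed; empty-set
    # words are skipped so each action still targets up to t words.
    eligible = [
        (e.position, e.word)
        for e in ranking.entries
        if e.word in synsets and len(synsets[e.word]) > 0
    ]
    if not eligible:
        return [], ledger, AttackOutcome(doc.doc_id, "no-op", 0, len(ranking))

    y_index = {lb: i for i, lb in enumerate(model.label_set)}[doc.label]
    # The original document's forward pass is shared with the gradient query
    # (the loss gradient requires the softmax output), so it is not an extra
    # probability query.
    f_orig_vec = model.predict_proba(doc)
    f_y_orig = float(f_orig_vec[y_index])

    current = list(doc.tokens)
    current_f_y = f_y_orig
    replaced: dict[int, tuple[str, str]] = {}
    records: list[AugmentationRecord] = []
    flag = "exhausted"
    n_actions = 0

    for j, start in enumerate(range(0, len(eligible), config.t)):
        if config.max_actions is not None and j >= config.max_actions:
            flag = "max_actions"
            break
        perset = eligible[start : start + config.t]
        maps = candidate_combinations(perset, synsets, config.r, rng)

        cand_tokens: list[tuple[str, ...]] = []
        for mp in maps:
            toks = list(current)
            for pos, sub in mp.items():
                toks[pos] = sub
            cand_tokens.append(tuple(toks))
        probs = _batch_proba(model, cand_tokens)
        ledger.probability_queries += len(cand_tokens)
        n_actions = j + 1

        preds = np.argmax(probs, axis=1)
        fy = probs[:, y_index]
        for i, mp in enumerate(maps):
            if fy[i] < f_y_orig - MIN_CONFIDENCE_DROP and preds[i] == y_index:
                rep = dict(replaced)
                for pos, sub in mp.items():
                    rep[pos] = (doc.tokens[pos], sub)
                records.append(
                    AugmentationRecord(
                        tokens=cand_tokens[i],
                        label=doc.label,
                        source_doc_id=doc.doc_id,
                        f_y=float(fy[i]),
                        f_y_orig=f_y_orig,
                        action_index=j,
                        replaced=tuple(
                            (pos, orig, sub) for pos, (orig, sub) in sorted(rep.items())
                        ),
                    )
                )
        best = int(np.argmin(fy))
        if preds[best] != y_index:
            # Successful attack: the flipping example is discarded, not kept.
            flag = "success"
            break
        if fy[best] < current_f_y - MIN_CONFIDENCE_DROP:
            current = list(cand_tokens[best])
            current_f_y = float(fy[best])
            for pos, sub in maps[best].items():
                replaced[pos] = (doc.tokens[pos], sub)
        # else: no candidate improved on the current state; move to the
        # next t ranked words with the state unchanged.

    return records, ledger, AttackOutcome(doc.doc_id, flag, n_actions, len(ranking))


def max_probability_queries(ranking_size: int, config: AttackConfig) -> int:
    """Trace-level per-document query bound: ceil(|W|/t) * r."""
    return math.ceil(ranking_size / config.t) * config.r


def augment_corpus(
    model: ClassifierContract,
    corpus: Corpus,
    synsets: dict[str, SynonymSet],
    config: AttackConfig,
    stoplist: StopWordList | None = None,
) -> AugmentationResult:
    """Attack every document and union the retained examples with the corpus.

    Retained sequences are deduplicated corpus-wide (first occurrence wins,
    and sequences identical to an original document are dropped).  The
    ``per_class_cap`` is then allocated round-robin over source documents
    (and, within a document, over attack actions in order), so the capped
    set spreads across as many distinct source documents as possible
    instead of exhausting the budget on the first few — a single action
    can qualify dozens of near-identical candidates.  Per-document RNG
    substreams are derived from (seed, document index) so results do not
    depend on evaluation order.
    """
    ledger = QueryLedger()
    outcomes: list[AttackOutcome] = []
    seen: set[tuple[str, ...]] = {doc.tokens for doc in corpus}
    # class -> list of per-source-document record queues, in corpus order
    queues: dict[str, list[list[AugmentationRecord]]] = {lb: [] for lb in corpus.labels}

    for i, doc in enumerate(corpus):
        rng = np.random.default_rng([config.seed, i])
        records, doc_ledger, outcome = attack_document(
            model, doc, synsets, config, stoplist=stoplist, rng=rng
        )
        ledger.merge(doc_ledger)
        outcomes.append(outcome)
        kept: list[AugmentationRecord] = []
        for rec in records:
            if rec.tokens in seen:
                continue
            seen.add(rec.tokens)
            kept.append(rec)
        if kept:
            queues[doc.label].append(kept)

    all_records: list[AugmentationRecord] = []
    for lb in corpus.labels:
        taken = 0
        doc_queues = queues[lb]
        round_i = 0
        while taken < config.per_class_cap:
            progressed = False
            for q in doc_queues:
                if round_i < len(q) and taken < config.per_class_cap:
                    all_records.append(q[round_i])
                    taken += 1
                    progressed = True
            if not progressed:
                break
            round_i += 1

    aug_docs = [
        Document(f"{rec.source_doc_id}::aug{n}", rec.tokens, rec.label)
        for n, rec in enumerate(all_records)
    ]
    combined = Corpus(
        tuple(corpus.documents) + tuple(aug_docs), corpus.labels, name=f"{corpus.name}+ada"
    )
    return AugmentationResult(combined, tuple(all_records), ledger, tuple(outcomes))


def sra_baseline(
    corpus: Corpus,
    lexicon: RawLexicon,
    rng: np.random.Generator,
    per_doc: int = 1,
) -> Corpus:
    """Synonym-replacement augmentation baseline.

    Produces ``per_doc`` copies of every document with each lexicon-covered
    token independently replaced by a uniformly random synonym; labels are
    preserved and copies are appended after the originals.
    """
    if per_doc < 0:
        raise ValueError("per_doc must be >= 0")
    if per_doc == 0:
        return corpus
    new_docs: list[Document] = []
    for doc in corpus:
        for c in range(per_doc):
            toks = []
            for tok in doc.tokens:
                syns = sorted(lexicon.get(tok))
                toks.append(syns[rng.integers(len(syns))] if syns else tok)
            new_docs.append(Document(f"{doc.doc_id}::sra{c}", tuple(toks), doc.label))
    return Corpus(
        tuple(corpus.documents) + tuple(new_docs), corpus.labels, name=f"{corpus.name}+sra"
    )
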