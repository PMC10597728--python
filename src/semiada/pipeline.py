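"""End-to-end orchestration: split, train, augment, retrain, recalibrate, evaluate.

The four-step augmentation protocol: (1) train a base model on the
original training set, (2) generate semiadversarial examples for its
documents, (3) take their union with the originals, (4) retrain on the
union.  Mode ``semiada_pi`` additionally builds the word-category
importance table from the augmented training corpus and applies the
probabilistic-information layer at inference.  Augmentation only ever sees
the training split.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .corpus import Corpus, StopWordList, load_default_stopwords
from .models import EmbeddingTable, ReferenceClassifier, TrainingConfig, train_reference
from .synonyms import RawLexicon, build_synonym_sets
from .augment import AttackConfig, AugmentationResult, augment_corpus, sra_baseline
from .pi import WCIParams, WCITable, count_statistics, classify_with_pi
from .metrics import MicroMetrics, confusion_summary, micro_metrics, metrics_row

__all__ = ["RunConfig", "PipelineResult", "stratified_split", "run_pipeline", "MODES"]

logger = logging.getLogger("semiada")

MODES = ("plain", "sra", "semiada", "semiada_pi")


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run depends on."""

    mode: str = "semiada"
    attack: AttackConfig = field(default_factory=AttackConfig)
    wci_params: WCIParams = field(default_factory=WCIParams)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    split_seed: int = 0
    train_ratio: float = 0.8
    sra_per_doc: int = 1
    wci_on_original: bool = False  # build the WCI table from D_orig instead of D_ada

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not (0.0 < self.train_ratio < 1.0):
            raise ValueError("train_ratio must lie in (0, 1)")


@dataclass(frozen=True)
class PipelineResult:
    mode: str
    metrics: MicroMetrics
    truth: tuple[str, ...]
    predicted: tuple[str, ...]
    base_model: ReferenceClassifier
    final_model: ReferenceClassifier
    augmentation: AugmentationResult | None
    wci_table: WCITable | None
    train_size: int
    test_size: int
    augmented_train_size: int
    manifest: dict

    def metrics_tsv(self) -> str:
        header = "mode\tacc\tmicro_p\tmicro_r\tmicro_f1\n"
        return header + metrics_row(self.mode, self.metrics) + "\n"


def stratified_split(corpus: Corpus, ratio: float = 0.8, seed: int = 0) -> tuple[Corpus, Corpus]:
    """Class-stratified partition into train and test, proportions to rounding.

    Every class must have at least two documents so both sides are
    non-empty for every class.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {lb: [] for lb in corpus.labels}
    for i, doc in enumerate(corpus):
        by_class[doc.label].append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lb in corpus.labels:
        idx = by_class[lb]
        if len(idx) < 2:
            raise ValueError(f"class {lb!r} has fewer than 2 documents; cannot stratify")
        perm = rng.permutation(len(idx))
        n_train = min(len(idx) - 1, max(1, round(ratio * len(idx))))
        for j, p in enumerate(perm):
            (train_idx if j < n_train else test_idx).append(idx[p])
    train_idx.sort()
    test_idx.sort()
    docs = corpus.documents
    train = Corpus(tuple(docs[i] for i in train_idx), corpus.labels, name=f"{corpus.name}-train")
    test = Corpus(tuple(docs[i] for i in test_idx), corpus.labels, name=f"{corpus.name}-test")
    return train, test


def run_pipeline(
    corpus: Corpus,
    embeddings: EmbeddingTable,
    lexicon: RawLexicon | None,
    config: RunConfig,
    stoplist: StopWordList | None = None,
) -> PipelineResult:
    """Run one mode end-to-end and evaluate on the held-out test split."""
    if stoplist is None:
        stoplist = load_default_stopwords()
    t0 = time.perf_counter()
    train, test = stratified_split(corpus, config.train_ratio, config.split_seed)
    logger.info("split: %d train / %d test documents", len(train), len(test))

    base = train_reference(train, embeddings, config.training)
    augmentation: AugmentationResult | None = None
    train_final = train

    if config.mode == "sra":
        if lexicon is None:
            raise ValueError("mode 'sra' requires a lexicon")
        rng = np.random.default_rng([config.attack.seed, 99])
        train_final = sra_baseline(train, lexicon, rng, per_doc=config.sra_per_doc)
    elif config.mode in ("semiada", "semiada_pi"):
        if lexicon is None:
            raise ValueError(f"mode {config.mode!r} requires a lexicon")
        synsets = build_synonym_sets(lexicon, embeddings, k=config.attack.k)
        augmentation = augment_corpus(base, train, synsets, config.attack, stoplist=stoplist)
        train_final = augmentation.corpus
        logger.info(
            "augmentation: %d retained examples, %d gradient / %d probability queries",
            len(augmentation.records),
            augmentation.ledger.gradient_queries,
            augmentation.ledger.probability_queries,
        )

    final = base if config.mode == "plain" else train_reference(train_final, embeddings, config.training)

    wci_table: WCITable | None = None
    if config.mode == "semiada_pi":
        wci_source = train if config.wci_on_original else train_final
        wci_table = WCITable(count_statistics(wci_source), config.wci_params)

    truth: list[str] = []
    predicted: list[str] = []
    for doc in test:
        truth.append(doc.label)
        if wci_table is not None:
            label, _ = classify_with_pi(final, wci_table, doc, stoplist=stoplist)
        else:
            label = final.predict(doc)
        predicted.append(label)

    metrics = micro_metrics(confusion_summary(truth, predicted, corpus.labels))
    manifest = {
        "mode": config.mode,
        "split_seed": config.split_seed,
        "train_ratio": config.train_ratio,
        "attack": asdict(config.attack),
        "wci_params": asdict(config.wci_params),
        "training": asdict(config.training),
        "train_size": len(train),
        "test_size": len(test),
        "augmented_train_size": len(train_final),
        "n_augmented": 0 if augmentation is None else len(augmentation.records),
        "gradient_queries": 0 if augmentation is None else augmentation.ledger.gradient_queries,
        "probability_queries": 0 if augmentation is None else augmentation.ledger.probability_queries,
        "metrics_percent": dict(
            zip(("acc", "micro_p", "micro_r", "micro_f1"), metrics.as_percent_row())
        ),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    logger.info("mode=%s metrics=%s", config.mode, manifest["metrics_percent"])
    return PipelineResult(
        mode=config.mode,
        metrics=metrics,
        truth=tuple(truth),
        predicted=tuple(predicted),
        base_model=base,
        final_model=final,
        augmentation=augmentation,
        wci_table=wci_table,
        train_size=len(train),
        test_size=len(test),
        augmented_train_size=len(train_final),
        manifest=manifest,
    )
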