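# Methods

This note documents the models, formulas, numerical choices, and synthetic
study conditions behind `semiada`, in the spirit of a statistical software
methods appendix.  Nothing stated here is an empirical claim beyond what
the test suite and `scripts/acceptance.py` compute at run time.

## Problem setting

Multi-class text classification with many classes and severely imbalanced
class sizes — the regime of clinical-note specialty routing, where a few
specialties dominate the corpus and the tail classes have a few dozen
examples.  Two mechanisms are provided:

1. **Semiadversarial data augmentation (SemiADA)** via a multiple-step
   word-substitution attack (MSAA) against a trained base classifier.
2. **Probabilistic-information (PI) recalibration** of the classifier's
   softmax output using corpus counting statistics (word-category
   importance, WCI).

## The classifier surface

Everything the attack needs from a victim model is a narrow contract:
softmax class probabilities `F(x)`, per-token-position gradients of the
training loss with respect to token embeddings, and an embedding lookup
with a `[MASK]` vector.  The packaged reference classifier represents a
document as the arithmetic mean of its token embeddings and applies a
linear softmax layer trained by full-batch gradient descent on
cross-entropy.  Its gradients exist in closed form,

    dJ/dV_{w_i} = (1/m) W^T (p − onehot(y)),

and are verified against central finite differences (< 1e-5 max absolute
deviation) in the tests.  Default training: learning rate 2.0, 500 epochs,
zero initialization (chosen so the training loss is monotone non-increasing
and the model reaches a stable optimum at the corpus sizes used here).
Predictions are invariant to token order — a property of mean pooling, not
of the transformer models this stand-in emulates.

The loss used for gradients is the gold-label cross-entropy by default; a
`use_predicted_label` flag switches to the model's own argmax label for
the importance computation, since either reading is defensible.

## Word importance

The importance of token `w_i` is the projection of the mask-replacement
direction onto the loss gradient,

    I(w_i, x) = (V_[MASK] − V_{w_i}) · dJ/dV_{w_i},

a first-order estimate of the loss increase from masking the word.  One
gradient query scores all positions, which is what keeps the attack linear
in document length; the ledger asserts exactly one gradient query per
document.  Stop words (packaged English snapshot) and out-of-vocabulary
words are excluded.  Ranking is by the signed score, descending, with ties
broken by ascending position; an absolute-value ranking is available by
flag.  If no `[MASK]` row exists in the embedding table the zero vector is
used, reducing the score to −V_{w_i}·∇J.

## The attack and retention rule

Per attack action the next `t` ranked words with non-empty synonym sets
form the perturbed set; `r = k·t` substitution combinations are sampled
uniformly (with replacement) from the per-word synonym sets, and each is
evaluated with one probability query.  Candidates are judged against the
**original** document's confidence `F_y(x)`:

* every evaluated candidate with `F_y(x′) < F_y(x)` and `argmax F(x′) = y`
  is retained as a semiadversarial example;
* the candidate minimizing `F_y` is committed as the new state (greedy
  descent); if it flips the label the attack stops and the flipping
  example is **discarded** — examples that cross the decision boundary
  teach the retrained model wrong boundaries;
* if no candidate improves on the current state the state is kept and the
  next `t` words are tried, maximizing coverage of the ranking.

Defaults `t = 3`, `k = 20`: candidate diversity saturates around twenty
synonyms, and larger per-action steps shrink the harvest of retained
examples faster than they add variety.  The per-document probability-query
count is bounded by `ceil(|W|/t) · k · t` and asserted per document.

Numerical guard: retention and commit require a confidence drop of at
least 1e-12.  Under mean pooling a candidate that merely transposes two
tokens has an *identical* document representation, and batched versus
per-document evaluation can disagree at the 1e-16 level on such exact
ties; the margin keeps the strict-decrease contract stable under
re-verification.

### Cap allocation

Augmented examples are deduplicated corpus-wide on token sequence (first
occurrence wins; sequences equal to an original document are dropped) and
capped per class.  The cap is allocated **round-robin over source
documents** (then over attack actions within a document) rather than
first-come: a single action can qualify dozens of near-identical
candidates, and a first-come cap concentrates the budget on near-copies
of the first few documents of each class.  A duplicates-control experiment
(retraining on unperturbed copies with the same source multiplicities)
showed that this concentration alone erases the augmentation benefit;
spreading the budget across sources removes the artifact.  Default cap:
100 per class at test scale — large relative to the tail classes (5× the
smallest), small relative to the head — mirroring the role of a large
absolute per-category cap at full scale.

All evaluated qualifying candidates are retained (not only committed
states); this maximizes augmentation yield and leaves selection to the
cap allocation.

## Word-category importance and the PI layer

With `|D|` total documents, `|D_w|` documents containing `w`, `|D_{y,w}|`
documents of class `y` containing `w`, `|D_y|` the class size, `C_{y,w}`
occurrences of `w` in class `y`, and `C_y` the class token total:

    TF′(w, y)  = C_{y,w} / C_y
    IDF′(w, y) = log(|D| / (|D_w| − |D_{y,w}| + 1) + 1) + (1 − a)·|D_{y,w}|/|D_y|
    WCI(w, y)  = IDF′ · (k1 + 1) · TF′ / ( k1·(1 − b + b·|D_y|/avg|D_Y|) + TF′ )

Natural logarithm throughout.  The damping factor `a ∈ (0,1)` (default
0.5) restrains the within-class coverage term of IDF′.  `k1` (default
1.2) is the usual saturation constant.

**On `b`.**  In BM25 the `b`-term normalizes raw term counts by relative
document length.  Here the frequency already *is* a ratio over the class
token total, so any `b > 0` double-normalizes: since TF′ ≪ k1, WCI is
approximately proportional to `1/(1 − b + b·|D_y|/avg)`, a pure class-size
prior that enters the document score squared (≈ 50× between the largest
and smallest classes at `b = 0.75` under the default study conditions) and
overrides word content entirely.  The default is therefore `b = 0`;
the parameter remains available for statistics that are not already
size-normalized.

A document's propensity for class `y` is the mean squared WCI over its
non-stop-word tokens (`Σ WCI² / n`); tokens unseen in the statistics
contribute zero to the sum but count in `n`.  A root-mean-square variant
is available by flag.  An empty post-filter document scores 0.  The PI
layer then replaces the softmax output `z` with

    Softmax-PI(z)_i = exp(z_i·Score_i − M) / Σ_j exp(z_j·Score_j − M),
    M = max_j z_j·Score_j,

where the `M` shift is an overflow guard that provably does not change the
result.  The prediction is the argmax of `z_i·Score_i`.  WCI statistics
are computed on the augmented training corpus by default (the corpus the
final model saw); a flag switches to the original training corpus.
Scoring uses all non-stop-word tokens; a noun-only variant would require
an external POS tagger and is deliberately out of scope.

## Evaluation metrics

Per-class one-vs-rest confusion counts are averaged over classes and the
four metrics computed from the averaged counts:

    Acc     = (TP̄ + TN̄) / (TP̄ + FP̄ + TN̄ + FN̄)
    micro-P = TP̄ / (TP̄ + FP̄),   micro-R = TP̄ / (TP̄ + FN̄)
    micro-F1 = harmonic mean of micro-P and micro-R

Two degeneracies of this construction are worth knowing and are asserted,
not hidden, by the tests: for single-label predictions the one-vs-rest
totals satisfy ΣFP = ΣFN = number of errors, so micro-P = micro-R =
micro-F1 = plain accuracy; and the averaged-counts Acc equals
`1 − 2(1 − acc)/C` for `C` classes, which coincides with plain accuracy
only at `C = 2`.  Zero denominators define a metric as 0 with a warning.
Reported percentages are rounded to one decimal place.

## Synthetic study conditions

The generator emulates the statistical shape the method assumes, at desk
scale.  Defaults (all overridable):

| parameter | default | rationale |
|---|---|---|
| classes | 18 | many-class regime |
| class sizes | geometric, 320 → 20 | largest/smallest = 16, ~2,000 docs; severe imbalance |
| vocabulary | 2,000 words, Zipf s = 1.1 | shared background distribution |
| signature words | 12 per class, disjoint, boost ×16 | class-discriminative vocabulary; the boost places the plain-trained reference model at roughly 75–80% test accuracy — a base model that fits its training data well, which semiadversarial harvesting presupposes (a base model that misclassifies its own minority training documents can never harvest for them) |
| document length | 20–60 tokens | scaled down from clinical-note lengths for speed |
| synonym groups | size 4; within-class signature groups + 1 cross-class bridge word per class + background groups | see below |
| embeddings | 50-d i.i.d. Gaussian; group members share a base vector + jitter 0.7 | within-group cosine ≈ 0.65, matching typical pretrained-embedding synonym pairs; jitter 0 gives cosine 1 |
| split | stratified 4:1 | train/test |

**Synonym-group design.**  Synonymy mostly lives within a class's
signature vocabulary: a specialty term's synonyms are same-specialty
terms, so substitution is label-preserving yet genuinely moves the
document in embedding space — exactly the invariance augmentation can
teach, and the channel through which tail classes gain the most (their
per-word statistics are the worst estimated).  One signature word per
class sits in a cross-class bridge group linking neighbouring classes;
bridges exist so that substitution can push a document across a decision
boundary and the attack can terminate with a genuine label flip (roughly
40% of documents under the defaults).  More bridging injects
systematically mislabeled evidence — a bridged substitution retained with
the source label teaches the model that a neighbouring class's marker
indicates the source class — and measurably degrades the retrained model,
so bridging is kept minimal.  Background groups are class-neutral filler.

With `signature_boost = 1` the class-conditional distributions are
identical and no method can beat the majority-class rate in expectation;
this no-signal control is asserted over five seeds.

**What the generator does not emulate:** real lexical semantics, syntax,
correlated word occurrences within documents, note-length distributions,
or transformer-scale classifiers.  Passing tests demonstrate that the
machinery behaves as specified under the stated generative assumptions,
not that the method improves any particular real-world system.

## Determinism

Every stochastic component takes an explicit seed: corpus/embedding/
lexicon generation, training initialization, the stratified split, and
the attack (one seeded generator per corpus run, with per-document
substreams derived from (seed, document index) so results are independent
of evaluation order).  Identical configuration and seeds give bit-identical
metrics files and augmented corpora.

## Problem sizes used in the checks

The oracle-equivalence checks use 50 random corpora of up to 60 documents.
The attack-contract, improvement-direction, no-signal, and determinism
checks run at the default study scale (18 classes, ~2,000 documents);
improvement direction is averaged over five seeded replicates, and
`scripts/acceptance.py` averages its reported metrics over five
replicates with seeds derived from its `--seed` argument.
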