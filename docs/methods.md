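# Methods

## The model

`circwalk` treats circRNA–disease association prediction as supervised
link prediction on a heterogeneous graph. The biological premise is the
ceRNA hypothesis: a circRNA that sponges a miRNA indirectly regulates
that miRNA's mRNA targets, so paths of the form
circRNA–miRNA–disease or circRNA–miRNA–mRNA–disease carry signal about
unobserved circRNA–disease links. The pipeline therefore (i) merges
every relation it can observe into one undirected, unweighted graph,
(ii) summarizes each node's neighbourhood with a DeepWalk embedding,
and (iii) trains a binary classifier on concatenated pair embeddings.

Key modelling assumptions:

* **All relations are symmetric associations.** No edge directions or
  weights are used anywhere; random walks take uniform steps and
  ignore node kinds. Heterogeneity enters only through which edges
  exist.
* **Known associations define the positive class; sampled unknown
  pairs define the negative class.** There is no verified negative
  set, so negatives are drawn uniformly from the circRNA × disease
  grid minus the positives. The contamination risk of that choice is
  quantified as n_pos / n_unknown (the chance a sampled "negative" is
  an undiscovered positive, if positives continue at the observed
  rate) and reported by `candidate_space`.
* **Embeddings are trained on the full graph, including the known
  circRNA–disease edges.** Cross-validation therefore evaluates the
  classifier given those embeddings, not a fully held-out discovery
  protocol; the case-study mode (below) is the discovery-shaped use.

## Similarity edge construction

**circRNA–circRNA.** Pairwise global alignment with match = +1,
mismatch = 0 and zero gap penalties, normalized by the shorter
sequence's length, giving scores in [0, 1] (under this scheme the raw
score is the longest-common-subsequence length). The retained edge set
is exactly the pairs scoring *strictly above* the arithmetic mean over
all off-diagonal unordered pairs. Match/mismatch/gap values, alignment
mode and normalization are all configurable (`AlignmentScoring`)
because reasonable alternatives exist; the default was chosen for
determinism and boundedness. All-pairs alignment is O(n²) dynamic
programming — fine at the scales this package targets (hundreds to a
few thousand sequences).

**disease–disease.** Wang semantic similarity on a MeSH-style ontology:
a term's position contributes 1 to itself and decays by Δ per edge
toward the root (best path taken when positions overlap); the semantic
value DV(A) is the sum of contributions over A's ancestor closure, and

sim(A, B) = Σ_{t ∈ T_A ∩ T_B} (S_A(t) + S_B(t)) / (DV(A) + DV(B)).

Δ defaults to 0.5, the customary value for this measure. Edges are
pairs with similarity strictly above 0.8. Parent resolution follows
tree-number semantics: a position's parent is the term owning its
longest proper dot-prefix. Diseases attached to several terms are
scored by the maximum over term pairs — an interpretation, flagged
here, since multi-attachment is common in real ontologies.

Both cutoffs use strict inequality; with an all-equal score matrix the
mean cutoff therefore retains nothing.

## DeepWalk

Walks: 10 per node, 80 nodes long, node order shuffled per pass,
uniform transitions; a walk stops early only at a degree-0 node.
Skip-gram: hierarchical softmax over a frequency-built Huffman tree,
window 5, 5 epochs, learning rate decaying linearly 0.025 → 1e-4,
input vectors initialized uniform in ±0.5/k, inner vectors at zero.
These defaults follow the original DeepWalk presentation; none is
sensitive at fixture scale, and all are configurable (`WalkConfig`).

Numerical choices: the sigmoid argument is clamped at ±8; the context
window is fixed rather than length-sampled (word2vec shrinks it
randomly — dropped here so that training is exactly reproducible);
training is single-threaded, making results bit-identical for a fixed
seed. Walk order is permuted each epoch from the same seeded stream.
The held-out mean log P(context | center) is recorded per epoch when
evaluation walks are supplied, so objective progress is testable.

A node absent from every walk (isolated nodes only, given
walks-per-node ≥ 1) receives a zero vector and a warning rather than
an error — it then scores at the classifier's mercy, which is the
honest representation of "no neighbourhood information".

For the embedding-size sweep (k = 10, 20, …, 200) walks are generated
once per seed and reused across sizes; only the skip-gram reruns. Ties
in the per-classifier argmax over mean AUC break toward smaller k.

## Benchmark and evaluation

Negatives are resampled once per experiment, not per fold, so the
benchmark is a single artifact. Folds are stratified by label — the
dataset is balanced by construction and stratification removes
fold-level class skew — but plain shuffling is available
(`make_folds(..., stratified=False)`). The identical fold assignment is
passed to every classifier.

Metrics come from the per-fold confusion tally: Acc = (TP+TN)/all,
Pre = TP/(TP+FP), Sen = TP/(TP+FN), Spe = TN/(TN+FP), FPR = FP/(FP+TN),
F1 = 2·Pre·Sen/(Pre+Sen); ROC from a threshold sweep with trapezoidal
area (equal, under ties, to the concordance probability
P(score_pos > score_neg) + ½P(tie); the test suite checks the two
formulations against each other to 1e-12). Reported summary values are
means over folds, not pooled predictions — note this makes the mean F1
not exactly the F1 of the mean Pre/Sen. A zero-denominator metric is
reported as undefined and flagged, never as 0. Classifiers without
calibrated probabilities (the SVM) contribute signed decision values to
the ROC, which the report notes.

Classifier hyperparameters are library defaults except: LR and MLP
iteration caps raised (1000 / 500) so small benchmarks converge;
AdaBoost-RF uses 10-tree forests as base learners to keep the ensemble
a sane size; XGBoost pinned to logloss and one thread. Every
hyperparameter can be overridden per run via
`ClassifierSpec(name, {...})`, which is also where externally
documented settings should be transcribed if a specific published
configuration is to be reproduced.

## Case study

The case-study scorer trains on **all** positives plus ⌊n_neg/3⌋
uniformly drawn negatives — fewer negatives because they are unverified
and may hide true associations, but not zero because the classifier
needs two classes. Candidates are every (benchmark circRNA, requested
disease) pair not in the training set; each gets a predicted
association probability and a 1-based rank per disease, ties broken by
circRNA id so output is stable. One model serves all requested
diseases. By construction no trained pair can appear in the output.

## The synthetic fixture

The generator emulates the *shape* of the real inputs, not their
content. Nodes of all four kinds are assigned round-robin to
communities (the stand-in for disease mechanisms). Regulatory edges
are independent Bernoulli draws: probability `p_within` = 0.3 inside a
community, `p_between` = 0.02 across. A circRNA–disease pair is a
planted positive exactly when it is same-community *and* shares at
least one miRNA via circRNA–miRNA and miRNA–disease edges — the sponge
path the method is built to exploit. The circRNA–disease edge list
supplied to the pipeline is that positive set, mirroring how curated
associations both sit in the graph and define the labels. Sequences
are per-community ancestors with 5% per-base substitution; the
ontology is a complete 3-ary tree of depth 2 with same-community
diseases placed under the same depth-1 subtree. Defaults: 60 circRNAs,
40 miRNAs, 40 mRNAs, 10 diseases, 3 communities — sized so the full
pipeline (including the O(n²) alignment stage) runs in seconds while
still yielding ≈150 planted positives. Configs whose expected positive
count falls below 10 are rejected as unbuildable.

What the fixture does **not** emulate: expression levels, binding
affinities, sequence-determined miRNA response elements, realistic
degree distributions, or ontology multi-attachment. Passing the
planted-recovery tests shows the pipeline can extract the path-borne
community signal it targets; it does not certify performance on real
curated networks, whose signal-to-noise profile is different.

## Determinism

A single integer seed drives fixture generation, walk generation,
skip-gram initialization, negative sampling, fold shuffling and
classifier seeding, each through its own explicitly constructed
generator (no global RNG state). Every stage is byte-reproducible
under a fixed seed; the test suite asserts this end to end.

## Known limitations

* Training embeddings on the graph that contains the benchmark's
  positive edges leaks label information into the features; the
  cross-validated numbers are therefore an optimistic measure of
  discovery performance (the held-out-positive enrichment test in the
  suite probes the discovery setting directly).
* The alignment-score normalization applied before mean-thresholding
  changes which edges are retained; it is exposed as configuration
  rather than decided silently.
* Hierarchical-softmax skip-gram is the only trainer; negative-sampling
  word2vec and biased (node2vec-style) walks are out of scope.
* The Wang measure is the only disease-similarity option; no
  information-content variants.
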