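# circwalk

Predicting circRNA–disease associations from random-walk embeddings of a
heterogeneous ceRNA network.

Circular RNAs (circRNAs) act as miRNA sponges: by sequestering shared
miRNAs they de-repress the miRNAs' mRNA targets, which is one mechanism
linking circRNAs to disease (the competing-endogenous-RNA, or ceRNA,
hypothesis). `circwalk` turns that mechanism into a link-prediction
pipeline for computational biologists who want to prioritize candidate
circRNA–disease associations:

1. **Network reconstruction.** Seven bipartite relation sets over
   circRNA / miRNA / mRNA / disease nodes are merged into one undirected
   graph *G* = (*V*, *E*): five curated association sets
   (circRNA–disease, circRNA–miRNA, miRNA–disease, miRNA–mRNA,
   mRNA–disease) plus two computed similarity sets — circRNA–circRNA
   edges from pairwise sequence-alignment scores thresholded at the
   all-pairs mean, and disease–disease edges from Wang semantic
   similarity on a MeSH-style ontology thresholded at 0.8. Identifiers
   are unified against a reference catalogue and a disease-synonym
   table before merging.
2. **Feature extraction.** DeepWalk learns a mapping
   Φ : *v* ∈ *V* → ℝ^k by maximizing
   ∏_{j=i−w..i+w, j≠i} P(v_j | Φ(v_i)) over truncated uniform random
   walks (skip-gram with hierarchical softmax, implemented here from
   the walks up, with the inner loop jitted via numba).
3. **Pair classification.** Each (circRNA, disease) pair gets the
   2k-dim concatenation of its two node embeddings. A balanced
   benchmark (all known positives plus an equal number of unknown pairs
   sampled uniformly as negatives) is evaluated with 5-fold
   cross-validation over six classifiers (SVM, LR, RF, AdaBoost-RF,
   XGBoost, MLP); Acc/F1/Pre/Sen/Spe and ROC-AUC are reported as
   per-fold values and fold means, with an embedding-size sweep
   (k = 10…200) to pick each classifier's optimal k. A case-study mode
   trains on all positives plus a third of the negatives and emits a
   probability-ranked candidate list per disease.

A synthetic-fixture module generates all inputs (edge lists, FASTA
sequences, ontology) with planted community structure, so the whole
pipeline runs and is validated end-to-end without any external
database.

## Worked example

```python
from circwalk import run_fixture_pipeline

result = run_fixture_pipeline(seed=1)
print(result.network.summary()["nodes_per_kind"])
print((result.benchmark["label"] == 1).sum(), "positives")
print(result.report.as_percent())
```

prints

```
{'circRNA': 60, 'miRNA': 40, 'mRNA': 40, 'disease': 10}
147 positives
{'Acc': 89.47, 'F1': 89.63, 'Pre': 87.81, 'Sen': 91.77, 'Spe': 87.06, 'AUC': 94.6}
```

The fixture plants 3 communities; 147 circRNA–disease pairs are
ground-truth positives (same community, ≥1 shared miRNA). The balanced
benchmark therefore has 294 pairs, and 5-fold cross-validated XGBoost
on the 40-dim pair features recovers the planted structure with a mean
AUC of 94.6% — far above the 50% a label permutation yields.

The same stages are available from the shell:

```sh
circwalk simulate --seed 1 --out fixture/
circwalk build-network --edges fixture/ --out net/
circwalk similarity seq --fasta fixture/circ_sequences.fasta --out circ_sim.tsv
```

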