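"""Derived similarity edge sets.

Two of the seven relation sets are computed rather than curated:

* circRNA-circRNA edges: pairwise sequence-alignment scores, normalized
  by the shorter sequence length, thresholded at the mean score over all
  pairs (strictly greater than the mean is kept).
* disease-disease edges: Wang semantic similarity on the disease
  ontology DAG, thresholded strictly above 0.8.

The alignment scheme is configurable because the upstream description
pins none of its knobs; the default (global alignment, match=+1,
mismatch=0, zero gap penalties) is deterministic and bounded in [0, 1]
after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .network import BipartiteNetwork

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence.upper()) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-nucleotide symbols {sorted(bad)}"
            )


@dataclass
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = 0.0
    open_gap: float = 0.0
    extend_gap: float = 0.0
    mode: str = "global"
    normalize: str = "shorter"  # "shorter" | "none"


@dataclass
class SimilarityMatrix:
    ids: list[str]
    scores: np.ndarray  # symmetric, diagonal excluded from statistics

    def pair_scores(self) -> np.ndarray:
        """Off-diagonal unordered-pair scores, row-major upper triangle."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.scores[iu]


def pairwise_sequence_scores(
    records: Sequence[SequenceRecord],
    scoring: AlignmentScoring | None = None,
) -> SimilarityMatrix:
    """All-pairs alignment scores as a symmetric similarity matrix.

    O(n^2) dynamic-programming alignments; normalization by the shorter
    sequence makes scores length-comparable and bounds them by 1 under
    the default scheme.
    """
    scoring = scoring or AlignmentScoring()
    if len(records) < 2:
        raise ValueError("need at least 2 sequence records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    aligner = Align.PairwiseAligner()
    aligner.mode = scoring.mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.open_gap
    aligner.extend_gap_score = scoring.extend_gap
    n = len(records)
    m = np.zeros((n, n))
    seqs = [r.sequence.upper() for r in records]
    for i in range(n):
        for j in range(i + 1, n):
            score = aligner.score(seqs[i], seqs[j])
            if scoring.normalize == "shorter":
                score /= min(len(seqs[i]), len(seqs[j]))
            m[i, j] = m[j, i] = score
        m[i, i] = 1.0 if scoring.normalize == "shorter" else aligner.score(seqs[i], seqs[i])
    return SimilarityMatrix(ids=ids, scores=m)


def mean_threshold_edges(m: SimilarityMatrix) -> tuple[BipartiteNetwork, float]:
    """Keep exactly the pairs whose score strictly exceeds the mean over
    all off-diagonal unordered pairs.  Returns (edges, cutoff)."""
    if len(m.ids) < 2:
        raise ValueError("similarity matrix has no pairs")
    pair_scores = m.pair_scores()
    cutoff = float(pair_scores.mean())
    iu = np.triu_indices(len(m.ids), k=1)
    keep = m.scores[iu] > cutoff
    edges = [
        (m.ids[i], m.ids[j])
        for i, j, k in zip(iu[0], iu[1], keep)
        if k
    ]
    return BipartiteNetwork("circRNA-circRNA", edges), cutoff


class OntologyDag:
    """Disease-term hierarchy from MeSH-style tree numbers.

    A term may carry several tree numbers (several positions in the
    hierarchy); a position's parent is the term owning its longest
    proper prefix.  Diseases attach to one or more terms.
    """

    def __init__(self, terms: pd.DataFrame, attachments: pd.DataFrame):
        """terms: columns (term_id, tree_number); attachments: columns
        (disease_id, term_id)."""
        self.tn_to_term: dict[str, str] = {}
        self.term_tns: dict[str, list[str]] = {}
        for term_id, tn in terms[["term_id", "tree_number"]].itertuples(index=False):
            if tn in self.tn_to_term:
                raise ValueError(f"duplicate tree number {tn!r}")
            self.tn_to_term[tn] = term_id
            self.term_tns.setdefault(term_id, []).append(tn)
        self.attachments: dict[str, list[str]] = {}
        for dis, term in attachments[["disease_id", "term_id"]].itertuples(index=False):
            if term not in self.term_tns:
                raise ValueError(f"disease {dis!r} attached to unknown term {term!r}")
            self.attachments.setdefault(dis, []).append(term)

    def parent_tn(self, tn: str) -> str | None:
        """Longest proper prefix of *tn* (on dot boundaries) that is a
        known tree number; None at a root."""
        parts = tn.split(".")
        for cut in range(len(parts) - 1, 0, -1):
            cand = ".".join(parts[:cut])
            if cand in self.tn_to_term:
                return cand
        return None

    def terms_of(self, disease: str) -> list[str]:
        if disease not in self.attachments:
            raise KeyError(f"disease {disease!r} not attached to the ontology")
        return self.attachments[disease]


def _semantic_contributions(dag: OntologyDag, tn: str, delta: float) -> dict[str, float]:
    """Wang S-values over the ancestor closure of the position *tn*:
    S(tn)=1 and S(parent) >= delta * S(child) along every upward path."""
    contrib = {tn: 1.0}
    frontier = [tn]
    while frontier:
        cur = frontier.pop()
        parent = dag.parent_tn(cur)
        if parent is None:
            continue
        cand = delta * contrib[cur]
        if cand > contrib.get(parent, 0.0):
            contrib[parent] = cand
            frontier.append(parent)
    return contrib


def wang_term_similarity(dag: OntologyDag, term_a: str, term_b: str, delta: float = 0.5) -> float:
    """Wang similarity between two ontology terms.

    Each term's semantic value DV is the sum of decayed contributions of
    its ancestors (decay factor ``delta`` per edge, best path taken);
    similarity is the shared ancestors' joint contribution over
    DV(A)+DV(B).  Symmetric and 1 at identity.
    """
    best = 0.0
    for tna in dag.term_tns[term_a]:
        ca = _semantic_contributions(dag, tna, delta)
        dva = sum(ca.values())
        for tnb in dag.term_tns[term_b]:
            cb = _semantic_contributions(dag, tnb, delta)
            dvb = sum(cb.values())
            shared = set(ca) & set(cb)
            if not shared:
                continue
            sim = sum(ca[t] + cb[t] for t in shared) / (dva + dvb)
            best = max(best, sim)
    return best


def wang_similarity(dag: OntologyDag, disease_a: str, disease_b: str, delta: float = 0.5) -> float:
    """Disease-level Wang similarity: the maximum term-pair similarity
    over the diseases' attachments (one attachment is the common case;
    the maximum handles multi-attached diseases)."""
    terms_a = dag.terms_of(disease_a)
    terms_b = dag.terms_of(disease_b)
    return max(
        wang_term_similarity(dag, ta, tb, delta) for ta in terms_a for tb in terms_b
    )


@dataclass
class SimilarityThresholds:
    disease_cutoff: float = 0.8
    wang_delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.disease_cutoff <= 1.0:
            raise ValueError("disease_cutoff must lie in (0, 1]")
        if not 0.0 < self.wang_delta < 1.0:
            raise ValueError("wang_delta must lie in (0, 1)")


def disease_similarity_edges(
    dag: OntologyDag,
    diseases: Iterable[str],
    thresholds: SimilarityThresholds | None = None,
) -> BipartiteNetwork:
    """disease-disease edges: unordered pairs with Wang similarity
    strictly above the cutoff (default 0.8)."""
    thresholds = thresholds or SimilarityThresholds()
    ids = sorted(set(diseases))
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if wang_similarity(dag, a, b, thresholds.wang_delta) > thresholds.disease_cutoff:
                edges.append((a, b))
    return BipartiteNetwork("disease-disease", edges)
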