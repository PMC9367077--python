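"""Balanced labeled benchmark of circRNA-disease pairs.

Positives are the known associations; negatives are an equal number of
pairs drawn uniformly without replacement from the unknown remainder of
the circRNA x disease grid.  Drawing from unknowns risks mislabelling a
true association as negative; the exposure of that risk is
n_pos / n_unknown and is reported by :func:`candidate_space`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, KFold

from .deepwalk import EmbeddingMatrix
from .network import BipartiteNetwork


def build_positive_pairs(circ_disease_edges: BipartiteNetwork) -> pd.DataFrame:
    """One label-1 pair per distinct circRNA-disease edge."""
    if circ_disease_edges.relation != "circRNA-disease":
        raise ValueError("expected the circRNA-disease relation")
    rows = sorted(circ_disease_edges.edges)
    df = pd.DataFrame(rows, columns=["circ_id", "disease_id"])
    df["label"] = 1
    return df


@dataclass
class CandidateSpace:
    """The circRNA x disease grid spanned by the positives."""

    circ_ids: list[str]
    disease_ids: list[str]
    n_pos: int
    positives: frozenset[tuple[str, str]]

    @property
    def n_total(self) -> int:
        return len(self.circ_ids) * len(self.disease_ids)

    @property
    def n_unknown(self) -> int:
        return self.n_total - self.n_pos

    @property
    def false_negative_exposure(self) -> float:
        """Probability mass of undiscovered positives among unknowns if
        negatives are drawn at the positive rate: n_pos / n_unknown."""
        return self.n_pos / self.n_unknown

    def iter_unknown(self) -> Iterator[tuple[str, str]]:
        for c in self.circ_ids:
            for d in self.disease_ids:
                if (c, d) not in self.positives:
                    yield (c, d)


def candidate_space(positives: pd.DataFrame) -> CandidateSpace:
    if positives.empty:
        raise ValueError("need at least one positive pair")
    pos = frozenset(zip(positives["circ_id"], positives["disease_id"]))
    return CandidateSpace(
        circ_ids=sorted(positives["circ_id"].unique()),
        disease_ids=sorted(positives["disease_id"].unique()),
        n_pos=len(pos),
        positives=pos,
    )


def sample_negatives(positives: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Exactly n_pos label-0 pairs, uniform without replacement from the
    unknown set; deterministic given the seed."""
    space = candidate_space(positives)
    unknown = list(space.iter_unknown())
    if len(unknown) < space.n_pos:
        raise ValueError(
            f"only {len(unknown)} unknown pairs but {space.n_pos} negatives needed"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(unknown), size=space.n_pos, replace=False)
    rows = [unknown[i] for i in sorted(idx)]
    df = pd.DataFrame(rows, columns=["circ_id", "disease_id"])
    df["label"] = 0
    return df


def build_benchmark(circ_disease_edges: BipartiteNetwork, seed: int) -> pd.DataFrame:
    """Positives plus an equal number of sampled negatives."""
    pos = build_positive_pairs(circ_disease_edges)
    neg = sample_negatives(pos, seed)
    return pd.concat([pos, neg], ignore_index=True)


def featurize_pairs(pairs: pd.DataFrame, emb: EmbeddingMatrix) -> np.ndarray:
    """Per-pair feature vector of length 2k: circRNA embedding followed
    by disease embedding, in that fixed order."""
    circ_vecs = emb.take(list(pairs["circ_id"]))
    dis_vecs = emb.take(list(pairs["disease_id"]))
    return np.hstack([circ_vecs, dis_vecs])


def make_folds(
    pairs: pd.DataFrame, n_folds: int = 5, seed: int = 0, stratified: bool = True
) -> np.ndarray:
    """Fold index (1-based) per pair; stratified by label by default so
    each fold's class balance matches the global one.  The assignment is
    computed once and shared by every classifier."""
    if len(pairs) < n_folds:
        raise ValueError(f"{len(pairs)} pairs cannot fill {n_folds} folds")
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.zeros(len(pairs), dtype=int)
    y = pairs["label"].to_numpy()
    for fold_idx, (_, test_idx) in enumerate(splitter.split(np.zeros(len(pairs)), y), start=1):
        folds[test_idx] = fold_idx
    return folds
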