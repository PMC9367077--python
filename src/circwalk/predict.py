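"""Case-study prediction: rank novel circRNA candidates per disease.

The scorer is trained on every positive pair but only a third of the
negatives — the negatives are unverified pairs, so training on fewer of
them limits learning from possible false negatives — then every
untrained (circRNA, disease) combination for the requested diseases is
scored with an association probability and ranked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deepwalk import EmbeddingMatrix
from .evaluate import ClassifierSpec, association_scores
from .pairs import featurize_pairs


@dataclass
class CaseModel:
    model: object
    trained_pairs: frozenset[tuple[str, str]]
    circ_ids: list[str]
    spec: ClassifierSpec


def train_case_model(
    benchmark: pd.DataFrame,
    emb: EmbeddingMatrix,
    neg_fraction: float = 1 / 3,
    seed: int = 0,
    spec: ClassifierSpec | None = None,
) -> CaseModel:
    """Fit on all positives plus ``floor(n_neg * neg_fraction)``
    uniformly sampled negatives."""
    spec = spec or ClassifierSpec("XGB")
    pos = benchmark[benchmark["label"] == 1]
    neg = benchmark[benchmark["label"] == 0]
    if len(neg) < 3:
        raise ValueError(
            "fewer than 3 negatives: there must be at least two classes in the dataset"
        )
    n_keep = int(len(neg) * neg_fraction)
    rng = np.random.default_rng(seed)
    keep_idx = np.sort(rng.choice(len(neg), size=n_keep, replace=False))
    train = pd.concat([pos, neg.iloc[keep_idx]], ignore_index=True)
    X = featurize_pairs(train, emb)
    model = spec.build(seed=seed)
    model.fit(X, train["label"].to_numpy())
    return CaseModel(
        model=model,
        trained_pairs=frozenset(zip(train["circ_id"], train["disease_id"])),
        circ_ids=sorted(benchmark["circ_id"].unique()),
        spec=spec,
    )


def rank_candidates(
    case: CaseModel,
    diseases: list[str],
    emb: EmbeddingMatrix,
) -> pd.DataFrame:
    """Probability-ranked candidates per disease.

    Candidates are every (benchmark circRNA, requested disease) pair the
    model was not trained on.  Output columns: disease_id, circ_id,
    probability, rank (1-based, descending probability; ties broken by
    circ_id so the listing is stable).
    """
    missing = [d for d in diseases if d not in emb]
    if missing:
        raise KeyError(f"no embedding for diseases {missing}")
    frames = []
    for disease in diseases:
        circ = [c for c in case.circ_ids if (c, disease) not in case.trained_pairs]
        if not circ:
            frames.append(pd.DataFrame(columns=["disease_id", "circ_id", "probability", "rank"]))
            continue
        cand = pd.DataFrame({"circ_id": circ, "disease_id": disease})
        X = featurize_pairs(cand, emb)
        cand["probability"] = association_scores(case.model, X)
        cand = cand.sort_values(
            ["probability", "circ_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        cand["rank"] = np.arange(1, len(cand) + 1)
        frames.append(cand[["disease_id", "circ_id", "probability", "rank"]])
    return pd.concat(frames, ignore_index=True)
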