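"""End-to-end orchestration: fixture (or loaded inputs) -> heterogeneous
network -> DeepWalk embeddings -> balanced benchmark -> cross-validated
evaluation.  ``CircWalkClassifier`` packages the trained scorer behind a
scikit-learn fit/predict_proba surface over (circRNA, disease) pairs."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import similarity as sim
from .deepwalk import DeepWalk, EmbeddingMatrix, WalkConfig
from .evaluate import ClassifierSpec, MetricsReport, association_scores, cross_validate
from .network import BipartiteNetwork, HeterogeneousNetwork, merge_networks
from .pairs import build_benchmark, featurize_pairs, make_folds
from .synthetic import FixtureBundle, SynthConfig, generate_fixture


def fixture_networks(bundle: FixtureBundle) -> list[BipartiteNetwork]:
    """The seven relation sets of a fixture: the five generated edge
    lists plus the two computed similarity sets."""
    parts = [
        BipartiteNetwork(name, list(df.itertuples(index=False, name=None)))
        for name, df in bundle.network.edge_lists.items()
    ]
    records = [sim.SequenceRecord(i, s) for i, s in bundle.sequences.records]
    circ_edges, _cutoff = sim.mean_threshold_edges(sim.pairwise_sequence_scores(records))
    parts.append(circ_edges)
    dag = sim.OntologyDag(bundle.ontology.terms, bundle.ontology.attachments)
    diseases = list(bundle.ontology.attachments["disease_id"])
    parts.append(sim.disease_similarity_edges(dag, diseases))
    return parts


class CircWalkClassifier(BaseEstimator, ClassifierMixin):
    """Pair classifier over pre-computed node embeddings.

    ``fit(pairs, y)`` expects a DataFrame with circ_id/disease_id
    columns; features are the 2k-dim concatenation of the two node
    embeddings.  Any of the six supported classifier families can sit
    underneath (XGBoost by default).
    """

    def __init__(self, embedding: EmbeddingMatrix | None = None,
                 classifier: str = "XGB", seed: int = 0,
                 hyperparameters: dict | None = None):
        self.embedding = embedding
        self.classifier = classifier
        self.seed = seed
        self.hyperparameters = hyperparameters

    def _spec(self) -> ClassifierSpec:
        return ClassifierSpec(self.classifier, dict(self.hyperparameters or {}))

    def fit(self, pairs: pd.DataFrame, y):
        if self.embedding is None:
            raise ValueError("an EmbeddingMatrix must be supplied")
        X = featurize_pairs(pairs, self.embedding)
        self.model_ = self._spec().build(seed=self.seed)
        self.model_.fit(X, np.asarray(y))
        self.classes_ = np.array([0, 1])
        return self

    def decision_scores(self, pairs: pd.DataFrame) -> np.ndarray:
        return association_scores(self.model_, featurize_pairs(pairs, self.embedding))

    def predict_proba(self, pairs: pd.DataFrame) -> np.ndarray:
        p1 = self.model_.predict_proba(featurize_pairs(pairs, self.embedding))
        return p1

    def predict(self, pairs: pd.DataFrame) -> np.ndarray:
        return self.model_.predict(featurize_pairs(pairs, self.embedding))


@dataclass
class PipelineResult:
    bundle: FixtureBundle
    network: HeterogeneousNetwork
    embedding: EmbeddingMatrix
    benchmark: pd.DataFrame
    folds: np.ndarray
    report: MetricsReport


def run_fixture_pipeline(
    config: SynthConfig | None = None,
    walk_cfg: WalkConfig | None = None,
    classifier: str = "XGB",
    seed: int = 0,
    n_folds: int = 5,
) -> PipelineResult:
    """The whole method on a synthetic fixture, one call.

    The seed drives fixture generation, walk generation, skip-gram
    initialisation, negative sampling, fold shuffling and classifier
    initialisation.
    """
    config = replace(config or SynthConfig(), seed=seed)
    walk_cfg = replace(walk_cfg or WalkConfig(), seed=seed)
    bundle = generate_fixture(config)
    net = merge_networks(fixture_networks(bundle))
    dw = DeepWalk(**{f: getattr(walk_cfg, f) for f in (
        "walks_per_node", "walk_length", "window", "dim", "epochs", "alpha", "min_alpha", "seed")})
    dw.fit(net)
    emb = dw.embedding_
    pos_edges = BipartiteNetwork(
        "circRNA-disease",
        list(bundle.network.edge_lists["circRNA-disease"].itertuples(index=False, name=None)),
    )
    benchmark = build_benchmark(pos_edges, seed=seed)
    folds = make_folds(benchmark, n_folds=n_folds, seed=seed)
    X = featurize_pairs(benchmark, emb)
    y = benchmark["label"].to_numpy()
    report = cross_validate(X, y, folds, ClassifierSpec(classifier), seed=seed)
    return PipelineResult(
        bundle=bundle, network=net, embedding=emb,
        benchmark=benchmark, folds=folds, report=report,
    )
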