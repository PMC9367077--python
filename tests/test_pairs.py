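"""Benchmark construction: positives, negative sampling, features, folds."""

import numpy as np
import pandas as pd
import pytest

from circwalk.deepwalk import EmbeddingMatrix
from circwalk.network import BipartiteNetwork
from circwalk.pairs import (
    build_positive_pairs,
    candidate_space,
    featurize_pairs,
    make_folds,
    sample_negatives,
)
from circwalk.synthetic import dense_association_edges


def small_embedding(ids, dim=3, seed=0):
    rng = np.random.default_rng(seed)
    return EmbeddingMatrix(ids=list(ids), vectors=rng.normal(size=(len(ids), dim)))


class TestPositivesAndCandidateSpace:
    def test_counts_from_shared_circrna(self):
        net = BipartiteNetwork("circRNA-disease", [("c1", "d1"), ("c1", "d2")])
        pos = build_positive_pairs(net)
        assert len(pos) == 2
        assert pos["circ_id"].nunique() == 1
        assert pos["disease_id"].nunique() == 2

    def test_duplicate_edges_collapse(self):
        net = BipartiteNetwork("circRNA-disease", [("c1", "d1"), ("c1", "d1")])
        assert len(build_positive_pairs(net)) == 1

    def test_fixture_positives_equal_planted_truth(self, pipeline_result):
        bundle = pipeline_result.bundle
        pos = pipeline_result.benchmark.query("label == 1")
        got = set(zip(pos["circ_id"], pos["disease_id"]))
        want = set(map(tuple, bundle.network.positives.to_numpy()))
        assert got == want

    def test_two_by_two_grid_enumerates_unknowns_exactly_once(self):
        space = candidate_space(
            pd.DataFrame({"circ_id": ["c1", "c2"], "disease_id": ["d1", "d2"],
                          "label": [1, 1]}))
        assert space.n_total == 4
        assert space.n_unknown == 2
        unknowns = list(space.iter_unknown())
        assert len(unknowns) == len(set(unknowns)) == 2

    def test_benchmark_design_arithmetic_at_catalogue_scale(self):
        edges = dense_association_edges(474, 64, 575)
        net = BipartiteNetwork("circRNA-disease",
                               list(edges.itertuples(index=False, name=None)))
        space = candidate_space(build_positive_pairs(net))
        assert space.n_total == 474 * 64 == 30336
        assert space.n_unknown == 30336 - 575 == 29761
        assert space.false_negative_exposure == pytest.approx(575 / 29761)


class TestSampleNegatives:
    def test_equal_count_and_disjointness(self):
        edges = dense_association_edges(20, 6, 30)
        pos = build_positive_pairs(
            BipartiteNetwork("circRNA-disease", list(edges.itertuples(index=False, name=None))))
        neg = sample_negatives(pos, seed=3)
        assert len(neg) == len(pos)
        assert (neg["label"] == 0).all()
        pos_set = set(zip(pos["circ_id"], pos["disease_id"]))
        neg_set = set(zip(neg["circ_id"], neg["disease_id"]))
        assert not pos_set & neg_set
        assert len(neg_set) == len(neg)

    def test_forced_sample_takes_entire_unknown_set(self):
        # 2x2 grid with 2 positives -> 2 unknowns, all needed
        pos = pd.DataFrame({"circ_id": ["c1", "c2"], "disease_id": ["d1", "d2"],
                            "label": [1, 1]})
        for seed in (0, 1, 99):
            neg = sample_negatives(pos, seed=seed)
            assert set(zip(neg["circ_id"], neg["disease_id"])) == {("c1", "d2"), ("c2", "d1")}

    def test_sampling_is_uniform_over_unknowns(self):
        # 3x3 grid, 3 diagonal positives -> 6 unknowns, 3 drawn per seed,
        # so each unknown should appear with frequency 1/2
        pos = pd.DataFrame({"circ_id": ["c1", "c2", "c3"],
                            "disease_id": ["d1", "d2", "d3"], "label": [1, 1, 1]})
        counts: dict[tuple, int] = {}
        n_seeds = 2000
        for seed in range(n_seeds):
            neg = sample_negatives(pos, seed=seed)
            for pair in zip(neg["circ_id"], neg["disease_id"]):
                counts[pair] = counts.get(pair, 0) + 1
        assert len(counts) == 6
        se = np.sqrt(0.5 * 0.5 / n_seeds)
        for pair, c in counts.items():
            assert abs(c / n_seeds - 0.5) < 3 * se

    def test_insufficient_unknowns_error(self):
        pos = pd.DataFrame({"circ_id": ["c1", "c1", "c2", "c2"],
                            "disease_id": ["d1", "d2", "d1", "d2"],
                            "label": [1] * 4})
        with pytest.raises(ValueError, match="unknown"):
            sample_negatives(pos, seed=0)

    def test_same_seed_reproduces_sample(self):
        edges = dense_association_edges(15, 5, 20)
        pos = build_positive_pairs(
            BipartiteNetwork("circRNA-disease", list(edges.itertuples(index=False, name=None))))
        pd.testing.assert_frame_equal(sample_negatives(pos, 7), sample_negatives(pos, 7))


class TestFeaturizePairs:
    def test_feature_length_is_twice_embedding_dim(self):
        pairs = pd.DataFrame({"circ_id": ["c1"], "disease_id": ["d1"]})
        emb = small_embedding(["c1", "d1"], dim=20)
        assert featurize_pairs(pairs, emb).shape == (1, 40)

    def test_order_is_circ_then_disease(self):
        pairs = pd.DataFrame({"circ_id": ["c1"], "disease_id": ["d1"]})
        emb = small_embedding(["c1", "d1"], dim=4)
        feats = featurize_pairs(pairs, emb)
        assert np.array_equal(feats[0, :4], emb["c1"])
        assert np.array_equal(feats[0, 4:], emb["d1"])
        swapped = featurize_pairs(
            pd.DataFrame({"circ_id": ["d1"], "disease_id": ["c1"]}), emb)
        assert not np.array_equal(feats, swapped)

    def test_zero_embeddings_give_zero_features(self):
        emb = EmbeddingMatrix(ids=["c1", "d1"], vectors=np.zeros((2, 5)))
        pairs = pd.DataFrame({"circ_id": ["c1"], "disease_id": ["d1"]})
        assert not featurize_pairs(pairs, emb).any()

    def test_missing_embedding_names_the_node(self):
        pairs = pd.DataFrame({"circ_id": ["c1"], "disease_id": ["d_missing"]})
        emb = small_embedding(["c1"])
        with pytest.raises(KeyError, match="d_missing"):
            featurize_pairs(pairs, emb)


class TestMakeFolds:
    def _balanced(self, n):
        half = n // 2
        return pd.DataFrame({
            "circ_id": [f"c{i}" for i in range(n)],
            "disease_id": [f"d{i}" for i in range(n)],
            "label": [1] * half + [0] * (n - half),
        })

    def test_ten_pairs_give_one_of_each_class_per_fold(self):
        pairs = self._balanced(10)
        folds = make_folds(pairs, n_folds=5, seed=0)
        for f in range(1, 6):
            sub = pairs[folds == f]
            assert len(sub) == 2
            assert sub["label"].sum() == 1

    def test_assignment_is_deterministic(self):
        pairs = self._balanced(30)
        assert np.array_equal(make_folds(pairs, seed=5), make_folds(pairs, seed=5))

    def test_balanced_1150_pairs_split_into_230s(self):
        pairs = self._balanced(1150)
        folds = make_folds(pairs, n_folds=5, seed=1)
        sizes = np.bincount(folds)[1:]
        assert list(sizes) == [230] * 5
        for f in range(1, 6):
            assert pairs[folds == f]["label"].mean() == pytest.approx(0.5)

    def test_folds_partition_the_dataset(self):
        pairs = self._balanced(23)
        folds = make_folds(pairs, n_folds=5, seed=2)
        assert set(folds) == {1, 2, 3, 4, 5}
        assert max(np.bincount(folds)[1:]) - min(np.bincount(folds)[1:]) <= 1

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError):
            make_folds(self._balanced(4), n_folds=5, seed=0)
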