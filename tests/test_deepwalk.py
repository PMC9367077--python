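"""Random-walk generation and skip-gram embedding training."""

import itertools

import numpy as np
import pytest

from circwalk.deepwalk import (
    DEFAULT_SWEEP_SIZES,
    DeepWalk,
    WalkConfig,
    embedding_sweep,
    generate_walks,
    train_skipgram,
)
from conftest import toy_network


def cosine(u, v):
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


class TestGenerateWalks:
    def test_two_node_path_forces_alternation(self):
        net = toy_network([("a", "b")])
        walks = generate_walks(net, WalkConfig(walks_per_node=1, walk_length=6, window=2, seed=0))
        for walk in walks:
            for i, node in enumerate(walk):
                assert node == walk[0] if i % 2 == 0 else node != walk[0]

    def test_walks_never_cross_components(self):
        net = toy_network([("a", "b"), ("c", "d")])
        walks = generate_walks(net, WalkConfig(walks_per_node=4, walk_length=10, seed=1))
        for walk in walks:
            assert set(walk) <= {"a", "b"} or set(walk) <= {"c", "d"}

    def test_every_step_is_an_edge(self, pipeline_result):
        net = pipeline_result.network
        walks = generate_walks(net, WalkConfig(walks_per_node=2, walk_length=20, seed=3))
        for walk in walks:
            for u, v in itertools.pairwise(walk):
                assert net.graph.has_edge(u, v)

    def test_uniform_transitions_on_star(self):
        leaves = [f"l{i}" for i in range(4)]
        net = toy_network([("hub", leaf) for leaf in leaves])
        walks = generate_walks(
            net, WalkConfig(walks_per_node=200, walk_length=10, seed=5))
        visits = {leaf: 0 for leaf in leaves}
        total = 0
        for walk in walks:
            for prev, cur in itertools.pairwise(walk):
                if prev == "hub":
                    visits[cur] += 1
                    total += 1
        assert total > 4000
        se = np.sqrt(0.25 * 0.75 / total)
        for leaf in leaves:
            assert abs(visits[leaf] / total - 0.25) < 3 * se

    def test_degree_zero_node_walk_terminates_immediately(self):
        net = toy_network([("a", "b")], extra_nodes=["x"])
        walks = generate_walks(net, WalkConfig(walks_per_node=1, walk_length=5, window=2, seed=0))
        assert [w for w in walks if w[0] == "x"] == [["x"]]

    def test_identical_seed_reproduces_walks(self):
        net = toy_network([("a", "b"), ("b", "c"), ("c", "a")])
        cfg = WalkConfig(walks_per_node=3, walk_length=12, seed=9)
        assert generate_walks(net, cfg) == generate_walks(net, cfg)

    @pytest.mark.parametrize("bad", [
        dict(walk_length=5, window=5),
        dict(dim=1),
        dict(walks_per_node=0),
    ])
    def test_invalid_walk_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            WalkConfig(**bad).validate()


class TestTrainSkipgram:
    def test_requested_dimension_is_honoured(self):
        net = toy_network([("a", "b"), ("b", "c")])
        cfg = WalkConfig(walks_per_node=2, walk_length=10, dim=10, epochs=1, seed=0)
        emb = train_skipgram(generate_walks(net, cfg), cfg)
        assert emb.vectors.shape == (3, 10)
        assert np.isfinite(emb.vectors).all()

    def test_unwalked_node_gets_zero_vector_and_warning(self):
        net = toy_network([("a", "b")])
        cfg = WalkConfig(walks_per_node=2, walk_length=8, dim=4, epochs=1, seed=0)
        walks = generate_walks(net, cfg)
        with pytest.warns(UserWarning, match="absent"):
            emb = train_skipgram(walks, cfg, nodes=["a", "b", "ghost"])
        assert np.all(emb["ghost"] == 0)
        assert emb.unreached == ["ghost"]

    def test_barbell_communities_separate_in_cosine_similarity(self):
        left = [f"L{i}" for i in range(6)]
        right = [f"R{i}" for i in range(6)]
        edges = list(itertools.combinations(left, 2)) + list(itertools.combinations(right, 2))
        edges.append((left[0], right[0]))
        within_means, across_means = [], []
        for seed in (1, 2, 3):
            net = toy_network(edges)
            cfg = WalkConfig(walks_per_node=10, walk_length=20, dim=8, epochs=3, seed=seed)
            emb = train_skipgram(generate_walks(net, cfg), cfg)
            within = [cosine(emb[a], emb[b])
                      for grp in (left, right) for a, b in itertools.combinations(grp, 2)]
            across = [cosine(emb[a], emb[b]) for a in left for b in right]
            within_means.append(np.mean(within))
            across_means.append(np.mean(across))
        assert np.mean(within_means) > np.mean(across_means)

    def test_associated_pairs_sit_closer_than_non_associated(self, pipeline_result):
        emb = pipeline_result.embedding
        bundle = pipeline_result.bundle
        positives = set(map(tuple, bundle.network.positives.to_numpy()))
        circ = sorted({c for c, _ in positives})
        diseases = sorted({d for _, d in positives})
        pos_d, neg_d = [], []
        for c in circ:
            for d in diseases:
                dist = float(np.linalg.norm(emb[c] - emb[d]))
                (pos_d if (c, d) in positives else neg_d).append(dist)
        assert np.mean(pos_d) < np.mean(neg_d)

    def test_training_is_bit_reproducible(self):
        net = toy_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        cfg = WalkConfig(walks_per_node=4, walk_length=12, dim=6, epochs=2, seed=21)
        e1 = train_skipgram(generate_walks(net, cfg), cfg)
        e2 = train_skipgram(generate_walks(net, cfg), cfg)
        assert np.array_equal(e1.vectors, e2.vectors)

    def test_heldout_objective_improves_with_training(self):
        edges = [(f"n{i}", f"n{(i + 1) % 12}") for i in range(12)]
        edges += [(f"n{i}", f"n{(i + 2) % 12}") for i in range(12)]
        net = toy_network(edges)
        cfg = WalkConfig(walks_per_node=12, walk_length=20, dim=8, epochs=5, seed=2)
        walks = generate_walks(net, cfg)
        held_out = walks[::7]
        train_walks = [w for i, w in enumerate(walks) if i % 7]
        emb = train_skipgram(train_walks, cfg, eval_walks=held_out)
        ll = emb._model.epoch_loglik_
        assert len(ll) == cfg.epochs
        assert ll[-1] > ll[0]


class TestEmbeddingSweep:
    def test_default_sizes_are_multiples_of_ten_up_to_200(self):
        assert len(DEFAULT_SWEEP_SIZES) == 20
        assert min(DEFAULT_SWEEP_SIZES) == 10
        assert max(DEFAULT_SWEEP_SIZES) == 200
        assert all(k % 10 == 0 for k in DEFAULT_SWEEP_SIZES)

    def test_single_size_matches_direct_training(self):
        net = toy_network([("a", "b"), ("b", "c"), ("c", "a")])
        cfg = WalkConfig(walks_per_node=3, walk_length=10, dim=10, epochs=2, seed=4)
        sweep = embedding_sweep(net, sizes=(10,), cfg=cfg)
        direct = train_skipgram(generate_walks(net, cfg), cfg, nodes=net.nodes)
        assert np.array_equal(sweep[10].vectors, direct.vectors)

    def test_all_sizes_cover_identical_node_set(self):
        net = toy_network([("a", "b"), ("b", "c")])
        cfg = WalkConfig(walks_per_node=2, walk_length=8, epochs=1, seed=0)
        sweep = embedding_sweep(net, sizes=(4, 6), cfg=cfg)
        ids = {tuple(e.ids) for e in sweep.values()}
        assert len(ids) == 1
        assert sweep[4].dim == 4 and sweep[6].dim == 6

    def test_estimator_interface_roundtrip(self):
        net = toy_network([("a", "b"), ("b", "c"), ("c", "a")])
        dw = DeepWalk(walks_per_node=2, walk_length=8, window=2, dim=4, epochs=1, seed=0)
        assert dw.get_params()["dim"] == 4
        dw.set_params(dim=6).fit(net)
        assert dw.transform(["a", "b"]).shape == (2, 6)
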