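"""DeepWalk node embeddings: truncated uniform random walks fed to a
skip-gram model with hierarchical softmax.

The trainer is written here in full (walk generation, Huffman coding,
and the SGD inner loop, jitted with numba) so that every step of the
embedding — the core of the pipeline — is explicit and reproducible.
Walks use uniform next-step transitions on the unweighted heterogeneous
graph; node kinds play no role during walking, the heterogeneity lives
only in which edges exist.

Reproducibility contract: a fixed (network, config, seed) yields
identical walks and, with the single-threaded trainer, bit-identical
embeddings.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

from .network import HeterogeneousNetwork

DEFAULT_SWEEP_SIZES = tuple(range(10, 201, 10))


@dataclass
class WalkConfig:
    """Walk and skip-gram hyperparameters.

    Defaults follow the original DeepWalk presentation: 10 walks per
    node of 80 steps, context window 5, 5 epochs.  The learning rate
    decays linearly from ``alpha`` to ``min_alpha`` over training.
    """

    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 5
    dim: int = 20
    epochs: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.window < 1 or self.walk_length <= self.window:
            raise ValueError("require walk_length > window >= 1")
        if self.dim < 2:
            raise ValueError("embedding dim must be >= 2")
        if self.walks_per_node < 1 or self.epochs < 1:
            raise ValueError("walks_per_node and epochs must be >= 1")


def generate_walks(
    net: HeterogeneousNetwork, cfg: WalkConfig, rng: np.random.Generator | None = None
) -> list[list[str]]:
    """``walks_per_node`` uniform random walks of ``walk_length`` nodes
    from every node.  Node order is shuffled per pass (as in DeepWalk);
    a walk stops early only at a degree-0 node."""
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    nodes = net.nodes
    if not nodes:
        raise ValueError("network is empty")
    neigh = {n: net.neighbors(n) for n in nodes}
    walks: list[list[str]] = []
    order = np.arange(len(nodes))
    for _ in range(cfg.walks_per_node):
        rng.shuffle(order)
        for idx in order:
            cur = nodes[idx]
            walk = [cur]
            for _ in range(cfg.walk_length - 1):
                nbrs = neigh[cur]
                if not nbrs:
                    break
                cur = nbrs[rng.integers(len(nbrs))]
                walk.append(cur)
            walks.append(walk)
    return walks


def _build_huffman(counts: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Huffman coding over word frequencies, as in word2vec hierarchical
    softmax.  Returns per-word (inner-node index path, binary code);
    ties broken by insertion order for determinism."""
    v = len(counts)
    if v == 1:
        return [np.zeros(0, dtype=np.int32)], [np.zeros(0, dtype=np.int8)]
    heap: list[tuple[int, int, int]] = [(int(c), i, i) for i, c in enumerate(counts)]
    heapq.heapify(heap)
    parent = np.full(2 * v - 1, -1, dtype=np.int64)
    binary = np.zeros(2 * v - 1, dtype=np.int8)
    nxt = v
    order = v
    while len(heap) > 1:
        c1, _, n1 = heapq.heappop(heap)
        c2, _, n2 = heapq.heappop(heap)
        parent[n1] = parent[n2] = nxt
        binary[n2] = 1
        heapq.heappush(heap, (c1 + c2, order, nxt))
        nxt += 1
        order += 1
    points: list[np.ndarray] = []
    codes: list[np.ndarray] = []
    for w in range(v):
        path_codes: list[int] = []
        path_points: list[int] = []
        node = w
        while parent[node] != -1:
            path_codes.append(int(binary[node]))
            node = parent[node]
            path_points.append(int(node) - v)  # inner-node index
        points.append(np.array(path_points[::-1], dtype=np.int32))
        codes.append(np.array(path_codes[::-1], dtype=np.int8))
    return points, codes


@njit(cache=False)
def _train_epoch(
    tokens: np.ndarray,
    offsets: np.ndarray,
    walk_order: np.ndarray,
    syn0: np.ndarray,
    syn1: np.ndarray,
    points_flat: np.ndarray,
    codes_flat: np.ndarray,
    path_offsets: np.ndarray,
    window: int,
    alpha_start: float,
    alpha_end: float,
    words_done: int,
    total_words: int,
) -> int:
    dim = syn0.shape[1]
    neu1e = np.empty(dim)
    for wi in range(walk_order.shape[0]):
        w = walk_order[wi]
        start, stop = offsets[w], offsets[w + 1]
        n = stop - start
        for i in range(n):
            alpha = alpha_start + (alpha_end - alpha_start) * (words_done / total_words)
            words_done += 1
            center = tokens[start + i]
            lo = i - window if i - window > 0 else 0
            hi = i + window + 1 if i + window + 1 < n else n
            for j in range(lo, hi):
                if j == i:
                    continue
                context = tokens[start + j]
                for d in range(dim):
                    neu1e[d] = 0.0
                for p in range(path_offsets[context], path_offsets[context + 1]):
                    node = points_flat[p]
                    code = codes_flat[p]
                    f = 0.0
                    for d in range(dim):
                        f += syn0[center, d] * syn1[node, d]
                    if f > 8.0:
                        f = 1.0
                    elif f < -8.0:
                        f = 0.0
                    else:
                        f = 1.0 / (1.0 + np.exp(-f))
                    g = (1.0 - code - f) * alpha
                    for d in range(dim):
                        neu1e[d] += g * syn1[node, d]
                        syn1[node, d] += g * syn0[center, d]
                for d in range(dim):
                    syn0[center, d] += neu1e[d]
    return words_done


@dataclass
class EmbeddingMatrix:
    """The learned mapping Phi: node id -> k-dimensional real vector."""

    ids: list[str]
    vectors: np.ndarray
    kinds: dict[str, str] = field(default_factory=dict)
    unreached: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def __getitem__(self, node_id: str) -> np.ndarray:
        return self.vectors[self._index[node_id]]

    def take(self, ids: list[str]) -> np.ndarray:
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise KeyError(f"no embedding for nodes {missing[:5]}")
        return self.vectors[[self._index[i] for i in ids]]


class _SkipGram:
    """Hierarchical-softmax skip-gram over tokenized walks; exposes
    per-epoch held-out log-likelihood so training progress on the
    objective (product of context probabilities) is observable."""

    def __init__(self, walks: list[list[str]], vocab: list[str], cfg: WalkConfig):
        self.cfg = cfg
        self.vocab = vocab
        self.word_index = {w: i for i, w in enumerate(vocab)}
        flat: list[int] = []
        offsets = [0]
        for walk in walks:
            flat.extend(self.word_index[w] for w in walk)
            offsets.append(len(flat))
        self.tokens = np.array(flat, dtype=np.int32)
        self.offsets = np.array(offsets, dtype=np.int64)
        counts = np.bincount(self.tokens, minlength=len(vocab))
        self.counts = counts
        points, codes = _build_huffman(np.maximum(counts, 1))
        self.points_flat = np.concatenate(points) if points else np.zeros(0, np.int32)
        self.codes_flat = np.concatenate(codes).astype(np.float64) if codes else np.zeros(0)
        self.path_offsets = np.zeros(len(vocab) + 1, dtype=np.int64)
        self.path_offsets[1:] = np.cumsum([len(p) for p in points])
        self.epoch_loglik_: list[float] = []

    def train(self, rng: np.random.Generator, eval_walks: list[list[str]] | None = None):
        cfg = self.cfg
        v, k = len(self.vocab), cfg.dim
        self.syn0 = (rng.random((v, k)) - 0.5) / k
        self.syn1 = np.zeros((max(v - 1, 1), k))
        total_words = max(cfg.epochs * len(self.tokens), 1)
        done = 0
        n_walks = len(self.offsets) - 1
        for _ in range(cfg.epochs):
            order = rng.permutation(n_walks).astype(np.int64)
            done = _train_epoch(
                self.tokens, self.offsets, order, self.syn0, self.syn1,
                self.points_flat, self.codes_flat, self.path_offsets,
                cfg.window, cfg.alpha, cfg.min_alpha, done, total_words,
            )
            if eval_walks is not None:
                self.epoch_loglik_.append(self.mean_log_likelihood(eval_walks))
        return self

    def _pair_loglik(self, center: int, context: int) -> float:
        ll = 0.0
        for p in range(self.path_offsets[context], self.path_offsets[context + 1]):
            node = self.points_flat[p]
            code = self.codes_flat[p]
            f = float(self.syn0[center] @ self.syn1[node])
            # P(branch) = sigma(f) for code 0, sigma(-f) for code 1
            z = -f if code == 0 else f
            ll += -np.logaddexp(0.0, z)
        return ll

    def mean_log_likelihood(self, walks: list[list[str]]) -> float:
        """Average skip-gram log P(context | center) over all windows."""
        total, n = 0.0, 0
        w = self.cfg.window
        for walk in walks:
            idx = [self.word_index[t] for t in walk if t in self.word_index]
            for i, center in enumerate(idx):
                for j in range(max(0, i - w), min(len(idx), i + w + 1)):
                    if j == i:
                        continue
                    total += self._pair_loglik(center, idx[j])
                    n += 1
        return total / max(n, 1)


class DeepWalk(BaseEstimator, TransformerMixin):
    """DeepWalk as a scikit-learn style transformer over graph nodes.

    ``fit`` takes a :class:`HeterogeneousNetwork` (or anything with
    ``nodes``/``neighbors``), generates walks and trains the skip-gram;
    ``transform`` maps node ids to their embedding rows.

    Parameters mirror :class:`WalkConfig`.  Fitted attributes:

    embedding_ : EmbeddingMatrix
    walks_ : the generated walks (reused by :func:`embedding_sweep`)
    """

    def __init__(self, walks_per_node: int = 10, walk_length: int = 80,
                 window: int = 5, dim: int = 20, epochs: int = 5,
                 alpha: float = 0.025, min_alpha: float = 1e-4, seed: int = 0):
        self.walks_per_node = walks_per_node
        self.walk_length = walk_length
        self.window = window
        self.dim = dim
        self.epochs = epochs
        self.alpha = alpha
        self.min_alpha = min_alpha
        self.seed = seed

    def _config(self) -> WalkConfig:
        return WalkConfig(
            walks_per_node=self.walks_per_node, walk_length=self.walk_length,
            window=self.window, dim=self.dim, epochs=self.epochs,
            alpha=self.alpha, min_alpha=self.min_alpha, seed=self.seed,
        )

    def fit(self, X: HeterogeneousNetwork, y=None, walks: list[list[str]] | None = None):
        cfg = self._config()
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        self.walks_ = walks if walks is not None else generate_walks(X, cfg, rng)
        self.embedding_ = train_skipgram(
            self.walks_, cfg, nodes=X.nodes,
            kinds={n: X.kind(n) for n in X.nodes},
            rng=np.random.default_rng(cfg.seed + 1),
        )
        return self

    def transform(self, node_ids: list[str]) -> np.ndarray:
        return self.embedding_.take(list(node_ids))


def train_skipgram(
    walks: list[list[str]],
    cfg: WalkConfig,
    nodes: list[str] | None = None,
    kinds: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
    eval_walks: list[list[str]] | None = None,
) -> EmbeddingMatrix:
    """Train skip-gram with hierarchical softmax on the walks and return
    one k-vector per node.  Nodes absent from every walk get a zero
    vector with a warning (flagged in ``EmbeddingMatrix.unreached``)."""
    cfg.validate()
    if not walks:
        raise ValueError("no walks to train on")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    vocab = sorted({n for w in walks for n in w})
    model = _SkipGram(walks, vocab, cfg)
    model.train(rng, eval_walks=eval_walks)
    all_nodes = sorted(nodes) if nodes is not None else vocab
    vectors = np.zeros((len(all_nodes), cfg.dim))
    unreached = []
    for i, n in enumerate(all_nodes):
        if n in model.word_index:
            vectors[i] = model.syn0[model.word_index[n]]
        else:
            unreached.append(n)
    if unreached:
        warnings.warn(
            f"{len(unreached)} node(s) absent from all walks; zero vectors assigned",
            stacklevel=2,
        )
    emb = EmbeddingMatrix(ids=all_nodes, vectors=vectors, kinds=kinds or {}, unreached=unreached)
    emb._model = model  # kept for objective introspection in diagnostics
    return emb


def embedding_sweep(
    net: HeterogeneousNetwork,
    sizes: tuple[int, ...] = DEFAULT_SWEEP_SIZES,
    cfg: WalkConfig | None = None,
) -> dict[int, EmbeddingMatrix]:
    """One embedding per requested dimension.  Walks are generated once
    per seed and reused across sizes; only the trainer reruns."""
    if not sizes:
        raise ValueError("sizes must be nonempty")
    cfg = cfg or WalkConfig()
    rng = np.random.default_rng(cfg.seed)
    walks = generate_walks(net, cfg, rng)
    kinds = {n: net.kind(n) for n in net.nodes}
    out: dict[int, EmbeddingMatrix] = {}
    for k in sizes:
        kcfg = replace(cfg, dim=k)
        out[k] = train_skipgram(
            walks, kcfg, nodes=net.nodes, kinds=kinds,
            rng=np.random.default_rng(cfg.seed + 1),
        )
    return out
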