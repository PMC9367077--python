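"""Synthetic fixtures with planted ceRNA structure.

Every input the pipeline needs — five bipartite edge lists, circRNA
sequences, and a small disease ontology — is generated here with a known
community structure, so the whole pipeline can be exercised and scored
against ground truth without touching any external database.

The planted model: nodes of all four kinds are split into communities
(the synthetic analogue of disease mechanisms).  Regulatory edges
(circRNA-miRNA, miRNA-mRNA, miRNA-disease, mRNA-disease) are Bernoulli
draws with probability ``p_within`` inside a community and ``p_between``
across.  A circRNA-disease pair is a ground-truth positive exactly when
the two live in the same community *and* share at least one miRNA — the
miRNA-sponge path the ceRNA hypothesis predicts.  Sequences within a
community are mutated copies of a common ancestor; the ontology places
same-community diseases under the same subtree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_BASES = np.array(list("ACGT"))

EDGE_LIST_NAMES = (
    "circRNA-disease",
    "circRNA-miRNA",
    "miRNA-disease",
    "miRNA-mRNA",
    "mRNA-disease",
)


@dataclass
class SynthConfig:
    """Fixture parameters; defaults are the benchmark study conditions
    (~60 circRNAs / 40 miRNAs / 40 mRNAs / 10 diseases in 3 communities
    with strong planting)."""

    n_circ: int = 60
    n_mirna: int = 40
    n_mrna: int = 40
    n_disease: int = 10
    n_modules: int = 3
    p_within: float = 0.3
    p_between: float = 0.02
    seq_length: int = 120
    seq_mutation_rate: float = 0.05
    ontology_branching: int = 3
    ontology_depth: int = 2
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_circ, self.n_mirna, self.n_mrna, self.n_disease, self.n_modules)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        for p in (self.p_within, self.p_between, self.seq_mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_within <= self.p_between:
            raise ValueError("p_within must exceed p_between (planted structure)")
        if self.seq_length < 20:
            raise ValueError("seq_length must be >= 20")
        if self.ontology_depth < 2:
            raise ValueError("ontology_depth must be >= 2")
        if self.ontology_branching < 2:
            raise ValueError("ontology_branching must be >= 2")


def _node_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def _communities(n: int, n_modules: int) -> np.ndarray:
    # round-robin keeps community sizes within one of each other
    return np.arange(n) % n_modules


@dataclass
class NetworkFixture:
    edge_lists: dict[str, pd.DataFrame]
    positives: pd.DataFrame  # columns circ_id, disease_id
    communities: dict[str, int]  # node id -> community index

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.edge_lists.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        self.positives.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


def expected_positive_count(config: SynthConfig) -> float:
    """Expected number of planted positives: same-community (c, d) pairs
    with >=1 shared miRNA, where a shared miRNA m needs both the c-m and
    m-d edge to be drawn."""
    sizes = np.bincount(_communities(config.n_mirna, config.n_modules), minlength=config.n_modules)
    circ_sizes = np.bincount(_communities(config.n_circ, config.n_modules), minlength=config.n_modules)
    dis_sizes = np.bincount(_communities(config.n_disease, config.n_modules), minlength=config.n_modules)
    pw2, pb2 = config.p_within**2, config.p_between**2
    total = 0.0
    for mod in range(config.n_modules):
        m_in = sizes[mod]
        m_out = config.n_mirna - m_in
        p_path = 1.0 - (1.0 - pw2) ** m_in * (1.0 - pb2) ** m_out
        total += circ_sizes[mod] * dis_sizes[mod] * p_path
    return total


def _bernoulli_edges(
    rng: np.random.Generator,
    left: list[str],
    left_comm: np.ndarray,
    right: list[str],
    right_comm: np.ndarray,
    p_within: float,
    p_between: float,
) -> pd.DataFrame:
    same = left_comm[:, None] == right_comm[None, :]
    probs = np.where(same, p_within, p_between)
    draws = rng.random(probs.shape) < probs
    li, ri = np.nonzero(draws)
    return pd.DataFrame({"source_id": [left[i] for i in li], "target_id": [right[j] for j in ri]})


def generate_network_fixture(config: SynthConfig) -> NetworkFixture:
    """Draw the five bipartite edge lists and the planted ground truth.

    The circRNA-disease edge list *is* the ground-truth positive set: in
    the real pipeline the known associations both sit in the graph and
    supply the positive labels, and the fixture mirrors that design.
    """
    config.validate()
    if expected_positive_count(config) < 10:
        raise ValueError(
            "config yields fewer than 10 expected positives; benchmark unbuildable"
        )
    rng = np.random.default_rng(config.seed)
    circ = _node_ids("circ_", config.n_circ)
    mirna = _node_ids("mir_", config.n_mirna)
    mrna = _node_ids("mrna_", config.n_mrna)
    disease = _node_ids("dis_", config.n_disease)
    c_circ = _communities(config.n_circ, config.n_modules)
    c_mir = _communities(config.n_mirna, config.n_modules)
    c_mrna = _communities(config.n_mrna, config.n_modules)
    c_dis = _communities(config.n_disease, config.n_modules)

    pw, pb = config.p_within, config.p_between
    circ_mir = _bernoulli_edges(rng, circ, c_circ, mirna, c_mir, pw, pb)
    mir_dis = _bernoulli_edges(rng, mirna, c_mir, disease, c_dis, pw, pb)
    mir_mrna = _bernoulli_edges(rng, mirna, c_mir, mrna, c_mrna, pw, pb)
    mrna_dis = _bernoulli_edges(rng, mrna, c_mrna, disease, c_dis, pw, pb)

    # positives: same community, >=1 shared miRNA on a circ-miRNA-disease path
    mir_of_circ = circ_mir.groupby("source_id")["target_id"].agg(set).to_dict()
    mir_of_dis = mir_dis.groupby("target_id")["source_id"].agg(set).to_dict()
    pos_rows = []
    for ci, c in enumerate(circ):
        for di, d in enumerate(disease):
            if c_circ[ci] != c_dis[di]:
                continue
            if mir_of_circ.get(c, set()) & mir_of_dis.get(d, set()):
                pos_rows.append((c, d))
    positives = pd.DataFrame(pos_rows, columns=["circ_id", "disease_id"])

    edge_lists = {
        "circRNA-disease": positives.rename(
            columns={"circ_id": "source_id", "disease_id": "target_id"}
        ),
        "circRNA-miRNA": circ_mir,
        "miRNA-disease": mir_dis,
        "miRNA-mRNA": mir_mrna,
        "mRNA-disease": mrna_dis,
    }
    communities = {}
    for ids, comm in ((circ, c_circ), (mirna, c_mir), (mrna, c_mrna), (disease, c_dis)):
        communities.update({i: int(c) for i, c in zip(ids, comm)})
    return NetworkFixture(edge_lists=edge_lists, positives=positives, communities=communities)


def dense_association_edges(n_circ: int, n_disease: int, n_pairs: int) -> pd.DataFrame:
    """A deterministic circRNA-disease edge list with exactly ``n_pairs``
    distinct pairs spanning exactly ``n_circ`` circRNAs and
    ``n_disease`` diseases — the shape of a curated association set,
    used to study benchmark-design arithmetic at any scale."""
    if n_pairs < max(n_circ, n_disease) or n_pairs > n_circ * n_disease:
        raise ValueError("n_pairs cannot span the requested node counts")
    circ = _node_ids("circ_", n_circ)
    dis = _node_ids("dis_", n_disease)
    pairs = [(circ[i], dis[i % n_disease]) for i in range(n_circ)]
    extra, offset = 0, 1
    while len(pairs) < n_pairs:
        cand = (circ[extra % n_circ], dis[(extra + offset) % n_disease])
        if cand not in pairs:
            pairs.append(cand)
        extra += 1
        if extra % n_circ == 0:
            offset += 1
    return pd.DataFrame(pairs, columns=["source_id", "target_id"])


@dataclass
class SequenceFixture:
    records: list[tuple[str, str]]  # (circ_id, sequence)
    communities: dict[str, int]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.records:
                fh.write(f">{name}\n{seq}\n")


def generate_sequence_fixture(config: SynthConfig) -> SequenceFixture:
    """One nucleotide sequence per circRNA: a community-shared ancestor
    with independent per-base substitutions at ``seq_mutation_rate``."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    circ = _node_ids("circ_", config.n_circ)
    comm = _communities(config.n_circ, config.n_modules)
    ancestors = rng.integers(0, 4, size=(config.n_modules, config.seq_length))
    records = []
    for cid, c in zip(circ, comm):
        seq = ancestors[c].copy()
        mutate = rng.random(config.seq_length) < config.seq_mutation_rate
        # substitution to one of the three *other* bases
        shifts = rng.integers(1, 4, size=config.seq_length)
        seq[mutate] = (seq[mutate] + shifts[mutate]) % 4
        records.append((cid, "".join(_BASES[seq])))
    return SequenceFixture(records=records, communities={i: int(c) for i, c in zip(circ, comm)})


@dataclass
class OntologyFixture:
    terms: pd.DataFrame  # columns term_id, tree_number
    attachments: pd.DataFrame  # columns disease_id, term_id

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.terms.to_csv(outdir / "ontology.tsv", sep="\t", index=False)
        self.attachments.to_csv(outdir / "disease_terms.tsv", sep="\t", index=False)


def generate_ontology_fixture(config: SynthConfig) -> OntologyFixture:
    """A complete ``branching``-ary tree of depth ``ontology_depth``
    encoded MeSH-style (dot-separated tree numbers; the parent's tree
    number is the longest proper prefix).  Each disease attaches to one
    leaf; same-community diseases share a depth-1 subtree, so semantic
    similarity is higher inside communities than across."""
    config.validate()
    b, depth = config.ontology_branching, config.ontology_depth
    rows = [("T_root", "01")]
    level = ["01"]
    for _ in range(depth):
        nxt = []
        for tn in level:
            for j in range(b):
                child = f"{tn}.{j + 1:02d}"
                rows.append((f"T_{child}", child))
                nxt.append(child)
        level = nxt
    terms = pd.DataFrame(rows, columns=["term_id", "tree_number"])
    leaves = [f"T_{tn}" for tn in level]

    disease = _node_ids("dis_", config.n_disease)
    comm = _communities(config.n_disease, config.n_modules)
    leaves_per_subtree = len(leaves) // b
    counters = [0] * b
    attach = []
    for d, c in zip(disease, comm):
        subtree = c % b
        pool = leaves[subtree * leaves_per_subtree : (subtree + 1) * leaves_per_subtree]
        attach.append((d, pool[counters[subtree] % len(pool)]))
        counters[subtree] += 1
    attachments = pd.DataFrame(attach, columns=["disease_id", "term_id"])
    return OntologyFixture(terms=terms, attachments=attachments)


@dataclass
class FixtureBundle:
    network: NetworkFixture
    sequences: SequenceFixture
    ontology: OntologyFixture
    config: SynthConfig = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.network.write(outdir)
        self.sequences.write_fasta(outdir / "circ_sequences.fasta")
        self.ontology.write(outdir)


def generate_fixture(config: SynthConfig | None = None) -> FixtureBundle:
    """All fixture inputs in one call (the `simulate` CLI entry point)."""
    config = config or SynthConfig()
    return FixtureBundle(
        network=generate_network_fixture(config),
        sequences=generate_sequence_fixture(config),
        ontology=generate_ontology_fixture(config),
        config=config,
    )
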