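"""Heterogeneous ceRNA network assembly.

Nodes are circRNAs, miRNAs, mRNAs and diseases; edges come from seven
bipartite relation sets (five association sets plus two computed
similarity sets).  The merged graph is undirected and unweighted: every
relation is treated as a symmetric association, and the random-walk
embedding downstream uses uniform transitions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

KINDS = ("circRNA", "miRNA", "mRNA", "disease")

#: relation label -> (kind of first column, kind of second column)
RELATIONS: dict[str, tuple[str, str]] = {
    "circRNA-disease": ("circRNA", "disease"),
    "circRNA-miRNA": ("circRNA", "miRNA"),
    "miRNA-disease": ("miRNA", "disease"),
    "miRNA-mRNA": ("miRNA", "mRNA"),
    "mRNA-disease": ("mRNA", "disease"),
    "circRNA-circRNA": ("circRNA", "circRNA"),
    "disease-disease": ("disease", "disease"),
}

_WS = re.compile(r"\s+")


def normalize_disease_name(name: str) -> str:
    """Case-fold and collapse whitespace; the first, mechanical layer of
    disease-name unification (synonym tables handle the rest)."""
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class NodeRef:
    id: str
    kind: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")
        if self.kind not in KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")


class BipartiteNetwork:
    """One relation set: a deduplicated collection of unordered id pairs.

    Edge tuples are stored in (first-kind, second-kind) column order for
    heterotypic relations and in sorted order for homotypic ones, so the
    representation is canonical and comparable.
    """

    def __init__(self, relation: str, edges: Iterable[tuple[str, str]] = ()):
        if relation not in RELATIONS:
            raise ValueError(f"unknown relation {relation!r}")
        self.relation = relation
        self.kinds = RELATIONS[relation]
        homotypic = self.kinds[0] == self.kinds[1]
        canon = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop {a!r} in relation {relation}")
            canon.add(tuple(sorted((a, b))) if homotypic else (a, b))
        self.edges: frozenset[tuple[str, str]] = frozenset(canon)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(sorted(self.edges))

    def node_refs(self) -> list[NodeRef]:
        ka, kb = self.kinds
        refs = {NodeRef(a, ka) for a, b in self.edges}
        refs |= {NodeRef(b, kb) for a, b in self.edges}
        return sorted(refs, key=lambda r: (r.kind, r.id))


class IdentifierMap:
    """Alias -> canonical id mapping, scoped per node kind.

    circRNAs without a canonical mapping are *dropped* during
    unification (the reference catalogue defines the universe).  Disease
    aliases fall back to their normalized form when no synonym entry
    matches; miRNA/mRNA ids pass through untouched.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, str]] | None = None):
        self._maps: dict[str, dict[str, str]] = {k: {} for k in KINDS}
        if entries:
            for kind, table in entries.items():
                for alias, canonical in table.items():
                    self.add(kind, alias, canonical)

    def add(self, kind: str, alias: str, canonical: str) -> None:
        if kind not in KINDS:
            raise ValueError(f"unknown kind {kind!r}")
        key = normalize_disease_name(alias) if kind == "disease" else alias
        table = self._maps[kind]
        if key in table and table[key] != canonical:
            raise ValueError(
                f"alias {alias!r} ({kind}) maps to both {table[key]!r} and {canonical!r}"
            )
        table[key] = canonical
        # canonical ids map to themselves
        ckey = normalize_disease_name(canonical) if kind == "disease" else canonical
        table.setdefault(ckey, canonical)

    def canonical(self, kind: str, raw: str) -> str | None:
        """Canonical id for *raw*, or None when a circRNA is unmapped."""
        if kind == "disease":
            key = normalize_disease_name(raw)
            return self._maps[kind].get(key, key)
        if kind == "circRNA" and self._maps["circRNA"]:
            return self._maps[kind].get(raw)
        return self._maps[kind].get(raw, raw)

    @classmethod
    def identity(cls) -> "IdentifierMap":
        return cls()


def unify_identifiers(
    raw_edges: Sequence[tuple[str, str]],
    relation: str,
    id_map: IdentifierMap,
) -> tuple[BipartiteNetwork, int]:
    """Replace aliases by canonical ids; drop records whose circRNA has no
    canonical mapping.  Returns (network, number of dropped records)."""
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    ka, kb = RELATIONS[relation]
    kept: list[tuple[str, str]] = []
    dropped = 0
    bad_lines: list[int] = []
    for lineno, row in enumerate(raw_edges, start=1):
        if len(row) != 2 or not row[0] or not row[1]:
            bad_lines.append(lineno)
            continue
        a = id_map.canonical(ka, row[0])
        b = id_map.canonical(kb, row[1])
        if a is None or b is None:
            dropped += 1
            continue
        kept.append((a, b))
    if bad_lines:
        raise ValueError(f"malformed rows (need 2 id columns) at lines {bad_lines}")
    return BipartiteNetwork(relation, kept), dropped


class HeterogeneousNetwork:
    """The merged graph G = (V, E) over all four node kinds.

    Thin wrapper over an undirected ``networkx.Graph`` whose nodes carry
    a ``kind`` attribute and whose edges record the relations that
    contributed them.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_node(self, ref: NodeRef) -> None:
        existing = self.graph.nodes.get(ref.id)
        if existing is not None and existing["kind"] != ref.kind:
            raise ValueError(
                f"id {ref.id!r} used as both {existing['kind']} and {ref.kind}"
            )
        self.graph.add_node(ref.id, kind=ref.kind)

    def add_part(self, part: BipartiteNetwork) -> None:
        for ref in part.node_refs():
            self.add_node(ref)
        for a, b in part.edges:
            if self.graph.has_edge(a, b):
                self.graph.edges[a, b]["relations"].add(part.relation)
            else:
                self.graph.add_edge(a, b, relations={part.relation})

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == kind)

    def neighbors(self, node_id: str) -> list[str]:
        return sorted(self.graph.neighbors(node_id))

    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def summary(self) -> dict:
        per_kind = {k: len(self.nodes_of_kind(k)) for k in KINDS}
        per_relation: dict[str, int] = {}
        for _, _, data in self.graph.edges(data=True):
            for rel in data["relations"]:
                per_relation[rel] = per_relation.get(rel, 0) + 1
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "nodes_per_kind": per_kind,
            "edges_per_relation": per_relation,
        }


def merge_networks(parts: Iterable[BipartiteNetwork]) -> HeterogeneousNetwork:
    """Union of nodes and edges across relation sets; duplicate edges
    collapse, conflicting kind assignments are a hard error."""
    net = HeterogeneousNetwork()
    for part in parts:
        net.add_part(part)
    return net


@dataclass
class ConnectivityReport:
    component_sizes: list[int]
    n_components: int
    isolated: list[str] = field(default_factory=list)


def connectivity_report(net: HeterogeneousNetwork) -> ConnectivityReport:
    """Component structure plus degree-0 nodes (their embeddings will see
    no walk context beyond themselves)."""
    comps = sorted((len(c) for c in nx.connected_components(net.graph)), reverse=True)
    isolated = sorted(n for n in net.graph.nodes if net.graph.degree[n] == 0)
    return ConnectivityReport(component_sizes=comps, n_components=len(comps), isolated=isolated)
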