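"""Readers and writers for the plain-text interchange formats: two-column
TSV edge lists, FASTA sequences, ontology tables and embedding TSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .deepwalk import EmbeddingMatrix
from .network import RELATIONS, BipartiteNetwork
from .similarity import SequenceRecord


def read_edge_tsv(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 id columns, found {df.shape[1]}")
    return list(df.itertuples(index=False, name=None))

def write_edge_tsv(net: BipartiteNetwork, path: str | Path) -> None:
    pd.DataFrame(sorted(net.edges), columns=["source_id", "target_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_lists(directory: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Load every ``<relation>.tsv`` present in *directory*."""
    directory = Path(directory)
    out = {}
    for relation in RELATIONS:
        path = directory / f"{relation}.tsv"
        if path.exists():
            out[relation] = read_edge_tsv(path)
    if not out:
        raise FileNotFoundError(f"no <relation>.tsv edge lists under {directory}")
    return out


def read_fasta_records(path: str | Path) -> list[SequenceRecord]:
    return [SequenceRecord(id=r.id, sequence=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def read_ontology(terms_path: str | Path, attachments_path: str | Path):
    terms = pd.read_csv(terms_path, sep="\t", dtype=str)
    attachments = pd.read_csv(attachments_path, sep="\t", dtype=str)
    return terms, attachments


def write_embeddings(emb: EmbeddingMatrix, path: str | Path) -> None:
    cols = {f"v{i + 1}": emb.vectors[:, i] for i in range(emb.dim)}
    df = pd.DataFrame({"node_id": emb.ids, "kind": [emb.kinds.get(n, "") for n in emb.ids]} | cols)
    df.to_csv(path, sep="\t", index=False)


def read_embeddings(path: str | Path) -> EmbeddingMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().split()
    if first and first[0] == "node_id":
        df = pd.read_csv(path, sep="\t")
        vec_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        return EmbeddingMatrix(
            ids=list(df["node_id"]),
            vectors=df[vec_cols].to_numpy(float),
            kinds=dict(zip(df["node_id"], df["kind"].fillna(""))),
        )
    # word2vec text format: header "n_words dim", then "id v1 .. vk"
    ids, rows = [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return EmbeddingMatrix(ids=ids, vectors=np.asarray(rows))
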