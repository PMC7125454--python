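"""Readers and writers for the pipeline's plain-text formats.

Canonical formats are tab-separated: TSV count matrices (header row of
sample ids, first column feature ids), Broad-dialect GMT gene sets
(name, description, then members), TSV interaction tables, and SIF /
GraphML network exports compatible with Cytoscape-style viewers.
Round-trip (write -> read) is the identity for all input formats.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    CountMatrix,
    FormatError,
    GeneSetCollection,
    MiRNATargetTable,
    make_condition_series,
)

EDGE_TYPES = ("mirna-gene", "gene-pathway", "pathway-pathway")


def read_count_matrix(
    path: str | Path, label_map: Mapping[str, str], sep: str = "\t"
) -> CountMatrix:
    """Read a feature x sample TSV count matrix.

    ``label_map`` supplies the tumor/control condition per sample id;
    every sample in the file must be present in it.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    missing = [s for s in df.columns if s not in label_map]
    if missing:
        raise FormatError(f"samples missing from label map: {missing}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.isfinite(values).all() or (values != np.floor(values)).any():
            raise FormatError(f"non-integer count value in {path}")
        df = df.astype("int64")
    return CountMatrix(df, make_condition_series(label_map))


def write_count_matrix(m: CountMatrix, path: str | Path, sep: str = "\t") -> None:
    m.counts.to_csv(path, sep=sep, index_label="feature")


def write_labels(m: CountMatrix, path: str | Path, sep: str = "\t") -> None:
    m.condition.rename("condition").to_csv(path, sep=sep, index_label="sample")


def read_labels(path: str | Path, sep: str = "\t") -> dict[str, str]:
    df = pd.read_csv(path, sep=sep, dtype=str)
    if not {"sample", "condition"} <= set(df.columns):
        raise FormatError("label file needs 'sample' and 'condition' columns")
    return dict(zip(df["sample"], df["condition"]))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            pid, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"GMT line {lineno}: pathway {pid!r} has no members")
            if pid in sets:
                raise FormatError(f"GMT line {lineno}: duplicate pathway id {pid!r}")
            sets[pid] = tuple(members)
            descriptions[pid] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, members in sets.sets.items():
            desc = sets.descriptions.get(pid, "")
            fh.write("\t".join([pid, desc, *members]) + "\n")


def read_interactions(path: str | Path, sep: str = "\t") -> MiRNATargetTable:
    """Read a miRNA->target TSV with at least columns ``mirna``, ``target``."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty and not {"mirna", "target"} <= set(df.columns):
        raise FormatError("interaction table missing columns: ['mirna', 'target']")
    return MiRNATargetTable(df)


def write_interactions(table: MiRNATargetTable, path: str | Path, sep: str = "\t") -> None:
    table.table.to_csv(path, sep=sep, index=False)


def _edge_type(graph: nx.Graph, u: str, v: str) -> str:
    kinds = frozenset((graph.nodes[u]["node_type"], graph.nodes[v]["node_type"]))
    if kinds == frozenset(("mirna", "gene")):
        return "mirna-gene"
    if kinds == frozenset(("gene", "pathway")):
        return "gene-pathway"
    if kinds == frozenset(("pathway",)):
        return "pathway-pathway"
    raise FormatError(f"edge {u!r}-{v!r} joins incompatible node types {sorted(kinds)}")


def write_network(network: nx.Graph, path: str | Path, format: str = "sif") -> None:
    """Export a typed tripartite network as SIF or GraphML.

    SIF rows are ``source<TAB>interaction<TAB>target`` with interaction in
    {mirna-gene, gene-pathway, pathway-pathway}; GraphML carries the
    node-type attribute so isolated nodes survive round-trips.
    """
    fmt = format.lower()
    priority = {"mirna": 0, "gene": 1, "pathway": 2}
    if fmt == "sif":

        def canonical(edge):
            return sorted(edge, key=lambda n: (priority[network.nodes[n]["node_type"]], n))

        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(canonical(e) for e in network.edges()):
                fh.write(f"{a}\t{_edge_type(network, a, b)}\t{b}\n")
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    else:
        raise FormatError(f"unknown network format: {format!r}")


def read_network_graphml(path: str | Path) -> nx.Graph:
    """Round-trip helper: read back a GraphML export with node types intact."""
    return nx.read_graphml(path)
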