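"""Tripartite miRNA-gene-pathway network construction and topology metrics.

Construction rule: for every correlated pathway pair (X, Y), the risk
genes common to BOTH pathways' member lists are collected; a qualifying
pair contributes the pathway-pathway edge X-Y and gene-pathway edges g-X,
g-Y for each common risk gene g, and every miRNA-risk-gene interaction
whose gene entered the network contributes a miRNA-gene edge.  The result
is a simple undirected graph with typed nodes.

The six per-node topology metrics — degree, average shortest path length,
betweenness centrality, closeness centrality, clustering coefficient and
topological coefficient — are implemented here directly on adjacency
sets, following the conventions of Cytoscape's NetworkAnalyzer: hop
distances, betweenness normalized by (N-1)(N-2)/2 with the whole-graph
node count, closeness as the reciprocal mean distance to reachable nodes,
and the topological coefficient with the +1 term for a direct edge.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import pandas as pd

from .types import FormatError, GeneSetCollection, RiskGeneResult

__all__ = [
    "build_network",
    "shortest_path_lengths",
    "betweenness",
    "closeness_and_aspl",
    "clustering_coefficient",
    "topological_coefficient",
    "topology_report",
]

METRIC_COLUMNS = [
    "degree",
    "avg_shortest_path_length",
    "betweenness",
    "closeness",
    "clustering_coefficient",
    "topological_coefficient",
]


def build_network(
    pairs: pd.DataFrame,
    risk: RiskGeneResult,
    sets: GeneSetCollection,
    include_pathway_pathway_edges: bool = True,
    gene_directions: dict[str, str] | None = None,
) -> nx.Graph:
    """Assemble the tripartite network from correlated pairs and risk genes.

    ``pairs`` is the correlated-pair table (columns pathway_x, pathway_y);
    only pairs sharing at least one common risk gene contribute edges.
    ``gene_directions`` optionally tags gene nodes with their expression
    direction (up / down).
    """
    g = nx.Graph()
    risk_ids = risk.risk_gene_ids
    directions = gene_directions or {}
    for row in pairs.itertuples(index=False):
        x, y = row.pathway_x, row.pathway_y
        for pid in (x, y):
            if pid not in sets:
                raise FormatError(f"pathway {pid!r} in pair list but not in gene sets")
        common = risk_ids & sets.members(x) & sets.members(y)
        if not common:
            continue
        g.add_node(x, node_type="pathway")
        g.add_node(y, node_type="pathway")
        if include_pathway_pathway_edges:
            g.add_edge(x, y, edge_type="pathway-pathway")
        for gene in sorted(common):
            g.add_node(gene, node_type="gene", direction=directions.get(gene, ""))
            g.add_edge(gene, x, edge_type="gene-pathway")
            g.add_edge(gene, y, edge_type="gene-pathway")
    genes_in = {n for n, d in g.nodes(data=True) if d["node_type"] == "gene"}
    for mirna, gene in risk.pairs:
        if gene in genes_in:
            g.add_node(mirna, node_type="mirna")
            g.add_edge(mirna, gene, edge_type="mirna-gene")
    return g


def _adjacency(net: nx.Graph) -> dict:
    return {n: set(net.neighbors(n)) - {n} for n in net.nodes()}


def shortest_path_lengths(net: nx.Graph, source) -> dict:
    """BFS hop distances from ``source`` to every reachable node."""
    if source not in net:
        raise KeyError(f"unknown node: {source!r}")
    adj = _adjacency(net)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def betweenness(net: nx.Graph) -> dict:
    """Normalized betweenness centrality via Brandes' accumulation.

    Pair dependencies over shortest paths are accumulated per source;
    undirected double-counting is halved and values are normalized by
    (N-1)(N-2)/2 with N the whole-graph node count.
    """
    nodes = list(net.nodes())
    n = len(nodes)
    adj = _adjacency(net)
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        # single-source shortest-path counting
        stack: list = []
        preds: dict = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        dist = dict.fromkeys(nodes, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
        # end source loop
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    return {v: bc[v] / 2.0 / norm for v in nodes}


def closeness_and_aspl(net: nx.Graph) -> tuple[dict, dict]:
    """Per-node (closeness, average shortest path length).

    ASPL is the mean hop distance to reachable nodes (self excluded);
    closeness is its reciprocal.  Nodes with no reachable neighbors get
    ASPL nan and closeness 0.
    """
    closeness: dict = {}
    aspl: dict = {}
    for node in net.nodes():
        dist = shortest_path_lengths(net, node)
        reachable = [d for v, d in dist.items() if v != node]
        if not reachable:
            aspl[node] = float("nan")
            closeness[node] = 0.0
        else:
            mean_d = sum(reachable) / len(reachable)
            aspl[node] = mean_d
            closeness[node] = 1.0 / mean_d
    return closeness, aspl


def clustering_coefficient(net: nx.Graph) -> dict:
    """C(n) = 2 e_n / (k_n (k_n - 1)); nodes of degree < 2 get 0."""
    adj = _adjacency(net)
    out = {}
    for node, neigh in adj.items():
        k = len(neigh)
        if k < 2:
            out[node] = 0.0
            continue
        links = sum(1 for u in neigh for v in adj[u] if v in neigh) / 2
        out[node] = 2.0 * links / (k * (k - 1))
    return out


def topological_coefficient(net: nx.Graph) -> dict:
    """Normalized neighbor-sharing: TC(n) = avg_m J(n, m) / k_n.

    The average runs over nodes m != n that share at least one neighbor
    with n; J(n, m) is the number of shared neighbors, plus one when n and
    m are directly linked.  Nodes of degree < 2 get 0.
    """
    adj = _adjacency(net)
    out = {}
    for node, neigh in adj.items():
        k = len(neigh)
        if k < 2:
            out[node] = 0.0
            continue
        j_values = []
        for m in adj:
            if m == node:
                continue
            shared = len(neigh & adj[m])
            if shared == 0:
                continue
            j_values.append(shared + (1 if m in neigh else 0))
        out[node] = (sum(j_values) / len(j_values)) / k if j_values else 0.0
    return out


def topology_report(net: nx.Graph) -> pd.DataFrame:
    """All six metrics per node, plus node type, sorted by degree.

    Ranking is by descending degree with ties broken by node id, matching
    the per-type candidate tables downstream (pathway table, gene table).
    """
    nodes = list(net.nodes())
    if not nodes:
        return pd.DataFrame(columns=["node", "node_type", *METRIC_COLUMNS])
    close, aspl = closeness_and_aspl(net)
    btw = betweenness(net)
    cc = clustering_coefficient(net)
    tc = topological_coefficient(net)
    df = pd.DataFrame(
        {
            "node": nodes,
            "node_type": [net.nodes[n].get("node_type", "") for n in nodes],
            "degree": [net.degree(n) for n in nodes],
            "avg_shortest_path_length": [aspl[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "closeness": [close[n] for n in nodes],
            "clustering_coefficient": [cc[n] for n in nodes],
            "topological_coefficient": [tc[n] for n in nodes],
        }
    )
    df = df.sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)
    return df
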