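"""Consensus-network assembly and simplification.

Builds the cross-species hub + connector graph (hub-hub edges plus non-hub
genes linking at least two hubs), extracts k-hop neighborhoods around seed
genes, and simplifies dense subgraphs to their maximum-weight spanning
forest so only the strongest alternative path between two genes survives.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


def build_consensus_graph(edges: pd.DataFrame, hub_set: Iterable[str]) -> nx.Graph:
    """Hub + connector graph from threshold-filtered interaction edges.

    Keeps all hub-hub edges; a non-hub node survives only as a *connector*,
    i.e. adjacent to >= 2 distinct hub genes (across the merged graph).
    Parallel edges contributed by different experiments are merged keeping
    the maximum adjacency, with the provenance union.  Edge input order
    does not affect the result.
    """
    hubs = {str(h) for h in hub_set}
    merged: dict[tuple[str, str], dict] = {}
    rows = edges.sort_values(["gene_a", "gene_b", "experiment_id"]) if len(edges) else edges
    for row in rows.itertuples(index=False):
        a, b = sorted((str(row.gene_a), str(row.gene_b)))
        if a == b:
            continue
        rec = merged.setdefault((a, b), {"weight": 0.0, "experiments": set()})
        rec["weight"] = max(rec["weight"], float(row.adjacency))
        rec["experiments"].add(str(row.experiment_id))

    g = nx.Graph()
    for h in sorted(hubs):
        g.add_node(h, role="hub")
    for (a, b), rec in sorted(merged.items()):
        g.add_edge(a, b, weight=rec["weight"], experiments=sorted(rec["experiments"]))
    for node in list(g.nodes):
        if node in hubs:
            continue
        hub_partners = {n for n in g.neighbors(node) if n in hubs}
        if len(hub_partners) >= 2:
            g.nodes[node]["role"] = "connector"
        else:
            g.remove_node(node)
    return g


def k_hop_neighborhood(g: nx.Graph, seeds: Sequence[str], k: int = 2) -> nx.Graph:
    """Induced subgraph on nodes within <= k transitions of any seed.

    All interactions between reached genes are retained.  Seeds absent from
    the graph are kept as isolated nodes (with a warning).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    missing = [s for s in seeds if s not in g]
    if missing:
        log.warning("seed gene(s) absent from the graph, kept isolated: %s", missing)
    reached: set[str] = set(str(s) for s in seeds)
    frontier = {s for s in seeds if s in g}
    for _ in range(k):
        frontier = {n for f in frontier for n in g.neighbors(f)} - reached
        if not frontier:
            break
        reached |= frontier
    sub = g.subgraph(n for n in reached if n in g).copy()
    for s in missing:
        sub.add_node(str(s))
    return sub


def spanning_tree_simplify(g: nx.Graph, weight: str = "weight") -> nx.Graph:
    """Maximum-weight spanning forest: the stronger of alternative paths wins.

    Kruskal over edges sorted by decreasing weight (ties broken
    lexicographically by endpoint names for determinism), per connected
    component; the node set is unchanged and components are never bridged.
    """
    forest = nx.Graph()
    forest.add_nodes_from(g.nodes(data=True))
    parent: dict = {n: n for n in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(
        g.edges(data=True),
        key=lambda e: (-float(e[2].get(weight, 1.0)), *sorted((str(e[0]), str(e[1])))),
    )
    for u, v, data in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            forest.add_edge(u, v, **data)
    return forest


def export_graph(g: nx.Graph, tsv_path=None, graphml_path=None) -> None:
    """Edge-list TSV and/or GraphML export with role and provenance attributes."""
    if tsv_path is not None:
        rows = [{
            "gene_a": min(str(u), str(v)),
            "gene_b": max(str(u), str(v)),
            "weight": d.get("weight", 1.0),
            "role_a": g.nodes[u].get("role", ""),
            "role_b": g.nodes[v].get("role", ""),
            "experiments": ",".join(d.get("experiments", [])),
        } for u, v, d in g.edges(data=True)]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "role_a", "role_b",
                                    "experiments"]).sort_values(
            ["gene_a", "gene_b"]).to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        h = g.copy()
        for _, _, d in h.edges(data=True):
            if isinstance(d.get("experiments"), list):
                d["experiments"] = ",".join(d["experiments"])
        nx.write_graphml(h, graphml_path)
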