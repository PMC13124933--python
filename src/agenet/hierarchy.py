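"""Position of genes in a pathway hierarchy (directed acyclic graph).

Roots are nodes with in-degree 0, leaves nodes with out-degree 0.  Each
gene's ``leaf_mean`` is the mean of its finite directed distances to
reachable leaves (out-paths on the original graph) and ``root_mean`` the mean
finite distance to reachable roots (out-paths on the edge-reversed graph);
unreachable targets are excluded, and a node that is itself a root or leaf
contributes its own distance of 0.  Degrees and (unnormalised) betweenness
are computed on the original directed graph.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["hierarchy_distances"]


def _mean_finite_to_targets(graph: nx.DiGraph, targets: list) -> dict:
    """node -> mean finite out-distance to the target nodes (NaN if none reachable)."""
    sums: dict = {}
    counts: dict = {}
    rev = graph.reverse(copy=False)
    for t in targets:
        for node, d in nx.single_source_shortest_path_length(rev, t).items():
            sums[node] = sums.get(node, 0) + d
            counts[node] = counts.get(node, 0) + 1
    return {n: (sums[n] / counts[n] if n in counts else np.nan) for n in graph.nodes}


def hierarchy_distances(dag: nx.DiGraph) -> pd.DataFrame:
    """HierarchyPosition table: root_mean, leaf_mean, degrees, betweenness.

    The input is simplified (self-loops and parallel edges removed) and must
    be acyclic; a cyclic input raises ``ValueError`` naming one cycle.
    """
    g = nx.DiGraph(dag)  # collapses multi-edges if a MultiDiGraph is passed
    g.remove_edges_from(nx.selfloop_edges(g))
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"input graph is cyclic, e.g. {cycle}")
    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    leaves = [n for n in g.nodes if g.out_degree(n) == 0]
    leaf_mean = _mean_finite_to_targets(g, leaves)
    root_mean = _mean_finite_to_targets(g.reverse(copy=False), roots)
    btw = nx.betweenness_centrality(g, normalized=False)
    rows = []
    for n in sorted(g.nodes):
        rows.append((n, root_mean[n], leaf_mean[n],
                     g.in_degree(n), g.out_degree(n), g.in_degree(n) + g.out_degree(n),
                     btw[n]))
    return pd.DataFrame(rows, columns=["gene", "root_mean", "leaf_mean",
                                       "in_degree", "out_degree", "all_degree",
                                       "betweenness"]).set_index("gene")
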