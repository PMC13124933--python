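"""Shortest-path proximity and indirect-interaction counts.

Distances are unweighted (edge counts, BFS).  The bounded closeness
transform ``proximity = 1 / (distance + 1)`` maps distance 0 to 1 and
disconnection (infinite distance) to 0, so proximities can be averaged over
disease gene sets; the inverse ``1 / proximity - 1`` converts a mean
proximity back to intuitive distance units.

Two per-gene indirect metrics are derived from first-order neighbourhoods:
the number of distinct diseases (ARDs) or disease clusters (ARCs) represented
among a gene's neighbours (ARD-/ARC-interactions), and per-cluster counts of
disease-associated neighbours.  A gene's own direct GWAS associations never
count towards its interactions — only its neighbours' do.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csgraph

from agenet.layers import NetworkLayer
from agenet.mapping import GeneTraitAssociations

__all__ = [
    "proximity",
    "set_proximities",
    "set_proximity_table",
    "mean_arc_distance",
    "count_arc_interactions",
    "interactions_table",
    "count_disease_neighbours",
    "neighbour_counts_table",
]


def proximity(distance):
    """``1 / (d + 1)`` with infinity mapped to 0; accepts scalars or arrays."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    with np.errstate(divide="ignore"):
        p = np.where(np.isinf(d), 0.0, 1.0 / (d + 1.0))
    return float(p) if np.isscalar(distance) or d.ndim == 0 else p


def _node_distances(layer: NetworkLayer, sources: Iterable[str]) -> pd.DataFrame:
    """BFS distance matrix (rows: sources, cols: all layer nodes; inf if unreachable)."""
    nodes = sorted(layer.graph.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(layer.graph, nodelist=nodes, format="csr")
    src = [g for g in sources if g in idx]
    if not src:
        return pd.DataFrame(np.empty((0, len(nodes))), index=[], columns=nodes)
    d = csgraph.shortest_path(adj, method="D", unweighted=True,
                              indices=[idx[g] for g in src])
    return pd.DataFrame(np.atleast_2d(d), index=src, columns=nodes)


def set_proximities(layer: NetworkLayer, gene: str, target_set: Iterable[str]) -> tuple:
    """(shortest_proximity, average_proximity) of ``gene`` to a target gene set.

    Shortest = max proximity over targets (1 if the gene is itself a target,
    since self-distance is 0); average = mean proximity over *all* targets
    present in the layer, disconnected pairs contributing 0.  Empty target
    sets yield (nan, nan).
    """
    if gene not in layer.graph:
        raise ValueError(f"gene {gene!r} not in layer {layer.name!r}")
    targets = [t for t in set(target_set) if t in layer.graph]
    if not targets:
        return (math.nan, math.nan)
    dist = nx.single_source_shortest_path_length(layer.graph, gene)
    p = np.array([proximity(dist.get(t, math.inf)) for t in targets])
    return (float(p.max()), float(p.mean()))


def set_proximity_table(layer: NetworkLayer, target_sets: Mapping[str, Iterable[str]]) -> tuple:
    """Shortest- and average-proximity of every layer gene to every target set.

    Returns two gene x target DataFrames.  Target genes absent from the layer
    are ignored; a set with no member in the layer yields a NaN column.
    """
    nodes = sorted(layer.graph.nodes)
    all_targets = sorted({t for s in target_sets.values() for t in s if t in layer.graph})
    dist = _node_distances(layer, all_targets)  # targets x nodes
    shortest = {}
    average = {}
    for label, members in target_sets.items():
        present = [t for t in set(members) if t in dist.index]
        if not present:
            shortest[label] = np.full(len(nodes), np.nan)
            average[label] = np.full(len(nodes), np.nan)
            continue
        p = proximity(dist.loc[present].to_numpy())  # members x nodes
        shortest[label] = p.max(axis=0)
        average[label] = p.mean(axis=0)
    return (pd.DataFrame(shortest, index=nodes), pd.DataFrame(average, index=nodes))


def mean_arc_distance(per_arc_proximities: Iterable[float]) -> float:
    """Mean per-cluster proximity converted back to distance units.

    ``1 / mean(P) - 1``; a mean proximity of 0 (fully disconnected) yields
    ``inf`` as the sentinel.
    """
    p = np.asarray(list(per_arc_proximities), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one proximity value")
    mean_p = float(p.mean())
    return math.inf if mean_p == 0.0 else 1.0 / mean_p - 1.0


def _neighbour_traits(layer: NetworkLayer, gene: str, assoc: GeneTraitAssociations,
                      level: str) -> list:
    if gene not in layer.graph:
        raise ValueError(f"gene {gene!r} not in layer {layer.name!r}")
    table = assoc.arcs if level == "arc" else assoc.ards
    out = []
    for n in layer.graph.neighbors(gene):
        out.extend(table.get(n, ()))
    return out


def count_arc_interactions(layer: NetworkLayer, gene: str, assoc: GeneTraitAssociations,
                           level: str = "arc") -> int:
    """Distinct ARCs (or ARDs with ``level='ard'``) among a gene's neighbours."""
    return len(set(_neighbour_traits(layer, gene, assoc, level)))


def interactions_table(layer: NetworkLayer, assoc: GeneTraitAssociations,
                       level: str = "arc") -> pd.Series:
    """ARC-(or ARD-)interaction counts for every gene present in the layer."""
    return pd.Series(
        {g: count_arc_interactions(layer, g, assoc, level) for g in sorted(layer.graph.nodes)},
        name=f"{level}_interactions", dtype=int)


def count_disease_neighbours(layer: NetworkLayer, gene: str, assoc: GeneTraitAssociations,
                             level: str = "arc") -> dict:
    """Per-cluster (or per-disease) counts of the gene's associated neighbours."""
    table = assoc.arcs if level == "arc" else assoc.ards
    if gene not in layer.graph:
        raise ValueError(f"gene {gene!r} not in layer {layer.name!r}")
    counts: dict = {}
    for n in layer.graph.neighbors(gene):
        for t in table.get(n, ()):
            counts[t] = counts.get(t, 0) + 1
    return counts


def neighbour_counts_table(layer: NetworkLayer, assoc: GeneTraitAssociations,
                           level: str = "arc") -> pd.DataFrame:
    """gene x cluster (or disease) matrix of disease-associated neighbour counts."""
    targets = sorted({t for s in (assoc.arcs if level == "arc" else assoc.ards).values()
                      for t in s})
    nodes = sorted(layer.graph.nodes)
    rows = {g: count_disease_neighbours(layer, g, assoc, level) for g in nodes}
    return (pd.DataFrame.from_dict(rows, orient="index")
            .reindex(index=nodes, columns=targets).fillna(0).astype(int))


def long_format(metric_tables: Mapping[str, pd.DataFrame], layer_name: str) -> pd.DataFrame:
    """Stack gene x target metric tables into (gene, layer, target, metric, value)."""
    frames = []
    for metric, df in metric_tables.items():
        long = df.stack().rename("value").reset_index()
        long.columns = ["gene", "target", "value"]
        long.insert(1, "layer", layer_name)
        long.insert(3, "metric", metric)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)
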