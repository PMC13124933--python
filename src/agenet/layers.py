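"""Network-layer construction and gene-set restriction.

The analysis uses four unweighted, undirected simple layers over gene
symbols: a protein-interaction layer (PPI), two coexpression layers obtained
by thresholding the absolute coexpression matrix at 0.90 and 0.95 (COX90,
COX95), and an undirected pathway layer (KEGG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkLayer",
    "threshold_coexpression",
    "restrict_sets_to_network",
    "neighbours_of_set",
    "read_edge_list",
    "write_edge_list",
    "layer_summary",
]


@dataclass
class NetworkLayer:
    """A named undirected simple graph over gene symbols."""

    name: str
    graph: nx.Graph

    def __post_init__(self) -> None:
        self.graph.remove_edges_from(nx.selfloop_edges(self.graph))

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)


def threshold_coexpression(coexpr: pd.DataFrame, cutoff: float, name: str | None = None) -> NetworkLayer:
    """Binary adjacency: edge (i, j), i != j, iff |r_ij| >= cutoff.

    Genes left without any qualifying edge are dropped from the layer.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    m = np.abs(coexpr.to_numpy())
    genes = list(coexpr.index)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = m[iu, ju] >= cutoff
    g = nx.Graph()
    g.add_edges_from((genes[i], genes[j]) for i, j in zip(iu[keep], ju[keep]))
    return NetworkLayer(name=name or f"COX{int(round(cutoff * 100))}", graph=g)


def restrict_sets_to_network(sets: Mapping[str, set], layer: NetworkLayer) -> dict:
    """Intersect each gene set with the layer's node set (empties allowed)."""
    nodes = layer.nodes
    out = {}
    for label, members in sets.items():
        kept = set(members) & nodes
        if members and not kept:
            logger.warning("gene set %r has no member in layer %r", label, layer.name)
        out[label] = kept
    return out


def neighbours_of_set(layer: NetworkLayer, targets: Iterable[str]) -> set:
    """All nodes adjacent to at least one target gene.

    A target is itself returned when it is adjacent to another target.
    """
    g = layer.graph
    out: set = set()
    for t in targets:
        if t in g:
            out.update(g.neighbors(t))
    return out


def read_edge_list(path: str | Path, name: str | None = None) -> NetworkLayer:
    """Two-column TSV edge list; an optional third (weight) column is ignored."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_edges_from(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return NetworkLayer(name=name or Path(path).stem, graph=g)


def write_edge_list(layer: NetworkLayer, path: str | Path) -> None:
    pd.DataFrame(sorted(map(sorted, layer.graph.edges)),
                 columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def layer_summary(layer: NetworkLayer, sets: Mapping[str, set] | None = None) -> dict:
    """Node/edge counts plus per-set coverage, JSON-serialisable."""
    out = {"name": layer.name,
           "nodes": layer.graph.number_of_nodes(),
           "edges": layer.graph.number_of_edges()}
    if sets:
        out["coverage"] = {label: len(set(m) & layer.nodes) for label, m in sets.items()}
    return out
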