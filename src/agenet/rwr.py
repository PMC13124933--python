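"""Random walk with restart (RWR) on single layers and multiplex stacks.

At every step the walker returns to the seed set with probability ``r``
(0.7 by default; the restart mass is shared equally among seeds, so with 10
seeds each receives 7%) or explores with probability ``1 - r``.

In the multiplex variant all layers share one gene universe; genes missing
from a layer are inserted as isolated replicas.  Exploration is tau-driven:
the walker first picks a layer with probability proportional to the
layer-preference vector tau, then either moves along that layer's edges (if
it picked the layer it is in) or jumps to its own replica in the chosen
layer.  An isolated replica holds the walker (self-loop) until restart or a
layer jump.  Replica probabilities are aggregated per gene (sum, i.e. the
arithmetic mean rescaled to a probability vector).

Steady states solve ``p = (1 - r) T p + r p0`` with ``T`` the
column-stochastic (supra-)transition matrix; small systems are solved
exactly, larger ones by power iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping
import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from agenet.layers import NetworkLayer

logger = logging.getLogger(__name__)

__all__ = [
    "RwrConfig",
    "MultiplexNetwork",
    "run_rwr_monoplex",
    "run_rwr_multiplex",
    "run_seed_sets",
    "rwr_score_matrix",
    "standardize_scores",
]


@dataclass(frozen=True)
class RwrConfig:
    r: float = 0.7
    tau: tuple | None = None  # one weight per layer; None = uniform
    tol: float = 1e-10
    max_iter: int = 1000
    exact_max_dim: int = 2000  # dense linear solve below this (supra-)dimension
    seed_mode: str = "ARC"

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError("restart probability must lie strictly in (0, 1)")
        if self.tau is not None:
            t = np.asarray(self.tau, dtype=float)
            if np.any(t < 0) or t.sum() <= 0:
                raise ValueError("tau entries must be >= 0 with at least one positive")


@dataclass
class MultiplexNetwork:
    """Named layers over a shared gene universe (union of layer nodes)."""

    layers: dict  # name -> networkx.Graph

    @property
    def genes(self) -> list:
        out: set = set()
        for g in self.layers.values():
            out.update(g.nodes)
        return sorted(out)

    @property
    def layer_names(self) -> list:
        return list(self.layers)


def _column_stochastic(graph: nx.Graph, nodes: list) -> sp.csr_matrix:
    """Column-normalised adjacency over ``nodes``; zero columns get a self-loop.

    ``nodes`` may be a superset of the graph's nodes (multiplex union): genes
    absent from the layer become isolated replicas whose self-loop holds the
    walker.
    """
    idx = {g: i for i, g in enumerate(nodes)}
    rows: list = []
    cols: list = []
    for u, v in graph.edges:
        if u != v and u in idx and v in idx:
            rows += [idx[u], idx[v]]
            cols += [idx[v], idx[u]]
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                        shape=(len(nodes), len(nodes)))
    deg = np.asarray(adj.sum(axis=0)).ravel()
    dangling = deg == 0
    if dangling.any():
        adj = adj + sp.diags(dangling.astype(float))
        deg = deg + dangling
    return (adj @ sp.diags(1.0 / deg)).tocsr()


def _steady_state(T: sp.spmatrix, p0: np.ndarray, config: RwrConfig) -> np.ndarray:
    n = p0.size
    r = config.r
    if n <= config.exact_max_dim:
        A = np.eye(n) - (1.0 - r) * np.asarray(T.todense())
        return np.linalg.solve(A, r * p0)
    p = p0.copy()
    for _ in range(config.max_iter):
        nxt = (1.0 - r) * (T @ p) + r * p0
        if np.abs(nxt - p).sum() < config.tol:
            return nxt
        p = nxt
    logger.warning("RWR power iteration hit max_iter=%d without tol=%g",
                   config.max_iter, config.tol)
    return p


def run_rwr_monoplex(layer: NetworkLayer, seeds: Iterable[str],
                     config: RwrConfig = RwrConfig()) -> pd.Series:
    """Steady-state visiting probability of every layer gene from a seed set."""
    nodes = sorted(layer.graph.nodes)
    present = sorted(set(seeds) & set(nodes))
    if not present:
        raise ValueError(f"no seed present in layer {layer.name!r}")
    idx = {g: i for i, g in enumerate(nodes)}
    p0 = np.zeros(len(nodes))
    p0[[idx[s] for s in present]] = 1.0 / len(present)
    T = _column_stochastic(layer.graph, nodes)
    p = _steady_state(T, p0, config)
    return pd.Series(p, index=nodes, name="rwr")


def _supra_transition(mux: MultiplexNetwork, nodes: list, tau: np.ndarray) -> sp.csr_matrix:
    """Block supra-transition: pick layer ~ tau, move within it or jump to replica."""
    L = len(mux.layers)
    n = len(nodes)
    eye = sp.identity(n, format="csr")
    blocks = []
    for li, name_i in enumerate(mux.layer_names):  # row blocks (destination layer)
        row = []
        for lj, name_j in enumerate(mux.layer_names):  # column blocks (current layer)
            if li == lj:
                row.append(tau[li] * _column_stochastic(mux.layers[name_i], nodes))
            else:
                row.append(tau[li] * eye)
        blocks.append(row)
    return sp.bmat(blocks, format="csr")


def run_rwr_multiplex(mux: MultiplexNetwork, seeds: Iterable[str],
                      config: RwrConfig = RwrConfig()) -> pd.Series:
    """Per-gene aggregated steady-state probability on the multiplex stack."""
    L = len(mux.layers)
    tau = (np.ones(L) if config.tau is None else np.asarray(config.tau, dtype=float))
    if tau.size != L:
        raise ValueError(f"tau has {tau.size} entries for {L} layers")
    tau = tau / tau.sum()
    nodes = mux.genes
    present = sorted(set(seeds) & set(nodes))
    if not present:
        raise ValueError("no seed present in the multiplex gene universe")
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    p0 = np.zeros(L * n)
    for l in range(L):  # seed mass shared equally over all seed replicas
        for s in present:
            p0[l * n + idx[s]] = 1.0 / (L * len(present))
    T = _supra_transition(mux, nodes, tau)
    p = _steady_state(T, p0, config)
    per_gene = p.reshape(L, n).sum(axis=0)  # replica aggregation (mean up to scale)
    return pd.Series(per_gene / per_gene.sum(), index=nodes, name="rwr_multiplex")


def rwr_score_matrix(network, seed_sets: Mapping[str, Iterable[str]],
                     config: RwrConfig = RwrConfig()) -> pd.DataFrame:
    """Gene x seed-set score matrix with one shared factorisation.

    ``network`` may be a :class:`~agenet.layers.NetworkLayer` (monoplex) or a
    :class:`MultiplexNetwork`.  The linear system ``(I - (1 - r) T) p = r p0``
    is factorised once and solved for every seed set, which is exact and much
    cheaper than iterating per run.  Seed sets with no gene in the network
    yield an all-NaN column (logged).
    """
    from scipy.linalg import lu_factor, lu_solve
    from scipy.sparse.linalg import splu

    if isinstance(network, MultiplexNetwork):
        L = len(network.layers)
        tau = (np.ones(L) if config.tau is None else np.asarray(config.tau, dtype=float))
        if tau.size != L:
            raise ValueError(f"tau has {tau.size} entries for {L} layers")
        tau = tau / tau.sum()
        nodes = network.genes
        n = len(nodes)
        T = _supra_transition(network, nodes, tau)
        dim = L * n
    else:
        nodes = sorted(network.graph.nodes)
        n = len(nodes)
        L = 1
        T = _column_stochastic(network.graph, nodes)
        dim = n
    idx = {g: i for i, g in enumerate(nodes)}
    A = sp.identity(dim, format="csc") - (1.0 - config.r) * T.tocsc()
    if dim <= config.exact_max_dim:
        lu = lu_factor(A.toarray())
        solve = lambda b: lu_solve(lu, b)
    else:
        lu = splu(A)
        solve = lu.solve
    cols = {}
    for label, seeds in seed_sets.items():
        present = sorted(set(seeds) & set(nodes))
        if not present:
            logger.warning("seed set %r has no gene in the network; scores NaN", label)
            cols[label] = np.full(n, np.nan)
            continue
        p0 = np.zeros(dim)
        for l in range(L):
            for s in present:
                p0[l * n + idx[s]] = 1.0 / (L * len(present))
        p = solve(config.r * p0)
        per_gene = p.reshape(L, n).sum(axis=0)
        cols[label] = per_gene / per_gene.sum()
    return pd.DataFrame(cols, index=nodes)


def run_seed_sets(runner, network, seed_sets: Mapping[str, Iterable[str]],
                  config: RwrConfig = RwrConfig()) -> pd.DataFrame:
    """One RWR run per seed set; returns the gene x seed-set score matrix.

    Seed sets with no gene in the network yield an all-NaN column (logged).
    """
    cols = {}
    for label, seeds in seed_sets.items():
        try:
            cols[label] = runner(network, seeds, config)
        except ValueError as exc:
            logger.warning("seed set %r skipped: %s", label, exc)
            cols[label] = pd.Series(dtype=float)
    return pd.DataFrame(cols)


def standardize_scores(scores: pd.DataFrame) -> tuple:
    """Z-standardise each seed-set column; also per-gene summaries.

    Returns ``(z, summary)`` where ``summary`` has the per-gene mean raw
    score across seed sets and the top seed-set assignment (argmax of the raw
    row).  A zero-variance column yields zeros with a warning.
    """
    z = {}
    for c in scores.columns:
        x = scores[c].to_numpy(dtype=float)
        sd = np.nanstd(x)
        if sd == 0 or np.isnan(sd):
            warnings.warn(f"zero-variance score column {c!r}; z set to 0")
            z[c] = np.zeros_like(x)
        else:
            z[c] = (x - np.nanmean(x)) / sd
    zdf = pd.DataFrame(z, index=scores.index)
    summary = pd.DataFrame({
        "mean_score": scores.mean(axis=1),
        "top_seed_set": scores.idxmax(axis=1),
    })
    return zdf, summary
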