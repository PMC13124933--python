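"""Random walk with restart: stationarity, restart mass, oracles, standardisation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from agenet.layers import NetworkLayer
from agenet.rwr import (MultiplexNetwork, RwrConfig, run_rwr_monoplex,
                        run_rwr_multiplex, rwr_score_matrix, standardize_scores)


def _column_norm(adj):
    deg = adj.sum(axis=0)
    deg[deg == 0] = 1
    return adj / deg


def _random_layer(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    g.add_edges_from((i, i + 1) for i in range(n - 1))  # keep connected
    return NetworkLayer("rand", nx.relabel_nodes(g, str))


def test_each_seed_gets_seven_percent_restart_mass_at_default_r():
    """r = 0.7 with 10 seeds: the restart term returns 7% to each seed."""
    layer = _random_layer(30, 0.15, seed=1)
    seeds = [str(i) for i in range(10)]
    cfg = RwrConfig(r=0.7)
    p = run_rwr_monoplex(layer, seeds, cfg)
    nodes = sorted(layer.graph.nodes)
    W = _column_norm(nx.to_numpy_array(layer.graph, nodelist=nodes))
    # restart contribution recovered from stationarity: p - (1-r) W p = r p0
    restart = p.to_numpy() - 0.3 * (W @ p.to_numpy())
    per_seed = {g: restart[nodes.index(g)] for g in seeds}
    assert np.allclose(list(per_seed.values()), 0.07, atol=1e-10)
    off_seed = [restart[i] for i, g in enumerate(nodes) if g not in set(seeds)]
    assert np.allclose(off_seed, 0.0, atol=1e-10)


def test_probability_conservation():
    layer = _random_layer(40, 0.1, seed=2)
    p = run_rwr_monoplex(layer, ["0", "5"], RwrConfig())
    assert p.sum() == pytest.approx(1.0, abs=1e-9)
    assert (p >= 0).all()


def test_monoplex_matches_dense_linear_solve_oracle():
    for seed in range(5):
        layer = _random_layer(50, 0.08, seed=seed)
        seeds = [str(i) for i in range(4)]
        p = run_rwr_monoplex(layer, seeds, RwrConfig(r=0.7))
        nodes = sorted(layer.graph.nodes)
        W = _column_norm(nx.to_numpy_array(layer.graph, nodelist=nodes))
        p0 = np.array([1 / 4 if g in set(seeds) else 0.0 for g in nodes])
        oracle = 0.7 * np.linalg.inv(np.eye(len(nodes)) - 0.3 * W) @ p0
        assert np.allclose(p.loc[nodes].to_numpy(), oracle, atol=1e-8)


def test_missing_seeds_raise():
    layer = _random_layer(10, 0.3, seed=3)
    with pytest.raises(ValueError, match="seed"):
        run_rwr_monoplex(layer, ["zz"], RwrConfig())


def test_single_layer_multiplex_reduces_to_monoplex():
    layer = _random_layer(25, 0.15, seed=4)
    mono = run_rwr_monoplex(layer, ["0", "1"], RwrConfig())
    mux = MultiplexNetwork({"L": layer.graph})
    multi = run_rwr_multiplex(mux, ["0", "1"], RwrConfig(tau=(1,)))
    assert np.allclose(mono.sort_index().to_numpy(), multi.sort_index().to_numpy(),
                       atol=1e-10)


def test_two_layer_multiplex_matches_explicit_supra_oracle():
    """Dense supra-matrix built independently in the test, solved in closed form."""
    g1 = nx.relabel_nodes(nx.path_graph(6), str)
    g2 = nx.relabel_nodes(nx.cycle_graph(4), str)  # nodes 0..3; 4,5 isolated here
    mux = MultiplexNetwork({"a": g1, "b": g2})
    r, tau = 0.7, np.array([0.5, 0.5])
    out = run_rwr_multiplex(mux, ["0"], RwrConfig(r=r, tau=tuple(tau)))

    nodes = sorted(set(g1) | set(g2))
    n = len(nodes)
    mats = []
    for g in (g1, g2):
        adj = np.zeros((n, n))
        for u, v in g.edges:
            iu, iv = nodes.index(u), nodes.index(v)
            adj[iu, iv] = adj[iv, iu] = 1
        for j in range(n):
            if adj[:, j].sum() == 0:
                adj[j, j] = 1.0  # isolated replica holds the walker
        mats.append(_column_norm(adj))
    eye = np.eye(n)
    supra = np.block([[tau[0] * mats[0], tau[0] * eye],
                      [tau[1] * eye, tau[1] * mats[1]]])
    p0 = np.zeros(2 * n)
    for l in range(2):
        p0[l * n + nodes.index("0")] = 1 / 2
    steady = r * np.linalg.inv(np.eye(2 * n) - (1 - r) * supra) @ p0
    per_gene = steady.reshape(2, n).sum(axis=0)
    assert np.allclose(out.loc[nodes].to_numpy(), per_gene / per_gene.sum(), atol=1e-8)


def test_equal_tau_splits_jump_mass_equally():
    layers = {f"L{i}": nx.relabel_nodes(nx.path_graph(5), str) for i in range(4)}
    mux = MultiplexNetwork(layers)
    from agenet.rwr import _supra_transition
    T = _supra_transition(mux, mux.genes, np.full(4, 0.25)).toarray()
    n = 5
    col = T[:, 0]  # gene "0" in layer 0
    for l in range(1, 4):
        assert col[l * n + 0] == pytest.approx(0.25)  # jump to each other layer
    assert col.sum() == pytest.approx(1.0)


def test_score_matrix_consistent_with_single_runs():
    layer = _random_layer(30, 0.12, seed=6)
    sets = {"s1": {"0", "1"}, "s2": {"5"}, "empty": {"zz"}}
    mat = rwr_score_matrix(layer, sets, RwrConfig())
    for label in ("s1", "s2"):
        single = run_rwr_monoplex(layer, sets[label], RwrConfig())
        assert np.allclose(mat[label].to_numpy(), single.loc[mat.index].to_numpy(),
                           atol=1e-10)
    assert mat["empty"].isna().all()


def test_standardize_scores():
    scores = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0]},
                          index=["g1", "g2", "g3"])
    with pytest.warns(UserWarning, match="zero-variance"):
        z, summary = standardize_scores(scores)
    assert z["A"].mean() == pytest.approx(0.0)
    assert z["A"].std(ddof=0) == pytest.approx(1.0)
    assert (z["B"] == 0).all()
    assert summary.at["g3", "top_seed_set"] == "B"  # argmax of raw row (3 < 5)
    assert summary.at["g1", "mean_score"] == pytest.approx(3.0)


def test_seeds_score_above_uniform_baseline():
    layer = _random_layer(40, 0.1, seed=8)
    p = run_rwr_monoplex(layer, ["0", "7"], RwrConfig(r=0.7))
    assert p["0"] > 1 / 40 and p["7"] > 1 / 40
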