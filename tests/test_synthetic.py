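"""Synthetic-study generator: determinism, planted structure, DAG and matrix invariants."""

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from agenet.synthetic import (StudyConfig, generate_coexpression_matrix,
                              generate_kegg_dag, generate_study)
from tests.conftest import SMALL_CONFIG


def test_identical_config_and_seed_gives_identical_study():
    a = generate_study(SMALL_CONFIG)
    b = generate_study(SMALL_CONFIG)
    pd.testing.assert_frame_equal(a.gene_ranges, b.gene_ranges)
    pd.testing.assert_frame_equal(a.snp_table, b.snp_table)
    pd.testing.assert_frame_equal(a.coexpr, b.coexpr)
    pd.testing.assert_frame_equal(a.expression, b.expression)
    assert a.ageing_like == b.ageing_like and a.pleio_like == b.pleio_like
    for name in a.layers:
        assert set(a.layers[name].edges) == set(b.layers[name].edges)
    assert set(a.kegg_dag.edges) == set(b.kegg_dag.edges)


def test_planted_pleiotropic_genes_hit_at_least_four_clusters(small_study):
    """Brute-force recount from the SNP table: >= 4 distinct ARCs per pleio gene."""
    s = small_study
    ranges = s.gene_ranges.set_index("gene")
    for g in s.pleio_like:
        start, end, chrom = ranges.at[g, "start"], ranges.at[g, "end"], ranges.at[g, "chrom"]
        hits = s.snp_table[(s.snp_table["chrom"] == chrom)
                           & (s.snp_table["pos"] >= start) & (s.snp_table["pos"] <= end)]
        arcs = {s.arc_map[a] for a in hits["ard_id"]}
        assert len(arcs) >= 4


def test_zero_pleiotropy_rate_gives_single_ard_per_gene():
    cfg = dataclasses.replace(SMALL_CONFIG, pleiotropy_rate=0.0, planted_pleio_size=0)
    s = generate_study(cfg)
    counts = s.snp_table.groupby("snp").size()
    assert (counts == 1).all()
    per_gene = {g: len(ards) for g, ards in s.truth.items()}
    assert set(per_gene.values()) == {1}


def test_planted_sets_disjoint_and_sized(small_study):
    s = small_study
    assert not (s.ageing_like & s.pleio_like)
    assert len(s.ageing_like) == SMALL_CONFIG.planted_ageing_size
    assert len(s.pleio_like) == SMALL_CONFIG.planted_pleio_size


def test_oversized_planted_sets_rejected():
    with pytest.raises(ValueError):
        StudyConfig(n_genes=10, planted_ageing_size=8, planted_pleio_size=8)


def test_kegg_dag_is_simple_acyclic_with_roots_and_leaves(small_study):
    dag = small_study.kegg_dag
    assert nx.is_directed_acyclic_graph(dag)
    assert nx.number_of_selfloops(dag) == 0
    assert any(dag.in_degree(n) == 0 for n in dag)
    assert any(dag.out_degree(n) == 0 for n in dag)


def test_kegg_dag_depth_bounded_by_layer_count():
    cfg = dataclasses.replace(SMALL_CONFIG, layer_specs={"kegg": {"depth": 4, "size": 60}})
    dag = generate_kegg_dag(cfg)
    # exhaustive longest-path check on the small instance
    assert nx.dag_longest_path_length(dag) <= 4


def test_kegg_dag_single_gene_universe():
    cfg = StudyConfig(n_genes=1, n_ards=1, n_arcs=1, planted_ageing_size=1,
                      planted_pleio_size=0)
    dag = generate_kegg_dag(cfg, genes=["G1"])
    assert list(dag.nodes) == ["G1"] and dag.number_of_edges() == 0


def test_coexpression_matrix_symmetric_unit_diagonal():
    m = generate_coexpression_matrix(SMALL_CONFIG, modules=[])
    x = m.to_numpy()
    assert np.allclose(x, x.T)
    assert np.allclose(np.diag(x), 1.0)
    assert x.min() >= 0.0 and x.max() <= 1.0


def test_coexpression_planted_modules_separate_from_background():
    genes = [f"G{i:04d}" for i in range(1, 301)]
    mods = [set(genes[:30]), set(genes[30:60])]
    m = generate_coexpression_matrix(SMALL_CONFIG, mods, within=0.6, between=0.1)
    x = m.to_numpy()
    within = x[np.ix_(range(30), range(30))][np.tril_indices(30, -1)].mean()
    between = x[np.ix_(range(30), range(30, 60))].mean()
    assert within > between + 0.3


def test_coexpression_zero_margin_is_null():
    mods = [set(f"G{i:04d}" for i in range(1, 31))]
    m = generate_coexpression_matrix(SMALL_CONFIG, mods, within=0.2, between=0.2)
    x = m.to_numpy()
    within = x[np.ix_(range(30), range(30))][np.tril_indices(30, -1)].mean()
    rest = x[np.ix_(range(30, 300), range(30, 300))][np.tril_indices(270, -1)].mean()
    assert abs(within - rest) < 0.02


def test_snp_table_ards_covered_by_arc_map(small_study):
    s = small_study
    assert set(s.snp_table["ard_id"]) <= set(s.arc_map)
    assert len(set(s.arc_map.values())) == SMALL_CONFIG.n_arcs


def test_planted_expression_poles(small_study):
    from agenet.tissue import compute_tau
    tau = compute_tau(small_study.expression)
    assert tau[sorted(small_study.ageing_like)].max() < 0.1
    assert tau[sorted(small_study.pleio_like)].min() > 0.9
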