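"""Synthetic study generator.

Emulates the inputs of the real-data pipeline — gene genomic ranges, per-ARD
significant SNP tables, an ARD-to-ARC cluster map, network layers (a scale-free
protein-interaction-like layer, a pathway DAG used both directed and as an
undirected layer, two coexpression-threshold layers), a dense absolute
coexpression matrix, a gene-by-tissue expression matrix, and two planted gene
sets:

``ageing_like``
    broadly connected: extra edges to disease-associated genes spanning many
    ARCs in the interaction-style layers, strong mutual coexpression, and
    near-uniform tissue expression (low Tau);
``pleio_like``
    directly GWAS-associated with four or more ARCs, but network-peripheral,
    weakly coexpressed, and expressed in essentially one tissue (Tau near 1).

Everything is driven by a single :class:`numpy.random.Generator` seeded from
``StudyConfig.seed``, so an identical config yields a bit-identical study.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "StudyConfig",
    "SyntheticStudy",
    "generate_study",
    "generate_kegg_dag",
    "generate_coexpression_matrix",
    "read_study",
    "write_study",
]


def _default_layer_specs() -> dict:
    return {
        "ppi": {
            "size": 1000,  # nodes drawn into the scale-free layer (before pleio attachment)
            "m": 3,  # preferential-attachment edges per new node
            "ageing_extra_edges": 6,  # planted ageing -> disease edges, distinct ARCs
        },
        "kegg": {
            "depth": 6,  # max root-to-leaf path length
            "size": 600,
            "ageing_extra_edges": 4,
        },
        "cox": {
            "background_mean": 0.15,
            "background_sd": 0.08,
            "ageing_within": (0.93, 0.025),
            "arc_within": (0.915, 0.015),
            "pleio_within": (0.08, 0.03),
            "ageing_disease_between": (0.40, 0.05),
        },
        "expression": {
            "uniform_level": 100.0,
            "uniform_cv": 0.03,
            "dominant_fold": 50.0,
        },
    }


@dataclass(frozen=True)
class StudyConfig:
    """Dimensions and noise parameters of a synthetic study.

    Defaults mirror the study design this pipeline targets: 57 ageing-related
    diseases grouped into 8 clusters, 30 tissues, global seed 42.  The gene
    universe and planted-set sizes are desk-scale choices (see docs/methods.md).
    """

    n_genes: int = 1200
    n_ards: int = 57
    n_arcs: int = 8
    snps_per_ard: int = 12
    pleiotropy_rate: float = 0.15
    n_tissues: int = 30
    layer_specs: dict = field(default_factory=_default_layer_specs)
    planted_ageing_size: int = 60
    planted_pleio_size: int = 60
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_ards, self.n_arcs, self.snps_per_ard, self.n_tissues) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_arcs > self.n_ards:
            raise ValueError("n_arcs must not exceed n_ards")
        if not 0.0 <= self.pleiotropy_rate <= 1.0:
            raise ValueError("pleiotropy_rate must be a probability")
        if self.planted_ageing_size + self.planted_pleio_size > self.n_genes:
            raise ValueError("planted set sizes exceed the gene universe")


@dataclass
class SyntheticStudy:
    """A complete synthetic study: every input the analysis stages read."""

    config: StudyConfig
    gene_ranges: pd.DataFrame  # gene, chrom, start, end (1-based inclusive)
    snp_table: pd.DataFrame  # snp, chrom, pos, ard_id
    arc_map: dict  # ard_id -> arc_id
    layers: dict  # name -> networkx.Graph (PPI, COX90, COX95, KEGG)
    kegg_dag: nx.DiGraph
    coexpr: pd.DataFrame  # symmetric, |r| in [0, 1], unit diagonal
    expression: pd.DataFrame  # gene x tissue, non-negative
    ageing_like: set
    pleio_like: set
    truth: dict = field(default_factory=dict)  # gene -> set of ard_ids (generative truth)

    @property
    def genes(self) -> list:
        return list(self.gene_ranges["gene"])


def _gene_names(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _make_gene_ranges(genes: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    """Place genes on 22 chromosomes with inter-gene gaps > 2 x 10 kb.

    Gaps exceed twice the default SNP-mapping flank, so a SNP inside one gene
    body can never fall inside another gene's +-10 kb window.
    """
    n = len(genes)
    chroms = [str(c % 22 + 1) for c in range(n)]
    lengths = rng.integers(5_000, 50_001, size=n)
    gaps = rng.integers(25_000, 60_001, size=n)
    rows = []
    cursor: dict = {}
    for g, c, ln, gap in zip(genes, chroms, lengths, gaps):
        start = cursor.get(c, 1) + int(gap)
        end = start + int(ln) - 1
        cursor[c] = end
        rows.append((g, c, start, end))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _make_arc_map(n_ards: int, n_arcs: int) -> dict:
    ards = [f"ARD{i:02d}" for i in range(1, n_ards + 1)]
    return {a: f"ARC{i % n_arcs + 1}" for i, a in enumerate(ards)}


def generate_coexpression_matrix(
    config: StudyConfig,
    modules: Sequence[set],
    *,
    within: float = 0.6,
    between: float = 0.1,
    sd: float = 0.05,
    genes: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Symmetric absolute-coexpression matrix with planted modules.

    Off-diagonal entries are |N(between, sd)| clipped to [0, 1]; pairs inside
    the same module are drawn around ``within`` instead.  With ``within ==
    between`` the construction is an exact null (no planted signal).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if genes is None:
        genes = _gene_names(config.n_genes)
    genes = list(genes)
    universe = set(genes)
    for m in modules:
        if not set(m) <= universe:
            raise ValueError("module gene sets must be subsets of the gene universe")
    blocks = [(set(m), set(m), within, sd) for m in modules]
    return _block_matrix(genes, blocks, between, sd, rng)


def _block_matrix(
    genes: Sequence[str],
    blocks: Sequence[tuple],
    background_mean: float,
    background_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Dense symmetric matrix from background noise plus (rows, cols, mean, sd) blocks.

    Later blocks overwrite earlier ones where they overlap; the diagonal is 1.
    """
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    m = np.abs(rng.normal(background_mean, background_sd, size=(n, n)))
    for rows, cols, mean, sd in blocks:
        ri = np.array(sorted(idx[g] for g in rows), dtype=int)
        ci = np.array(sorted(idx[g] for g in cols), dtype=int)
        m[np.ix_(ri, ci)] = rng.normal(mean, sd, size=(len(ri), len(ci)))
    m = np.clip(np.triu(m, 1), 0.0, 1.0)
    m = m + m.T
    np.fill_diagonal(m, 1.0)
    return pd.DataFrame(m, index=list(genes), columns=list(genes))


def generate_kegg_dag(
    config: StudyConfig,
    *,
    genes: Sequence[str] | None = None,
    ageing: Sequence[str] = (),
    pleio: Sequence[str] = (),
    disease: Sequence[str] = (),
    rng: np.random.Generator | None = None,
) -> nx.DiGraph:
    """Layered pathway-like DAG over (a subset of) the gene universe.

    Nodes are arranged in ``depth + 1`` levels; edges run only between
    consecutive levels, so every root-to-leaf path has length <= ``depth`` and
    the graph is acyclic by construction.  Planted structure: ``pleio`` genes
    sit on the bottom level (they become leaves), ``ageing`` genes occupy
    middle levels and receive extra child edges to ``disease`` genes so their
    undirected neighbourhood spans many disease clusters.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec = config.layer_specs.get("kegg", _default_layer_specs()["kegg"])
    depth = int(spec.get("depth", 6))
    if genes is None:
        genes = _gene_names(config.n_genes)
    genes = list(genes)
    if len(genes) == 1:
        g = nx.DiGraph()
        g.add_node(genes[0])
        return g

    ageing = [g for g in ageing if g in set(genes)]
    pleio = [g for g in pleio if g in set(genes)]
    disease = [g for g in disease if g in set(genes)]
    size = min(len(genes), int(spec.get("size", 600)))
    chosen: list = list(dict.fromkeys(list(ageing) + list(pleio) + list(disease)))
    rest = [g for g in genes if g not in set(chosen)]
    if len(chosen) < size:
        extra = rng.choice(rest, size=min(size - len(chosen), len(rest)), replace=False)
        chosen = chosen + list(extra)
    chosen = chosen[:max(size, 2)]

    n_levels = depth + 1
    level: dict = {}
    mid = depth // 2
    for g in chosen:
        if g in set(pleio):
            level[g] = depth
        elif g in set(ageing):
            level[g] = int(rng.integers(max(1, mid - 1), min(depth - 1, mid + 1) + 1))
        else:
            level[g] = int(rng.integers(0, depth))
    # every level must be populated so roots/leaves exist at the extremes
    by_level: dict = {l: [] for l in range(n_levels)}
    for g, l in level.items():
        by_level[l].append(g)
    pool = [g for g in chosen if g not in set(ageing) | set(pleio)]
    for l in range(n_levels):
        if not by_level[l] and pool:
            g = pool.pop()
            by_level[level[g]].remove(g)
            level[g] = l
            by_level[l].append(g)

    dag = nx.DiGraph()
    dag.add_nodes_from(chosen)
    for l in range(1, n_levels):
        parents = by_level[l - 1]
        if not parents:
            continue
        for g in by_level[l]:
            k = int(rng.integers(1, min(3, len(parents)) + 1))
            for p in rng.choice(parents, size=k, replace=False):
                dag.add_edge(str(p), g)
    # non-bottom nodes with no child would be spurious leaves; give them one
    for l in range(n_levels - 1):
        children = by_level[l + 1]
        if not children:
            continue
        for g in by_level[l]:
            if dag.out_degree(g) == 0:
                dag.add_edge(g, str(rng.choice(children)))
    # planted ageing -> disease child edges (distinct-cluster reach is arranged
    # by the caller passing disease genes spanning clusters)
    extra = int(spec.get("ageing_extra_edges", 4))
    for g in ageing:
        targets = [d for d in disease if level.get(d, -1) == level[g] + 1]
        if not targets:
            targets = [d for d in disease if level.get(d, -1) > level[g]]
        if targets:
            for t in rng.choice(targets, size=min(extra, len(targets)), replace=False):
                if level[str(t)] == level[g] + 1:
                    dag.add_edge(g, str(t))
    assert nx.is_directed_acyclic_graph(dag)
    return dag


def _draw_associations(config: StudyConfig, genes: list, ageing: set, pleio: set,
                       arc_map: dict, rng: np.random.Generator) -> dict:
    """Generative gene -> {ARD} truth with a controllable pleiotropy distribution."""
    ards = sorted(arc_map)
    arcs: dict = {}
    for ard, arc in arc_map.items():
        arcs.setdefault(arc, []).append(ard)
    arc_ids = sorted(arcs)
    pool = [g for g in genes if g not in ageing and g not in pleio]
    per_ard = min(config.snps_per_ard, len(pool) // len(ards))
    if per_ard == 0:
        raise ValueError("gene universe too small for one associated gene per ARD")
    # disjoint base draws: one ARD per associated gene unless pleiotropy adds more
    shuffled = list(rng.permutation(pool))
    truth: dict = {}
    for i, ard in enumerate(ards):
        for g in shuffled[i * per_ard:(i + 1) * per_ard]:
            truth.setdefault(str(g), set()).add(ard)
    if config.pleiotropy_rate > 0:
        for g in sorted(truth):
            if rng.random() < config.pleiotropy_rate:
                others = [a for a in ards if a not in truth[g]]
                if others:
                    truth[g].add(str(rng.choice(others)))
    # pleiotropic-like genes: direct hits spread over >= 4 clusters
    lo = min(4, config.n_arcs)
    for g in sorted(pleio):
        k = int(rng.integers(lo, min(lo + 2, config.n_arcs) + 1))
        for arc in rng.choice(arc_ids, size=k, replace=False):
            truth.setdefault(g, set()).add(str(rng.choice(arcs[str(arc)])))
    return truth


def _make_snp_table(truth: dict, gene_ranges: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One significant SNP inside the gene body per (gene, ARD) truth pair."""
    loc = gene_ranges.set_index("gene")
    rows = []
    i = 0
    for g in sorted(truth):
        for ard in sorted(truth[g]):
            i += 1
            start, end = int(loc.at[g, "start"]), int(loc.at[g, "end"])
            pos = int(rng.integers(start, end + 1))
            rows.append((f"rs{i:06d}", str(loc.at[g, "chrom"]), pos, ard))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "ard_id"])


def _make_ppi(config: StudyConfig, genes: list, ageing: set, pleio: set,
              gene_arcs: dict, rng: np.random.Generator) -> nx.Graph:
    """Scale-free interaction layer with planted ageing connectivity.

    Preferential attachment over non-peripheral genes reproduces hub structure;
    each ageing-like gene gains extra edges to disease genes of distinct ARCs,
    and each pleio-like gene is attached by exactly one edge (peripheral).
    """
    spec = config.layer_specs.get("ppi", _default_layer_specs()["ppi"])
    disease = sorted(g for g in gene_arcs if g not in pleio)
    core = list(dict.fromkeys(sorted(ageing) + disease))
    rest = [g for g in genes if g not in set(core) | pleio]
    size = min(int(spec.get("size", 1000)), len(genes) - len(pleio))
    if len(core) < size:
        core += list(rng.choice(rest, size=min(size - len(core), len(rest)), replace=False))
    order = list(core)
    rng.shuffle(order)
    ba = nx.barabasi_albert_graph(len(order), int(spec.get("m", 3)),
                                  seed=int(rng.integers(0, 2**31 - 1)))
    graph = nx.relabel_nodes(ba, {i: order[i] for i in range(len(order))})
    # planted broad reach: edges to disease genes in distinct clusters
    k = int(spec.get("ageing_extra_edges", 6))
    by_arc: dict = {}
    for g in disease:
        for arc in gene_arcs[g]:
            by_arc.setdefault(arc, []).append(g)
    arc_ids = sorted(by_arc)
    for g in sorted(ageing):
        for arc in rng.choice(arc_ids, size=min(k, len(arc_ids)), replace=False):
            t = str(rng.choice(by_arc[str(arc)]))
            if t != g:
                graph.add_edge(g, t)
    # peripheral pleiotropic genes: a single edge each
    anchors = list(graph.nodes)
    for g in sorted(pleio):
        graph.add_edge(g, str(rng.choice(anchors)))
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph


def _make_expression(config: StudyConfig, genes: list, ageing: set, pleio: set,
                     rng: np.random.Generator) -> pd.DataFrame:
    spec = config.layer_specs.get("expression", _default_layer_specs()["expression"])
    n, t = len(genes), config.n_tissues
    expr = rng.lognormal(mean=2.0, sigma=1.0, size=(n, t))
    idx = {g: i for i, g in enumerate(genes)}
    level = float(spec.get("uniform_level", 100.0))
    cv = float(spec.get("uniform_cv", 0.05))
    for g in sorted(ageing):  # near-uniform across tissues -> Tau near 0
        expr[idx[g]] = np.clip(level * (1.0 + cv * rng.normal(size=t)), 1e-6, None)
    fold = float(spec.get("dominant_fold", 50.0))
    for g in sorted(pleio):  # one dominant tissue -> Tau near 1 - 1/fold
        row = np.full(t, 2.0)
        row[int(rng.integers(0, t))] = 2.0 * fold
        expr[idx[g]] = row
    tissues = [f"tissue_{i:02d}" for i in range(1, t + 1)]
    return pd.DataFrame(expr, index=list(genes), columns=tissues)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a complete synthetic study with planted signal.

    See the module docstring for the planted contrasts.  Identical
    ``config`` (including ``seed``) yields a bit-identical study.
    """
    from agenet.layers import threshold_coexpression

    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    gene_ranges = _make_gene_ranges(genes, rng)
    arc_map = _make_arc_map(config.n_ards, config.n_arcs)

    planted = rng.choice(genes, size=config.planted_ageing_size + config.planted_pleio_size,
                         replace=False)
    ageing = set(map(str, planted[: config.planted_ageing_size]))
    pleio = set(map(str, planted[config.planted_ageing_size:]))

    truth = _draw_associations(config, genes, ageing, pleio, arc_map, rng)
    snp_table = _make_snp_table(truth, gene_ranges, rng)
    gene_arcs = {g: {arc_map[a] for a in ards} for g, ards in truth.items()}

    # coexpression: ageing module tight; per-cluster disease modules moderate;
    # pleio block weak; ageing strongly coexpressed with disease modules
    cox = config.layer_specs.get("cox", _default_layer_specs()["cox"])
    first_arc: dict = {}
    for g, arcs in gene_arcs.items():
        if g not in pleio:
            first_arc.setdefault(sorted(arcs)[0], set()).add(g)
    disease_all = set().union(*first_arc.values()) if first_arc else set()
    blocks = []
    for arc in sorted(first_arc):
        blocks.append((first_arc[arc], first_arc[arc], *cox["arc_within"]))
    blocks.append((ageing, disease_all, *cox["ageing_disease_between"]))
    blocks.append((disease_all, ageing, *cox["ageing_disease_between"]))
    blocks.append((ageing, ageing, *cox["ageing_within"]))
    blocks.append((pleio, set(genes), *cox["pleio_within"]))
    blocks.append((set(genes), pleio, *cox["pleio_within"]))
    coexpr = _block_matrix(genes, blocks, cox["background_mean"], cox["background_sd"], rng)

    disease_span = sorted(disease_all)
    dag = generate_kegg_dag(config, genes=genes, ageing=sorted(ageing), pleio=sorted(pleio),
                            disease=disease_span, rng=rng)
    kegg_layer = nx.Graph()
    kegg_layer.add_edges_from((u, v) for u, v in dag.edges if u != v)

    layers = {
        "PPI": _make_ppi(config, genes, ageing, pleio, gene_arcs, rng),
        "COX90": threshold_coexpression(coexpr, 0.90).graph,
        "COX95": threshold_coexpression(coexpr, 0.95).graph,
        "KEGG": kegg_layer,
    }
    expression = _make_expression(config, genes, ageing, pleio, rng)

    return SyntheticStudy(
        config=config,
        gene_ranges=gene_ranges,
        snp_table=snp_table,
        arc_map=arc_map,
        layers=layers,
        kegg_dag=dag,
        coexpr=coexpr,
        expression=expression,
        ageing_like=ageing,
        pleio_like=pleio,
        truth=truth,
    )


def read_study(indir: str | Path) -> SyntheticStudy:
    """Load a study from the plain-text files written by :func:`write_study`.

    The same reader serves real-data inputs prepared in these formats.  The
    generative truth is not stored on disk, so ``truth`` comes back empty and
    ``config`` records the inferred dimensions only.
    """
    from agenet.layers import read_edge_list

    d = Path(indir)
    gene_ranges = pd.read_csv(d / "gene_ranges.tsv", sep="\t",
                              dtype={"chrom": str})
    snp_table = pd.read_csv(d / "snp_table.tsv", sep="\t", dtype={"chrom": str})
    arc_map = dict(pd.read_csv(d / "arc_map.tsv", sep="\t").values)
    layers = {p.stem.removeprefix("layer_"): read_edge_list(p).graph
              for p in sorted(d.glob("layer_*.tsv"))}
    dag_edges = pd.read_csv(d / "kegg_dag.tsv", sep="\t")
    kegg_dag = nx.DiGraph(list(dag_edges.itertuples(index=False, name=None)))
    coexpr = pd.read_csv(d / "coexpression.tsv", sep="\t", index_col=0)
    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    sets = {}
    for label in ("ageing_like", "pleio_like"):
        p = d / f"{label}.txt"
        sets[label] = set(p.read_text().split()) if p.exists() else set()
    cfg = StudyConfig(n_genes=len(gene_ranges), n_ards=len(arc_map),
                      n_arcs=len(set(arc_map.values())),
                      n_tissues=expression.shape[1])
    return SyntheticStudy(config=cfg, gene_ranges=gene_ranges, snp_table=snp_table,
                          arc_map=arc_map, layers=layers, kegg_dag=kegg_dag,
                          coexpr=coexpr, expression=expression,
                          ageing_like=sets["ageing_like"], pleio_like=sets["pleio_like"])


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict:
    """Write the study in the plain-text formats the real-data mode reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _save(name: str, df: pd.DataFrame, **kw) -> None:
        p = out / name
        df.to_csv(p, sep="\t", **kw)
        paths[name] = p

    _save("gene_ranges.tsv", study.gene_ranges, index=False)
    _save("snp_table.tsv", study.snp_table, index=False)
    arc_df = pd.DataFrame(sorted(study.arc_map.items()), columns=["ard_id", "arc_id"])
    _save("arc_map.tsv", arc_df, index=False)
    for name, g in study.layers.items():
        _save(f"layer_{name}.tsv",
              pd.DataFrame(sorted(map(sorted, g.edges)), columns=["gene_a", "gene_b"]),
              index=False)
    _save("kegg_dag.tsv", pd.DataFrame(sorted(study.kegg_dag.edges),
                                       columns=["parent", "child"]), index=False)
    _save("coexpression.tsv", study.coexpr)
    _save("expression.tsv", study.expression)
    for label, s in (("ageing_like", study.ageing_like), ("pleio_like", study.pleio_like)):
        p = out / f"{label}.txt"
        p.write_text("\n".join(sorted(s)) + "\n")
        paths[f"{label}.txt"] = p
    return paths
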