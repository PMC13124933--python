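"""Sequential orchestration of the synthetic end-to-end study.

``run_pipeline`` executes simulate -> map -> layers -> metrics -> rwr ->
coexpression -> tau -> hierarchy -> permutation -> ml in order, writing each
stage's outputs as plain-text tables under the output directory and
recording every file (with a content hash) plus the global seed in a run
manifest.  Deterministic stages are bit-identical under a fixed config and
seed.

``compute_metric_tables`` is the shared feature-computation entry point used
by the ML stage, the analysis drivers and the acceptance script: it returns
gene x target tables for the four connectivity metrics per network layer
(and multiplex RWR), keyed by ``(network, metric, mode)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from agenet import coexpression, hierarchy, layers, mapping, ml, permutation, proximity, rwr, tissue
from agenet.synthetic import StudyConfig, SyntheticStudy, generate_study, write_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "compute_metric_tables",
           "load_pipeline_config", "study_groups"]


@dataclass
class PipelineConfig:
    """All knobs of a synthetic end-to-end run.

    ``n_perm`` trades permutation-p resolution for runtime (minimum
    achievable p is 1/(n_perm + 1), flagged in the outputs).  ML settings
    default to a light single-cell grid; the full nested-CV grid is available
    through :func:`agenet.ml.evaluate_classifier` directly.
    """

    study: StudyConfig = field(default_factory=StudyConfig)
    flank: int = 10_000
    cox_cutoffs: tuple = (0.90, 0.95)
    rwr: rwr.RwrConfig = field(default_factory=rwr.RwrConfig)
    n_perm: int = 10_000
    interaction_family_size: int = 16  # 4 gene groups x 4 networks
    ml_datasets: tuple = ("rwr|Multiplex|ARD",)
    ml_n_trees: int = 200
    ml_outer_folds: int = 5
    ml_param_grid: dict = field(default_factory=lambda: {"max_depth": [None],
                                                         "max_features": ["sqrt"]})
    outdir: str = "results/pipeline"
    seed: int = 42


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Top-level keys map to ``PipelineConfig`` fields; the nested ``study`` and
    ``rwr`` mappings populate :class:`StudyConfig` and
    :class:`~agenet.rwr.RwrConfig`.
    """
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    study = StudyConfig(**data.pop("study", {}))
    rwr_cfg = rwr.RwrConfig(**{k: tuple(v) if k == "tau" else v
                               for k, v in data.pop("rwr", {}).items()})
    for key in ("cox_cutoffs", "ml_datasets"):
        if key in data:
            data[key] = tuple(data[key])
    return PipelineConfig(study=study, rwr=rwr_cfg, **data)


def study_groups(study: SyntheticStudy, assoc: mapping.GeneTraitAssociations,
                 pleiotropy: pd.DataFrame) -> dict:
    """The five analysis gene sets (they may overlap)."""
    high = set(pleiotropy.loc[pleiotropy["pleiotropy_class"] == "high", "gene"])
    diseases = set(assoc.genes)
    ppi = study.layers["PPI"]
    neighbours = layers.neighbours_of_set(layers.NetworkLayer("PPI", ppi), diseases)
    return {
        "GenAgeHum": set(study.ageing_like),
        "GenAgeMod": set(study.ageing_like),  # synthetic mode plants one ageing set
        "Diseases": diseases,
        "Neighbours": neighbours,
        "HighPleio": high,
    }


def compute_metric_tables(
    study: SyntheticStudy,
    assoc: mapping.GeneTraitAssociations,
    modes: tuple = ("ARC",),
    config: rwr.RwrConfig | None = None,
    include_multiplex: bool = True,
) -> dict:
    """(network, metric, mode) -> gene x target DataFrame of connectivity features."""
    config = config or rwr.RwrConfig()
    tables: dict = {}
    for mode in modes:
        if mode == "ARC":
            targets = {a: assoc.genes_for_arc(a) for a in sorted(set(assoc.arc_map.values()))}
        else:
            targets = {a: assoc.genes_for_ard(a) for a in sorted(set(assoc.arc_map))}
        for name, graph in study.layers.items():
            layer = layers.NetworkLayer(name, graph)
            shortest, average = proximity.set_proximity_table(layer, targets)
            tables[(name, "shortest", mode)] = shortest
            tables[(name, "average", mode)] = average
            counts = proximity.neighbour_counts_table(
                layer, assoc, level=mode.lower()).reindex(columns=sorted(targets)).fillna(0)
            tables[(name, "neighbours", mode)] = counts
            tables[(name, "rwr", mode)] = rwr.rwr_score_matrix(layer, targets, config)
        if include_multiplex:
            mux = rwr.MultiplexNetwork(dict(study.layers))
            tables[("Multiplex", "rwr", mode)] = rwr.rwr_score_matrix(mux, targets, config)
    return tables


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic study; returns the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "warnings": [],
                "min_permutation_p": 1.0 / (config.n_perm + 1),
                "created": time.strftime("%Y-%m-%dT%H:%M:%S")}
    if config.n_perm < 10_000:
        manifest["warnings"].append(
            f"n_perm={config.n_perm} gives reduced p resolution (min p = 1/{config.n_perm + 1})")

    def record(stage: str, paths: dict) -> None:
        manifest["stages"][stage] = {str(k): _hash(Path(v)) for k, v in paths.items()}

    # 1. simulate
    study_cfg = StudyConfig(**{**vars(config.study), "seed": config.seed})
    study = generate_study(study_cfg)
    record("simulate", write_study(study, out / "study"))

    # 2. map (reads the stage-1 files, not generator internals)
    snps = pd.read_csv(out / "study" / "snp_table.tsv", sep="\t")
    ranges = pd.read_csv(out / "study" / "gene_ranges.tsv", sep="\t")
    arc_map = dict(pd.read_csv(out / "study" / "arc_map.tsv", sep="\t").values)
    assoc = mapping.map_snps_to_genes(snps, ranges, flank=config.flank, arc_map=arc_map)
    pleio = mapping.compute_pleiotropy(assoc)
    p = out / "associations.tsv"
    assoc.to_frame().to_csv(p, sep="\t", index=False)
    p2 = out / "pleiotropy.tsv"
    pleio.to_csv(p2, sep="\t", index=False)
    record("map", {"associations.tsv": p, "pleiotropy.tsv": p2})

    # 3. layers
    groups = study_groups(study, assoc, pleio)
    summaries = [layers.layer_summary(layers.NetworkLayer(n, g), groups)
                 for n, g in study.layers.items()]
    p = out / "layer_summary.json"
    p.write_text(json.dumps(summaries, indent=2))
    record("layers", {"layer_summary.json": p})

    # 4. metrics (proximity + interactions) and 5. rwr
    tables = compute_metric_tables(study, assoc, modes=("ARC",), config=config.rwr)
    long = pd.concat([proximity.long_format({m: df}, n)
                      for (n, m, _mode), df in tables.items()], ignore_index=True)
    p = out / "metrics_long.tsv"
    long.to_csv(p, sep="\t", index=False)
    inter = {n: proximity.interactions_table(layers.NetworkLayer(n, g), assoc)
             for n, g in study.layers.items()}
    p2 = out / "arc_interactions.tsv"
    pd.DataFrame(inter).to_csv(p2, sep="\t")
    record("metrics", {"metrics_long.tsv": p, "arc_interactions.tsv": p2})
    rwr_cols = {f"{n}|{mode}": df for (n, m, mode), df in tables.items() if m == "rwr"}
    p = out / "rwr_scores.tsv"
    pd.concat(rwr_cols, axis=1).to_csv(p, sep="\t")
    record("rwr", {"rwr_scores.tsv": p})

    # 6. coexpression
    cox_groups = {"GenAgeHum": groups["GenAgeHum"], "Diseases": groups["Diseases"],
                  "HighPleio": groups["HighPleio"]}
    p = out / "coexpression_groups.tsv"
    coexpression.group_mean_matrix(study.coexpr, cox_groups).to_csv(p, sep="\t")
    record("coexpression", {"coexpression_groups.tsv": p})

    # 7. tau
    tau = tissue.compute_tau(study.expression)
    p = out / "tau.tsv"
    tau.to_csv(p, sep="\t")
    record("tau", {"tau.tsv": p})

    # 8. hierarchy
    hier = hierarchy.hierarchy_distances(study.kegg_dag)
    p = out / "hierarchy.tsv"
    hier.to_csv(p, sep="\t")
    record("hierarchy", {"hierarchy.tsv": p})

    # 9. permutation: ARC-interaction enrichment per group per network
    perm_rows = []
    for n in study.layers:
        values = inter[n].astype(float)
        universe = values.index
        for label in ("GenAgeHum", "Diseases", "HighPleio"):
            members = set(groups[label]) & set(universe)
            if not members:
                continue
            res = permutation.permutation_null_mean(
                values, members, universe, n_perm=config.n_perm, seed=config.seed,
                label=f"{n}:{label}", family_size=config.interaction_family_size)
            perm_rows.append({"network": n, "group": label, **res.to_dict()})
    p = out / "permutation_interactions.tsv"
    pd.DataFrame(perm_rows).to_csv(p, sep="\t", index=False)
    record("permutation", {"permutation_interactions.tsv": p})

    # 10. ml
    specs = {s.name: s for s in ml.dataset_grid()}
    ml_rows = []
    ard_tables = None
    for name in config.ml_datasets:
        spec = specs[name]
        needed = tables
        if spec.mode == "ARD":
            if ard_tables is None:
                ard_tables = compute_metric_tables(study, assoc, modes=("ARD",),
                                                   config=config.rwr)
            needed = ard_tables
        table = ml.build_feature_table(needed, study.ageing_like, spec)
        rec = ml.evaluate_classifier(table, outer_folds=config.ml_outer_folds,
                                     n_trees=config.ml_n_trees, seed=config.seed,
                                     param_grid=config.ml_param_grid)
        ml_rows.append({"dataset": name, "auc": rec.auc, "n_genes": len(table)})
    p = out / "ml_auc.tsv"
    pd.DataFrame(ml_rows).to_csv(p, sep="\t", index=False)
    record("ml", {"ml_auc.tsv": p})

    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2))
    return manifest
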