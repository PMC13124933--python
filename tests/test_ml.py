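"""Feature assembly, the balanced forest, nested CV and candidate ranking."""

import numpy as np
import pandas as pd
import pytest

from agenet import ml


def _tables(genes, targets, networks=("PPI",), mode="ARC", seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for n in networks:
        for m in ml.METRICS:
            out[(n, m, mode)] = pd.DataFrame(
                rng.uniform(size=(len(genes), len(targets))), index=genes,
                columns=targets)
    return out


def test_dataset_grid_census_is_47():
    specs = ml.dataset_grid()
    assert len(specs) == 47
    assert len({s.name for s in specs}) == 47
    singles = [s for s in specs if len(s.metrics) == 1 and len(s.networks) == 1
               and not s.multiplex]
    assert len(singles) == 32
    assert sum(s.multiplex for s in specs) == 1


def test_feature_widths_by_mode():
    genes = [f"g{i}" for i in range(30)]
    arc_targets = [f"ARC{i}" for i in range(1, 9)]
    ard_targets = [f"ARD{i:02d}" for i in range(1, 58)]
    pos = set(genes[:5])
    spec_arc = ml.DatasetSpec("shortest|PPI|ARC", ("shortest",), ("PPI",), "ARC")
    t = ml.build_feature_table(_tables(genes, arc_targets), pos, spec_arc)
    assert t.shape[1] - 1 == 8  # 8 cluster features plus the label
    spec_ard = ml.DatasetSpec("shortest|PPI|ARD", ("shortest",), ("PPI",), "ARD")
    t = ml.build_feature_table(_tables(genes, ard_targets, mode="ARD"), pos, spec_ard)
    assert t.shape[1] - 1 == 57
    spec_agg = ml.DatasetSpec("shortest|all|ARC", ("shortest",),
                              ("PPI", "COX90", "COX95", "KEGG"), "ARC")
    t = ml.build_feature_table(_tables(genes, arc_targets,
                                       networks=("PPI", "COX90", "COX95", "KEGG")),
                               pos, spec_agg)
    assert t.shape[1] - 1 == 32  # 8 x 4 networks


def test_aggregation_imputes_absent_genes_with_zero():
    arc_targets = [f"ARC{i}" for i in range(1, 9)]
    tabs = _tables([f"g{i}" for i in range(10)], arc_targets)
    tabs.update(_tables([f"g{i}" for i in range(5, 15)], arc_targets,
                        networks=("KEGG",), seed=1))
    spec = ml.DatasetSpec("x", ("shortest",), ("PPI", "KEGG"), "ARC")
    t = ml.build_feature_table(tabs, {"g0"}, spec)
    assert len(t) == 15
    assert (t.loc["g14", [c for c in t.columns if c.startswith("PPI|")]] == 0).all()


def test_empty_positives_rejected():
    tabs = _tables(["g0", "g1"], ["ARC1"])
    spec = ml.DatasetSpec("x", ("shortest",), ("PPI",), "ARC")
    with pytest.raises(ValueError):
        ml.build_feature_table(tabs, set(), spec)


def _labelled_table(n=300, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.uniform(size=n) < 0.15).astype(int)
    x = rng.normal(size=(n, 6))
    if informative:
        x[:, 0] += 3.0 * y
    t = pd.DataFrame(x, index=[f"g{i}" for i in range(n)],
                     columns=[f"f{i}" for i in range(6)])
    t["label"] = y
    return t


LIGHT_GRID = {"max_depth": [None], "max_features": ["sqrt"]}


def test_perfectly_separable_features_give_auc_one():
    t = _labelled_table()
    t["f0"] = t["label"] * 10.0  # deterministic separator
    rec = ml.evaluate_classifier(t, outer_folds=4, n_trees=30, seed=0,
                                 param_grid=LIGHT_GRID)
    assert rec.auc == pytest.approx(1.0)


def test_label_independent_features_give_chance_auc():
    t = _labelled_table(n=500, informative=False, seed=3)
    rec = ml.evaluate_classifier(t, outer_folds=4, n_trees=60, seed=1,
                                 param_grid=LIGHT_GRID)
    assert 0.4 < rec.auc < 0.6


def test_every_gene_scored_out_of_fold_and_deterministic():
    t = _labelled_table(seed=4)
    rec = ml.evaluate_classifier(t, outer_folds=5, n_trees=25, seed=2,
                                 param_grid=LIGHT_GRID)
    assert rec.scores.notna().all()
    assert set(rec.fold.unique()) == set(range(5))
    rec2 = ml.evaluate_classifier(t, outer_folds=5, n_trees=25, seed=2,
                                  param_grid=LIGHT_GRID)
    assert np.allclose(rec.scores, rec2.scores)
    assert rec.auc == rec2.auc


def test_inner_grid_search_runs():
    t = _labelled_table(seed=5)
    rec = ml.evaluate_classifier(t, outer_folds=3, inner_folds=3, n_trees=15, seed=0,
                                 param_grid={"max_depth": [2, None],
                                             "max_features": ["sqrt"]})
    assert len(rec.best_params) == 3
    assert all("max_depth" in p for p in rec.best_params)


def test_single_class_table_rejected():
    t = _labelled_table()
    t["label"] = 0
    with pytest.raises(ValueError):
        ml.evaluate_classifier(t, param_grid=LIGHT_GRID, n_trees=5, outer_folds=2)


def test_balanced_forest_uses_balanced_bootstraps():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(200, 3))
    y = np.r_[np.ones(20), np.zeros(180)].astype(int)
    clf = ml.BalancedRandomForest(n_estimators=20, random_state=0).fit(x, y)
    # with balanced bootstraps the minority class is predicted at a decent rate
    assert 0.2 < clf.predict(x).mean() < 0.8
    proba = clf.predict_proba(x)
    assert proba.shape == (200, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)


def test_rank_candidates_threshold_sort_and_ties():
    scores = pd.Series({"a": 0.9, "b": 0.9, "c": 0.7, "d": 0.4, "pos": 0.99})
    out = ml.rank_candidates(scores, {"pos"}, threshold=0.5, top_k=2)
    assert list(out["gene"]) == ["a", "b"]  # ties broken lexicographically
    out_all = ml.rank_candidates(scores, {"pos"}, threshold=0.5, top_k=30)
    assert list(out_all["gene"]) == ["a", "b", "c"]
    none = ml.rank_candidates(scores, {"pos"}, threshold=0.99)
    assert none.empty
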