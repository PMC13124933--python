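"""Network-feature-based prediction of ageing genes.

Feature tables hold, per gene, connectivity metrics to disease targets
(per-cluster or per-disease): shortest-path proximity, average-path
proximity, disease-neighbour counts and RWR diffusion scores, computed per
network layer or aggregated.  The configured dataset grid instantiates 47
specifications: 4 metrics x 4 networks x 2 target modes (32), per-network
integrations across metrics (8), per-metric integrations across networks for
the three path/count metrics (6), and one multiplex RWR dataset.

Classification uses a balanced random forest — an ensemble of decision trees
each trained on a class-balanced bootstrap — evaluated with nested
stratified cross-validation (outer folds give every gene an out-of-fold
probability score; inner folds tune the tree grid).  Performance is the AUC
of the pooled out-of-fold scores; candidate ageing genes are unlabelled
genes scoring above 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DatasetSpec",
    "dataset_grid",
    "build_feature_table",
    "BalancedRandomForest",
    "evaluate_classifier",
    "rank_candidates",
]

NETWORKS = ("PPI", "COX90", "COX95", "KEGG")
METRICS = ("shortest", "average", "neighbours", "rwr")
MODES = ("ARC", "ARD")


@dataclass(frozen=True)
class DatasetSpec:
    """One metric/network/mode combination of the prediction grid."""

    name: str
    metrics: tuple
    networks: tuple
    mode: str  # "ARC" or "ARD"
    multiplex: bool = False


def dataset_grid(networks: Sequence[str] = NETWORKS, metrics: Sequence[str] = METRICS,
                 modes: Sequence[str] = MODES) -> list:
    """The configured grid of dataset specifications (47 with the defaults)."""
    specs = []
    for mode in modes:  # single metric x network
        for m in metrics:
            for n in networks:
                specs.append(DatasetSpec(f"{m}|{n}|{mode}", (m,), (n,), mode))
    for mode in modes:  # per-network integration across metrics
        for n in networks:
            specs.append(DatasetSpec(f"all-metrics|{n}|{mode}", tuple(metrics), (n,), mode))
    for mode in modes:  # per-metric integration across networks (RWR is covered
        for m in metrics:  # by the multiplex dataset instead)
            if m == "rwr":
                continue
            specs.append(DatasetSpec(f"{m}|all-networks|{mode}", (m,), tuple(networks), mode))
    specs.append(DatasetSpec("rwr|Multiplex|ARD", ("rwr",), ("Multiplex",), "ARD",
                             multiplex=True))
    return specs


def build_feature_table(
    metric_tables: Mapping[tuple, pd.DataFrame],
    positives: Iterable[str],
    spec: DatasetSpec,
    presence_indicators: bool = False,
) -> pd.DataFrame:
    """Assemble the feature table for one dataset specification.

    ``metric_tables`` maps ``(network, metric, mode)`` to a gene x target
    DataFrame.  Single-network datasets keep only that network's member
    genes; aggregated datasets take the union of member genes and impute a
    metric's disconnected value (0) for genes absent from a layer, optionally
    adding one presence-indicator column per network.  The ``label`` column
    is 1 iff the gene belongs to the positive (ageing) set.
    """
    positives = set(positives)
    if not positives:
        raise ValueError("positive gene set is empty")
    parts = []
    for n in spec.networks:
        for m in spec.metrics:
            key = (n, m, spec.mode)
            if key not in metric_tables:
                raise KeyError(f"missing metric table for {key}")
            df = metric_tables[key]
            df = df.rename(columns={c: f"{n}|{m}|{c}" for c in df.columns})
            parts.append((n, df))
    genes = sorted(set().union(*(set(df.index) for _, df in parts)))
    out = []
    for n, df in parts:
        out.append(df.reindex(genes).fillna(0.0))
    if presence_indicators and len(spec.networks) > 1:
        for n in spec.networks:
            member = set().union(*(set(df.index) for nn, df in parts if nn == n))
            out.append(pd.DataFrame({f"{n}|present": [float(g in member) for g in genes]},
                                    index=genes))
    table = pd.concat(out, axis=1)
    if table.isna().any().any():
        raise ValueError("feature/label misalignment: NaNs after assembly")
    table["label"] = [int(g in positives) for g in genes]
    return table


class BalancedRandomForest(ClassifierMixin, BaseEstimator):
    """Random forest over class-balanced bootstraps.

    Each tree is fitted on a bootstrap drawing ``n_min`` samples with
    replacement from every class, where ``n_min`` is the minority-class
    count, so heavily imbalanced labels (ageing genes are a few percent of
    the universe) do not swamp the trees.
    """

    def __init__(self, n_estimators: int = 500, max_depth: int | None = None,
                 max_features: str = "sqrt", random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training data contains a single class")
        rng = np.random.default_rng(self.random_state)
        by_class = [np.flatnonzero(y_enc == k) for k in range(self.classes_.size)]
        n_min = min(len(ix) for ix in by_class)
        self.estimators_ = []
        for _ in range(self.n_estimators):
            idx = np.concatenate([rng.choice(ix, size=n_min, replace=True)
                                  for ix in by_class])
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)))
            tree.fit(X[idx], y_enc[idx])
            self.estimators_.append(tree)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        proba = np.zeros((X.shape[0], self.classes_.size))
        for tree in self.estimators_:
            p = tree.predict_proba(X)
            proba[:, tree.classes_] += p
        return proba / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


DEFAULT_GRID = {"max_depth": [None, 10, 20], "max_features": ["sqrt", "log2"]}


@dataclass
class EvaluationRecord:
    auc: float
    scores: pd.Series  # out-of-fold probability per gene
    fold: pd.Series  # outer-fold assignment per gene
    best_params: list = field(default_factory=list)


def evaluate_classifier(
    table: pd.DataFrame,
    outer_folds: int = 10,
    inner_folds: int = 5,
    n_trees: int = 500,
    seed: int = 0,
    param_grid: Mapping | None = None,
) -> EvaluationRecord:
    """Nested stratified CV: out-of-fold scores for every gene, pooled AUC.

    Hyperparameters are tuned on the inner folds by AUC; with a single-cell
    grid the inner loop is skipped.  No gene's score comes from a model that
    saw it in training.
    """
    if "label" not in table.columns:
        raise ValueError("feature table must carry a 'label' column")
    y = table["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature table contains a single class")
    X = table.drop(columns="label").to_numpy(dtype=float)
    grid = dict(DEFAULT_GRID if param_grid is None else param_grid)
    n_cells = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    scores = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1)
    best_params = []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        model = BalancedRandomForest(n_estimators=n_trees, random_state=seed + 1000 + k)
        if n_cells > 1:
            inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                    random_state=seed + 2000 + k)
            search = GridSearchCV(model, grid, cv=inner, scoring="roc_auc", n_jobs=1)
            search.fit(X[tr], y[tr])
            model = search.best_estimator_
            best_params.append(search.best_params_)
        else:
            model.set_params(**{kk: v[0] for kk, v in grid.items()})
            model.fit(X[tr], y[tr])
            best_params.append(model.get_params())
        pos = list(model.classes_).index(1)
        scores[te] = model.predict_proba(X[te])[:, pos]
        fold_of[te] = k
    auc = float(roc_auc_score(y, scores))
    idx = table.index
    return EvaluationRecord(auc=auc,
                            scores=pd.Series(scores, index=idx, name="score"),
                            fold=pd.Series(fold_of, index=idx, name="fold"),
                            best_params=best_params)


def rank_candidates(scores: pd.Series, positives: Iterable[str],
                    threshold: float = 0.5, top_k: int = 30) -> pd.DataFrame:
    """Top unlabelled genes scoring above the decision threshold.

    Non-positive genes with score > threshold, sorted by descending score
    with lexicographic gene-id tie-break; at most ``top_k`` rows.
    """
    positives = set(positives)
    cand = scores[~scores.index.isin(positives) & (scores > threshold)]
    ranked = cand.reset_index()
    ranked.columns = ["gene", "score"]
    ranked = ranked.sort_values(["score", "gene"], ascending=[False, True],
                                kind="mergesort").head(top_k)
    return ranked.reset_index(drop=True)
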