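"""Size-matched permutation nulls and group-comparison tests.

For a per-gene statistic and an observed gene set, the null is the
distribution of the mean over ``n_perm`` random sets of identical size drawn
without replacement from a declared background universe.  Empirical
two-tailed p-values use the add-one rule ``p = (r + 1) / (n + 1)`` where r
counts permutations at least as extreme (in absolute deviation from the null
mean) as the observation, so the minimum achievable p is ``1 / (n_perm + 1)``
(1/10,001 at the default 10,000 permutations).  Bonferroni family sizes are
declared explicitly per analysis, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationResult",
    "permutation_null_mean",
    "empirical_p_two_tailed",
    "pairwise_group_tests",
    "bonferroni",
]


@dataclass
class PermutationResult:
    label: str
    observed: float
    null_mean: float
    null_sd: float
    p: float
    p_adj: float
    n_perm: int

    @property
    def difference(self) -> float:
        return self.observed - self.null_mean

    @property
    def z(self) -> float:
        return (self.observed - self.null_mean) / self.null_sd if self.null_sd > 0 else np.nan

    def to_dict(self) -> dict:
        return {
            "label": self.label, "observed": self.observed,
            "null_mean": self.null_mean, "null_sd": self.null_sd,
            "difference": self.difference, "p": self.p, "p_adj": self.p_adj,
            "z": self.z, "n_perm": self.n_perm,
        }


def bonferroni(p: float, family_size: int) -> float:
    return min(1.0, p * family_size)


def empirical_p_two_tailed(observed: float, null_values: Iterable[float],
                           null_mean: float | None = None) -> float:
    """Add-one two-tailed empirical p: extremity is |value - null mean|."""
    null = np.asarray(list(null_values), dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    centre = float(null.mean()) if null_mean is None else null_mean
    r = int(np.sum(np.abs(null - centre) >= abs(observed - centre)))
    return (r + 1) / (null.size + 1)


def permutation_null_mean(
    values: pd.Series,
    observed_set: Iterable[str],
    universe: Iterable[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 42,
    label: str = "",
    family_size: int = 1,
    one_tailed: str | None = None,
) -> PermutationResult:
    """Mean of ``values`` over a gene set vs size-matched random sets.

    ``one_tailed`` may be ``"greater"`` or ``"less"`` for a directional test;
    the default is the symmetric two-tailed extremity rule.
    """
    values = values.dropna()
    observed_set = set(observed_set)
    universe = sorted(set(values.index) if universe is None else set(universe) & set(values.index))
    if len(observed_set) > len(universe):
        raise ValueError("observed set larger than universe")
    members = sorted(observed_set & set(universe))
    if not members:
        raise ValueError("observed set has no member in the universe")
    rng = np.random.default_rng(seed)
    pool = values.loc[universe].to_numpy(dtype=float)
    k = len(members)
    observed = float(values.loc[members].mean())
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = pool[rng.choice(len(pool), size=k, replace=False)].mean()
    null_mean = float(null.mean())
    if one_tailed == "greater":
        p = (int(np.sum(null >= observed)) + 1) / (n_perm + 1)
    elif one_tailed == "less":
        p = (int(np.sum(null <= observed)) + 1) / (n_perm + 1)
    else:
        p = empirical_p_two_tailed(observed, null, null_mean)
    return PermutationResult(label=label, observed=observed, null_mean=null_mean,
                             null_sd=float(null.std(ddof=0)), p=p,
                             p_adj=bonferroni(p, family_size), n_perm=n_perm)


def pairwise_group_tests(
    values: pd.Series,
    groups: Mapping[str, Iterable[str]],
    family_size: int | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests between all unordered group pairs.

    Groups may overlap (shared members appear in both samples).  The
    Bonferroni family defaults to the number of pairs tested (10 for five
    groups) but can be declared explicitly when the family spans several
    layers.  Pairs where either group has fewer than two valued members are
    reported with NaN statistics.
    """
    values = values.dropna()
    samples = {label: values.loc[sorted(set(m) & set(values.index))]
               for label, m in groups.items()}
    pairs = list(combinations(groups, 2))
    if family_size is None:
        family_size = len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = samples[a], samples[b]
        if len(xa) < 2 or len(xb) < 2:
            rows.append((a, b, len(xa), len(xb), np.nan, np.nan, np.nan, "skipped"))
            continue
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append((a, b, len(xa), len(xb), float(res.statistic), float(res.pvalue),
                     bonferroni(float(res.pvalue), family_size), "ok"))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b",
                                       "statistic", "p", "p_adj", "status"])
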