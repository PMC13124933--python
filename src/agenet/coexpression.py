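"""Intra- and inter-set mean absolute coexpression.

Statistics operate on a gene-labelled symmetric matrix of absolute
correlations.  Intra-set coherence is the mean of the lower triangle of the
set's submatrix (each unordered pair once, diagonal excluded).  Inter-set
coherence between two possibly overlapping sets counts every unordered gene
pair exactly once, merging three components: pairs among the overlap (upper
triangle), pairs of group-1-only genes with all of group 2, and pairs of
group-2-only genes with all of group 1; self-pairs are always excluded.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["intra_set_coexpression", "inter_set_coexpression", "group_mean_matrix"]


def _present(M: pd.DataFrame, genes: Iterable[str], label: str = "set") -> list:
    genes = set(genes)
    kept = sorted(genes & set(M.index))
    dropped = len(genes) - len(kept)
    if dropped:
        logger.info("%s: %d genes absent from the coexpression matrix dropped",
                    label, dropped)
    return kept


def intra_set_coexpression(M: pd.DataFrame, genes: Iterable[str]) -> float:
    """Mean of the n(n-1)/2 off-diagonal entries of the set's submatrix.

    NaN (with a warning) when fewer than two set members are in the matrix.
    """
    kept = _present(M, genes)
    if len(kept) < 2:
        logger.warning("intra-set coexpression undefined for <2 present members")
        return math.nan
    sub = np.abs(M.loc[kept, kept].to_numpy())
    il = np.tril_indices(len(kept), k=-1)
    return float(sub[il].mean())


def inter_set_coexpression(M: pd.DataFrame, A: Iterable[str], B: Iterable[str]) -> float:
    """Mean absolute coexpression over unordered pairs between two sets.

    Every unordered pair {a, b} with a in A, b in B and a != b contributes
    exactly once, whether or not the sets overlap.  NaN when no valid pair
    exists.
    """
    a = set(_present(M, A, "group 1"))
    b = set(_present(M, B, "group 2"))
    pairs = {frozenset((x, y)) for x in a for y in b if x != y}
    if not pairs:
        logger.warning("inter-set coexpression undefined: no valid gene pair")
        return math.nan
    idx = {g: i for i, g in enumerate(M.index)}
    m = np.abs(M.to_numpy())
    ii, jj = zip(*(sorted(idx[g] for g in p) for p in pairs))
    return float(m[np.array(ii), np.array(jj)].mean())


def group_mean_matrix(M: pd.DataFrame, groups: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """group x group matrix: intra-set means on the diagonal, inter-set off it."""
    labels = list(groups)
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for gi in labels:
        out.loc[gi, gi] = intra_set_coexpression(M, groups[gi])
    for gi, gj in combinations(labels, 2):
        v = inter_set_coexpression(M, groups[gi], groups[gj])
        out.loc[gi, gj] = v
        out.loc[gj, gi] = v
    return out
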