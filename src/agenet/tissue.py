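"""Tissue-specificity index (Tau).

For a gene expressed across N tissues with non-negative levels x_i,

    tau = sum_i (1 - x_i / max_i x_i) / (N - 1)

ranges from 0 (uniform expression across tissues) to 1 (expression restricted
to a single tissue) and is invariant to rescaling a gene's row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_tau"]


def compute_tau(expression: pd.DataFrame, log2: bool = False) -> pd.Series:
    """Per-gene Tau from a gene x tissue matrix.

    Rows with all-zero expression are excluded (Tau undefined).  With
    ``log2=True`` expression is transformed as log2(x + 1) first.
    """
    if expression.shape[1] < 2:
        raise ValueError("Tau requires at least two tissues")
    x = expression.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("expression must be non-negative")
    if log2:
        x = np.log2(x + 1.0)
    xmax = x.max(axis=1)
    keep = xmax > 0
    n = x.shape[1]
    tau = np.full(x.shape[0], np.nan)
    tau[keep] = (1.0 - x[keep] / xmax[keep, None]).sum(axis=1) / (n - 1)
    return pd.Series(tau, index=expression.index, name="tau").dropna()
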