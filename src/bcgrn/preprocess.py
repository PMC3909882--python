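"""Probe-level normalization and probe-to-gene collapse.

Microarray probe intensities (already log2-scaled) are quantile-normalized
so every sample shares one empirical distribution, then probes mapping to
the same gene are collapsed to their per-sample median.  Probes without a
gene mapping are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["quantile_normalize", "collapse_probes"]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of row-means of the
    column-sorted matrix.

    Tied values within a column receive the mean of the reference values at
    their rank positions (average-rank convention).  Row and column labels
    are preserved.  Idempotent to numerical tolerance.
    """
    if matrix.shape[1] < 1:
        raise ValueError("matrix must have at least one column")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    x = matrix.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(x.shape[0], dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average") - 1.0
        # fractional (tied) ranks interpolate between neighbouring reference values
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(probe_matrix: pd.DataFrame,
                    probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    Each gene's value per sample is the median over its mapped probes;
    probes absent from ``probe_to_gene`` are dropped.  Output rows are
    sorted by gene id, so the result is invariant to probe row order.
    """
    if not probe_to_gene:
        raise ValueError("probe-to-gene mapping is empty; no genes would remain")
    mapped = [p for p in probe_matrix.index if p in probe_to_gene]
    if not mapped:
        raise ValueError("no probe in the matrix has a gene mapping")
    sub = probe_matrix.loc[mapped]
    genes = pd.Series({p: probe_to_gene[p] for p in mapped}, name="gene")
    collapsed = sub.groupby(genes).median()
    collapsed.index.name = probe_matrix.index.name or "gene"
    return collapsed.sort_index()
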