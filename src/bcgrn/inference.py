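"""BC3Net: bootstrap-aggregated C3NET network inference.

The pipeline's core inference method, in four layers:

1.  Pairwise mutual information is estimated from the Pearson correlation
    via the bivariate-Gaussian closed form MI = -1/2 ln(1 - rho^2), in nats.
2.  C3NET: each gene nominates its maximum-MI partner, and the edge is
    kept iff that MI is significant against a pooled permutation null,
    Bonferroni-corrected over the p genes (one null hypothesis per gene).
    A C3NET network therefore has at most p edges.
3.  The expression matrix is bootstrapped B times (samples resampled with
    replacement) and C3NET is run on each replicate, yielding an ensemble
    of member networks.
4.  Each edge's occurrence count k_e across the ensemble is tested with a
    one-sided binomial test against a null success probability p0 (by
    default the ensemble's mean edge frequency over the union of observed
    edges); edges with tail probability P(X >= k_e) <= alpha form the
    final network G_BC3Net.
"""

from __future__ import annotations

from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gaussian_mi",
    "estimate_mi_matrix",
    "mi_null",
    "empirical_pvalue",
    "c3net",
    "bootstrap_ensemble",
    "aggregate",
    "binomial_edge_test",
    "bc3net",
]

_RHO_SQ_CEIL = 1.0 - 1e-12


def gaussian_mi(rho):
    """Mutual information (nats) of a bivariate Gaussian with correlation rho.

    MI = -1/2 ln(1 - rho^2); rho^2 is clamped to 1 - 1e-12 so perfectly
    correlated pairs map to a large finite value.  Accepts scalars or
    arrays; symmetric in the sign of rho.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) > 1.0 + 1e-9):
        raise ValueError("correlation must lie in [-1, 1]")
    rho_sq = np.minimum(rho * rho, _RHO_SQ_CEIL)
    out = -0.5 * np.log1p(-rho_sq)
    return float(out) if out.ndim == 0 else out


def _mi_from_rows(x: np.ndarray) -> np.ndarray:
    """Pairwise Gaussian MI between rows; zero-variance rows get MI 0."""
    sd = x.std(axis=1)
    zero = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(x)
    rho = np.nan_to_num(rho, nan=0.0)
    if zero.any():
        rho[zero, :] = 0.0
        rho[:, zero] = 0.0
    rho = np.triu(rho)  # symmetric by construction, bit-exactly
    rho = rho + np.triu(rho, k=1).T
    np.clip(rho, -1.0, 1.0, out=rho)
    mi = gaussian_mi(rho)
    np.fill_diagonal(mi, 0.0)
    return mi


def estimate_mi_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Symmetric genes x genes mutual-information matrix of an expression
    matrix (genes x samples).  Genes with zero variance are rejected.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.to_numpy(dtype=float)
    flat = expr.index[x.std(axis=1) == 0].tolist()
    if flat:
        raise ValueError(f"zero-variance genes: {flat}")
    return pd.DataFrame(_mi_from_rows(x), index=expr.index, columns=expr.index)


def mi_null(expr: pd.DataFrame, n_resample: int = 100_000,
            seed: int = 0) -> np.ndarray:
    """Pooled permutation null of MI values.

    Every gene row is permuted independently (destroying all pairwise
    dependence while preserving marginals) and all off-diagonal MI values
    are pooled; shuffles repeat until the pool reaches ``n_resample``.
    Returns the pool sorted ascending.
    """
    if n_resample < 100:
        raise ValueError("n_resample must be >= 100")
    rng = np.random.default_rng(seed)
    x = expr.to_numpy(dtype=float)
    p = x.shape[0]
    iu = np.triu_indices(p, k=1)
    pool: list[np.ndarray] = []
    total = 0
    while total < n_resample:
        shuffled = rng.permuted(x, axis=1)
        vals = _mi_from_rows(shuffled)[iu]
        pool.append(vals)
        total += vals.size
    return np.sort(np.concatenate(pool))


def empirical_pvalue(mi, null_pool: np.ndarray):
    """Right-tail empirical p-value with the +1 pseudo-count:
    p = (#{null >= mi} + 1) / (n_pool + 1).  Vectorized over ``mi``.
    """
    mi = np.asarray(mi, dtype=float)
    n = null_pool.size
    n_ge = n - np.searchsorted(null_pool, mi, side="left")
    p = (n_ge + 1.0) / (n + 1.0)
    return float(p) if p.ndim == 0 else p


def c3net(mi: pd.DataFrame, null_pool: np.ndarray,
          alpha: float = 0.05) -> nx.Graph:
    """C3NET edge rule on an MI matrix.

    Each gene g contributes at most the edge {g, argmax MI(g, .)}; the edge
    enters iff its empirical p-value passes Bonferroni at ``alpha`` with
    m = p tests.  Argmax ties break toward the lexicographically smaller
    partner id.  The result is simple, undirected, |E| <= p.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    order = np.argsort(mi.index)
    genes = mi.index.to_numpy()[order]
    m = mi.to_numpy(dtype=float)[np.ix_(order, order)].copy()
    p = len(genes)
    np.fill_diagonal(m, -np.inf)
    partner = np.argmax(m, axis=1)  # first (lexicographically smallest) max
    best_mi = m[np.arange(p), partner]
    pvals = empirical_pvalue(best_mi, null_pool)
    threshold = alpha / p
    g = nx.Graph()
    g.add_nodes_from(genes.tolist())
    for i in np.flatnonzero(pvals <= threshold):
        g.add_edge(str(genes[i]), str(genes[partner[i]]))
    return g


def bootstrap_ensemble(expr: pd.DataFrame, B: int = 100, seed: int = 0,
                       alpha: float = 0.05,
                       null_pool_size: int = 100_000) -> list[nx.Graph]:
    """Infer a C3NET network from each of B bootstrap replicates.

    Each replicate resamples the samples (columns) with replacement — the
    gene set is never resampled.  Genes that become constant inside a
    replicate simply take correlation 0 there.  A fixed seed makes the
    ensemble bit-reproducible.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    x = expr.to_numpy(dtype=float)
    n = x.shape[1]
    members: list[nx.Graph] = []
    for _ in range(B):
        cols = rng.integers(0, n, size=n)
        rep = pd.DataFrame(x[:, cols], index=expr.index)
        mi = pd.DataFrame(_mi_from_rows(rep.to_numpy()),
                          index=expr.index, columns=expr.index)
        null_pool = mi_null(rep, n_resample=null_pool_size,
                            seed=int(rng.integers(0, 2**31 - 1)))
        members.append(c3net(mi, null_pool, alpha=alpha))
    return members


def aggregate(ensemble: list[nx.Graph]) -> dict[tuple[str, str], int]:
    """Edge occurrence counts k_e across the ensemble (the weighted
    aggregate network G^b_w); edges keyed with the smaller gene first."""
    counts: Counter = Counter()
    for g in ensemble:
        for u, v in g.edges():
            counts[tuple(sorted((str(u), str(v))))] += 1
    return dict(counts)


def binomial_edge_test(freq: dict[tuple[str, str], int], B: int,
                       ensemble_alpha: float = 0.05,
                       p0: float | None = None,
                       genes=None) -> nx.Graph:
    """Keep edges whose ensemble count passes a one-sided binomial test.

    Edge e with count k_e is kept iff P(X >= k_e | B, p0) <= alpha.  The
    default null probability p0 is the ensemble's mean edge frequency over
    the union of observed edges, (sum_e k_e) / (B * |union|).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not freq:
        raise ValueError("empty edge-frequency table")
    if not 0.0 < ensemble_alpha < 1.0:
        raise ValueError("ensemble_alpha must lie in (0, 1)")
    if p0 is None:
        p0 = sum(freq.values()) / (B * len(freq))
    p0 = min(max(p0, 1e-12), 1.0 - 1e-12)
    g = nx.Graph()
    if genes is not None:
        g.add_nodes_from(map(str, genes))
    edges = sorted(freq)
    counts = np.array([freq[e] for e in edges])
    tails = stats.binom.sf(counts - 1, B, p0)
    for (u, v), tail in zip(edges, tails):
        if tail <= ensemble_alpha:
            g.add_edge(u, v)
    return g


def bc3net(expr: pd.DataFrame, B: int = 100, seed: int = 0,
           edge_alpha: float = 0.05, ensemble_alpha: float = 0.05,
           null_pool_size: int = 100_000, p0: float | None = None):
    """Full BC3Net run: bootstrap ensemble -> aggregation -> binomial test.

    Returns ``(network, edge_frequency)`` where ``network`` is the final
    G_BC3Net over all genes of ``expr`` and ``edge_frequency`` maps each
    union edge to its ensemble count.
    """
    ensemble = bootstrap_ensemble(expr, B=B, seed=seed, alpha=edge_alpha,
                                  null_pool_size=null_pool_size)
    freq = aggregate(ensemble)
    if not freq:
        g = nx.Graph()
        g.add_nodes_from(map(str, expr.index))
        return g, freq
    network = binomial_edge_test(freq, B=B, ensemble_alpha=ensemble_alpha,
                                 p0=p0, genes=expr.index)
    return network, freq
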