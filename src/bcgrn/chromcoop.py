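"""Chromosome cooperation: do some chromosome pairs share more network
edges than chance allows?

Each edge joins genes on chromosomes (i, j); the observed interaction
count s_ij is compared against its own null distribution obtained by
permuting the gene -> chromosome assignment uniformly while the network
is held fixed.  The permutation conserves the edge count, the full graph
structure, and the uneven chromosome sizes.  The empirical p-value is

    p_ij = (1/E) * sum_e I(s^e_ij > s_ij)        (strict >, so 0 attainable)

over E label permutations, with an optional smoothed variant
(#{s^e >= s} + 1)/(E + 1) that is valid for FDR procedures,
followed by Benjamini-Hochberg over all (c^2 - c)/2 + c chromosome pairs
(diagonal pairs — within-chromosome interaction — are tested too; for the
24 human chromosomes that is 300 tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import CHROMOSOMES

__all__ = [
    "ChromPairTest",
    "intra_fraction",
    "chrom_pair_counts",
    "permutation_pvalue",
    "permutation_test",
]


@dataclass
class ChromPairTest:
    """Permutation-test record for one chromosome pair (i <= j)."""

    chrom_i: str
    chrom_j: str
    s_observed: int
    exceed_count: int
    E: int
    p_value: float
    p_adjusted: float
    significant: bool
    s_null_mean: float = float("nan")


def _edge_chrom_indices(network: nx.Graph, catalog: pd.DataFrame):
    """Map the network's edges onto chromosome-index pairs.

    Returns (labels, u_idx, v_idx, chroms): per-gene chromosome index
    array, the two per-edge endpoint gene indices, and the ordered
    chromosome labels actually allowed (the canonical 24).
    """
    genes = sorted(map(str, network.nodes()))
    missing = [g for g in genes if g not in catalog.index]
    if missing:
        raise KeyError(f"genes missing from catalog: {missing[:10]}")
    chrom_of = catalog["chromosome"].astype(str)
    bad = sorted(set(chrom_of.loc[genes]) - set(CHROMOSOMES))
    if bad:
        raise ValueError(f"invalid chromosome labels: {bad}")
    chrom_index = {c: k for k, c in enumerate(CHROMOSOMES)}
    gene_index = {g: i for i, g in enumerate(genes)}
    labels = np.array([chrom_index[chrom_of[g]] for g in genes])
    u_idx = np.array([gene_index[str(u)] for u, _ in network.edges()], dtype=int)
    v_idx = np.array([gene_index[str(v)] for _, v in network.edges()], dtype=int)
    return labels, u_idx, v_idx


def _pair_count_matrix(labels, u_idx, v_idx, c: int) -> np.ndarray:
    """Symmetric c x c edge-count table; each edge counted once (the
    diagonal holds within-chromosome counts)."""
    ci = labels[u_idx]
    cj = labels[v_idx]
    lo = np.minimum(ci, cj)
    hi = np.maximum(ci, cj)
    flat = np.bincount(lo * c + hi, minlength=c * c)
    s = flat.reshape(c, c)
    return s + np.triu(s, k=1).T


def intra_fraction(network: nx.Graph, catalog: pd.DataFrame) -> float:
    """Fraction of edges whose endpoints share a chromosome
    (cis-interactions, in the loose regulatory analogy)."""
    if network.number_of_edges() == 0:
        raise ValueError("network has no edges")
    labels, u_idx, v_idx = _edge_chrom_indices(network, catalog)
    return float(np.mean(labels[u_idx] == labels[v_idx]))


def chrom_pair_counts(network: nx.Graph, catalog: pd.DataFrame) -> pd.DataFrame:
    """Symmetric 24 x 24 interaction-count table s_ij (diagonal =
    within-chromosome counts); the upper triangle plus diagonal sums to
    the network's edge count."""
    labels, u_idx, v_idx = _edge_chrom_indices(network, catalog)
    c = len(CHROMOSOMES)
    s = _pair_count_matrix(labels, u_idx, v_idx, c)
    return pd.DataFrame(s, index=list(CHROMOSOMES), columns=list(CHROMOSOMES))


def permutation_pvalue(observed: int, replicate_counts, E: int | None = None,
                       smoothed: bool = False) -> float:
    """Empirical p from replicate counts.

    The literal form is (1/E) sum_e I(s^e > observed) — strict exceedance,
    so p = 0 is attainable (and a pair whose null is identically equal to
    its observed count also gets 0, a known pathology of the strict form
    on sparse tables).  ``smoothed=True`` switches to the standard valid
    permutation p-value (#{s^e >= observed} + 1) / (E + 1), which is
    stochastically >= uniform under the null and safe to feed into FDR
    procedures.
    """
    replicate_counts = np.asarray(replicate_counts)
    if E is None:
        E = replicate_counts.size
    if smoothed:
        x = int(np.sum(replicate_counts >= observed))
        return (x + 1) / (E + 1)
    if observed == 0:
        # zero observed interactions cannot be an excess; the strict-> form
        # would report a vacuous 0 whenever the null is identically zero too
        return 1.0
    return int(np.sum(replicate_counts > observed)) / E


def permutation_test(network: nx.Graph, catalog: pd.DataFrame,
                     E: int = 100_000, seed: int = 0, alpha: float = 0.05,
                     smoothed: bool = False) -> list[ChromPairTest]:
    """Gene-label permutation test for every chromosome pair.

    Each of the E replicates permutes the chromosome assignment uniformly
    over the network's genes (graph fixed), recomputes all pair counts
    s^e_ij, and each pair's p-value is the strict-exceedance fraction
    against its own null distribution.  BH correction runs over all 300
    pairs of the 24 canonical chromosomes.
    """
    if E < 1:
        raise ValueError("E must be >= 1")
    labels, u_idx, v_idx = _edge_chrom_indices(network, catalog)
    c = len(CHROMOSOMES)
    observed = _pair_count_matrix(labels, u_idx, v_idx, c)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(c)
    obs_flat = observed[iu]
    exceed = np.zeros(obs_flat.size, dtype=np.int64)
    exceed_eq = np.zeros(obs_flat.size, dtype=np.int64)
    null_sum = np.zeros(obs_flat.size, dtype=np.int64)
    for _ in range(E):
        perm = rng.permutation(labels)
        s_e = _pair_count_matrix(perm, u_idx, v_idx, c)[iu]
        exceed += s_e > obs_flat
        exceed_eq += s_e >= obs_flat
        null_sum += s_e
    if smoothed:
        pvals = (exceed_eq + 1) / (E + 1)
    else:
        pvals = exceed / E
        pvals[obs_flat == 0] = 1.0  # zero observed count is never an excess
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    results = []
    for idx, (a, b) in enumerate(zip(*iu)):
        results.append(ChromPairTest(
            chrom_i=CHROMOSOMES[a], chrom_j=CHROMOSOMES[b],
            s_observed=int(obs_flat[idx]), exceed_count=int(exceed[idx]),
            E=E, p_value=float(pvals[idx]), p_adjusted=float(p_adj[idx]),
            significant=bool(reject[idx]),
            s_null_mean=float(null_sum[idx] / E)))
    return results
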