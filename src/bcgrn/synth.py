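"""Synthetic data with planted structure for every pipeline stage.

The generator plants an undirected "true" regulatory network, emits
expression data whose marginal correlations track the planted edges,
annotation terms enriched for planted edges, a chromosome catalog with
optional planted chromosome cooperation, and a census-gene subset that can
be biased toward a chosen module.  Downstream stages are thereby testable
end to end with a known ground truth.

Expression model
----------------
Each planted edge e carries an independent standard-normal latent factor
f_e per sample.  Gene g's expression is

    x_g = sqrt(s) * sum_{e incident to g} f_e + sigma_g * eps_g

with s the edge strength and sigma_g^2 = max(1 - s * deg(g), 0.05).  For a
degree-1--degree-1 edge the Pearson correlation is exactly s; edges into
hubs attenuate (the hub's variance grows with its degree), which is the
regime a marginal-dependence method actually faces.  Non-adjacent genes
share no factor and are uncorrelated.  Values are shifted to a log2-like
location (mean 8) with user noise on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import CHROMOSOMES, AnnotationSet

__all__ = [
    "PlantedTruth",
    "generate_network",
    "simulate_expression",
    "generate_annotations",
    "generate_catalog",
    "generate_census",
    "generate_probe_matrix",
]

# Relative gene-count weights for chromosomes 1..22, X, Y, shaped like the
# human genome's uneven chromosome sizes so per-pair permutation nulls differ.
_CHROM_WEIGHTS = np.array(
    [2000, 1300, 1100, 800, 900, 1000, 950, 700, 800, 750,
     1300, 1050, 350, 650, 650, 850, 1200, 300, 1400, 550,
     250, 450, 850, 60], dtype=float)


def _gene_ids(p: int) -> list[str]:
    width = len(str(p - 1))
    return [f"G{i:0{width}d}" for i in range(p)]


@dataclass
class PlantedTruth:
    """Ground truth underlying a synthetic dataset.

    Fields
    ------
    network
        The planted simple undirected network.
    edge_strength
        Target per-edge correlation magnitude, strictly inside (0, 1).
    module_terms
        Term ids planted to be enriched for within-term edges.
    coop_pairs
        Chromosome pairs planted with excess inter-chromosome edges.
    """

    network: nx.Graph
    edge_strength: float = 0.8
    module_terms: list[str] = field(default_factory=list)
    coop_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.edge_strength < 1.0:
            raise ValueError("edge_strength must lie strictly in (0, 1)")
        if any(u == v for u, v in self.network.edges()):
            raise ValueError("planted network must be simple (no self-loops)")


def generate_network(p: int, model: str = "scale-free",
                     mean_degree: float = 2.0, seed: int = 0) -> nx.Graph:
    """Generate a planted network over ``p`` genes.

    ``model="scale-free"`` grows the graph by preferential attachment
    (heavy-tailed degrees, exponent near 3); ``model="random"`` draws a
    uniform G(n, m) graph.  Fractional mean degrees are honoured in
    expectation by randomizing each new node's attachment count.
    """
    if p < 3:
        raise ValueError("p must be >= 3")
    n_edges = round(p * mean_degree / 2)
    if n_edges > p * (p - 1) // 2:
        raise ValueError(
            f"mean_degree {mean_degree} implies {n_edges} edges, more than "
            f"the {p * (p - 1) // 2} possible for p={p}")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(p)
    g = nx.Graph()
    g.add_nodes_from(genes)
    if model == "random":
        pairs = rng.choice(p * (p - 1) // 2, size=n_edges, replace=False)
        # unrank the combination index to an (i, j) pair, i > j
        for idx in pairs:
            idx = int(idx)
            i = (1 + math.isqrt(8 * idx + 1)) // 2
            j = idx - i * (i - 1) // 2
            g.add_edge(genes[i], genes[j])
    elif model == "scale-free":
        m_mean = mean_degree / 2.0
        lo = int(np.floor(m_mean))
        frac = m_mean - lo
        # degree+1 attachment kernel lets isolated nodes be reached
        for i in range(1, p):
            m_i = lo + (1 if rng.random() < frac else 0)
            m_i = min(m_i, i)
            if m_i == 0:
                continue
            weights = np.array([g.degree(genes[j]) + 1 for j in range(i)],
                               dtype=float)
            targets = rng.choice(i, size=m_i, replace=False,
                                 p=weights / weights.sum())
            for t in targets:
                g.add_edge(genes[i], genes[t])
    else:
        raise ValueError(f"unknown network model {model!r}")
    return g


def simulate_expression(truth: PlantedTruth, n_samples: int = 300,
                        noise_sd: float = 0.25, seed: int = 0) -> pd.DataFrame:
    """Simulate a genes x samples expression matrix from the planted truth.

    See the module docstring for the shared-latent-factor model.
    ``noise_sd`` adds measurement noise on top of the unit-scale biological
    signal; the output is shifted to a log2-like location.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    net = truth.network
    genes = sorted(net.nodes())
    p = len(genes)
    s = truth.edge_strength
    gene_index = {g: i for i, g in enumerate(genes)}
    edges = [tuple(sorted((u, v))) for u, v in net.edges()]
    x = np.zeros((p, n_samples))
    if edges:
        factors = rng.standard_normal((len(edges), n_samples))
        w = np.sqrt(s)
        for e_idx, (u, v) in enumerate(edges):
            x[gene_index[u]] += w * factors[e_idx]
            x[gene_index[v]] += w * factors[e_idx]
    deg = np.array([net.degree(g) for g in genes], dtype=float)
    # residual absorbs the measurement noise so a degree-1--degree-1 edge
    # hits the target correlation exactly (total variance 1)
    resid_var = np.maximum(1.0 - s * deg - noise_sd**2, 0.05)
    x += np.sqrt(resid_var)[:, None] * rng.standard_normal((p, n_samples))
    x += noise_sd * rng.standard_normal((p, n_samples))
    x += 8.0  # log2-intensity-like location
    cols = [f"S{j:03d}" for j in range(n_samples)]
    return pd.DataFrame(x, index=genes, columns=cols)


def generate_annotations(truth: PlantedTruth, n_terms: int = 50,
                         size_range: tuple[int, int] = (5, 40),
                         n_planted: int = 5, seed: int = 0) -> AnnotationSet:
    """Generate GMT-style terms; ``n_planted`` of them cover connected
    neighborhoods of the planted network (guaranteeing excess within-term
    edges), the rest are uniform gene draws.

    Planted term ids are recorded in ``truth.module_terms``.
    """
    lo, hi = size_range
    genes = sorted(truth.network.nodes())
    p = len(genes)
    if not 3 <= lo <= hi <= p:
        raise ValueError(f"size_range must satisfy 3 <= lo <= hi <= {p}")
    if n_planted > n_terms:
        raise ValueError("n_planted must be <= n_terms")
    rng = np.random.default_rng(seed)
    net = truth.network
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    truth.module_terms = []
    # planted terms: breadth-first neighborhoods seeded at high-degree nodes
    by_degree = sorted(genes, key=lambda g: (-net.degree(g), g))
    for t in range(n_planted):
        size = int(rng.integers(lo, hi + 1))
        seed_gene = by_degree[t % max(1, len(by_degree) // 4)]
        members: list[str] = []
        seen = set()
        frontier = [seed_gene]
        while frontier and len(members) < size:
            node = frontier.pop(0)
            if node in seen:
                continue
            seen.add(node)
            members.append(node)
            nbrs = sorted(set(net.neighbors(node)) - seen)
            frontier.extend(nbrs)
        if len(members) < size:  # pad from the complement if neighborhood ran dry
            pool = [g for g in genes if g not in seen]
            extra = rng.choice(len(pool), size=size - len(members), replace=False)
            members.extend(pool[i] for i in extra)
        term_id = f"T{t:04d}_planted"
        terms[term_id] = frozenset(members)
        descriptions[term_id] = "planted module"
        truth.module_terms.append(term_id)
    for t in range(n_planted, n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = [genes[i] for i in rng.choice(p, size=size, replace=False)]
        term_id = f"T{t:04d}"
        terms[term_id] = frozenset(members)
        descriptions[term_id] = "background term"
    return AnnotationSet(terms=terms, descriptions=descriptions)


def generate_catalog(genes, n_chrom: int = 24,
                     coop_pairs=None, seed: int = 0,
                     network: nx.Graph | None = None,
                     coop_fraction: float = 0.2) -> pd.DataFrame:
    """Assign every gene exactly one chromosome (unevenly sized, mirroring
    the human genome), optionally planting chromosome cooperation.

    With ``coop_pairs`` and ``network`` given, for each planted pair
    (i, j) a ``coop_fraction`` share of the network's edges is relabelled
    so one endpoint sits on i and the other on j, inflating the
    inter-chromosome interaction count s_ij that the permutation test
    should then rediscover.  The ``census`` column is initialized to 0;
    use :func:`generate_census` to flag census genes.
    """
    genes = sorted(str(g) for g in genes)
    if not 2 <= n_chrom <= 24:
        raise ValueError("n_chrom must be in [2, 24]")
    rng = np.random.default_rng(seed)
    chroms = list(CHROMOSOMES[:n_chrom])
    w = _CHROM_WEIGHTS[:n_chrom]
    labels = rng.choice(n_chrom, size=len(genes), p=w / w.sum())
    assignment = {g: chroms[k] for g, k in zip(genes, labels)}
    if coop_pairs:
        if network is None:
            raise ValueError("planting coop_pairs requires the network")
        edges = sorted(tuple(sorted((str(u), str(v))))
                       for u, v in network.edges())
        for ci, cj in coop_pairs:
            if ci not in chroms or cj not in chroms:
                raise ValueError(f"coop pair ({ci}, {cj}) outside catalog chromosomes")
            k = max(1, round(coop_fraction * len(edges)))
            picked = rng.choice(len(edges), size=min(k, len(edges)),
                                replace=False)
            for e in picked:
                u, v = edges[e]
                assignment[u] = ci
                assignment[v] = cj
    return pd.DataFrame(
        {"chromosome": [assignment[g] for g in genes],
         "census": 0},
        index=pd.Index(genes, name="gene"))


def generate_census(genes, n_census: int, bias_term=None,
                    seed: int = 0, bias_fraction: float = 0.5) -> frozenset[str]:
    """Draw a census gene set; with ``bias_term`` (a gene collection) given,
    a ``bias_fraction`` share of the set is drawn from the term's genes and
    the rest uniformly from the remainder.  Without bias the draw is uniform.
    """
    genes = sorted(str(g) for g in genes)
    if n_census > len(genes):
        raise ValueError(f"n_census {n_census} exceeds gene count {len(genes)}")
    rng = np.random.default_rng(seed)
    if bias_term is None:
        picked = rng.choice(len(genes), size=n_census, replace=False)
        return frozenset(genes[i] for i in picked)
    term_genes = sorted(set(map(str, bias_term)) & set(genes))
    n_from_term = min(len(term_genes), round(bias_fraction * n_census))
    chosen = set(term_genes[i] for i in
                 rng.choice(len(term_genes), size=n_from_term, replace=False))
    pool = [g for g in genes if g not in chosen]
    rest = rng.choice(len(pool), size=n_census - len(chosen), replace=False)
    chosen.update(pool[i] for i in rest)
    return frozenset(chosen)


def generate_probe_matrix(expr: pd.DataFrame, probes_per_gene: int = 2,
                          n_unmapped: int = 0, noise_sd: float = 0.1,
                          seed: int = 0):
    """Fan a gene-level matrix out to probe level for preprocess testing.

    Each gene gets ``probes_per_gene`` probes (gene value + probe noise);
    ``n_unmapped`` extra probes carry no mapping.  Returns
    ``(probe_matrix, probe_to_gene)``.
    """
    rng = np.random.default_rng(seed)
    rows, ids, mapping = [], [], {}
    for gene in expr.index:
        for k in range(probes_per_gene):
            pid = f"{gene}_at{k}"
            ids.append(pid)
            mapping[pid] = gene
            rows.append(expr.loc[gene].to_numpy()
                        + noise_sd * rng.standard_normal(expr.shape[1]))
    for k in range(n_unmapped):
        ids.append(f"AFFX_ctrl{k}")
        rows.append(8.0 + rng.standard_normal(expr.shape[1]))
    probe_matrix = pd.DataFrame(rows, index=ids, columns=expr.columns)
    return probe_matrix, mapping
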