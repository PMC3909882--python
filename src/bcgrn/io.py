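"""Readers and writers for the pipeline's file formats.

Expression matrices are genes x samples TSV files (first column gene ids,
header row sample ids) held in memory as pandas DataFrames.  Networks are
simple undirected :class:`networkx.Graph` objects, written canonically as
two-column edge-list TSV with the lexicographically smaller gene first
(diff-able and deterministic); GraphML is offered for interoperability.
Gene sets use the tab-separated GMT convention; the gene catalog is a TSV
with columns ``gene``, ``chromosome`` (1..22, X, Y) and ``census`` (0/1).

Every writer/reader pair is a lossless round trip on valid inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger("bcgrn")

#: The 24 admissible chromosome labels.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

__all__ = [
    "CHROMOSOMES",
    "AnnotationSet",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_catalog",
    "write_catalog",
    "read_network",
    "write_network",
    "read_gene_list",
    "write_gene_list",
]


@dataclass
class AnnotationSet:
    """Term -> gene-set annotations (the GMT model of GO Biological Process).

    ``terms`` maps a term id to its (deduplicated) gene set;
    ``descriptions`` carries the free-text second GMT column.
    """

    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.terms[term]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 expression TSV.

    Raises on duplicated gene ids (naming them) and on non-numeric cells
    (naming the offending row/column).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    dups = df.index[df.index.duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any() or df.isna().any().any():
        mask = numeric.isna()
        r, c = next(zip(*mask.values.nonzero()))
        raise ValueError(
            f"non-numeric or missing value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}"
        )
    logger.info("read expression matrix %s: %d genes x %d samples",
                path, *numeric.shape)
    return numeric.astype(float)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read gene sets in GMT format: term id, description, then gene ids.

    Terms with no genes are skipped with a warning; gene lists are
    deduplicated.
    """
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(g for g in parts[2:]):
                logger.warning("skipping GMT line %d (term %r): no genes",
                               lineno, parts[0] if parts else "")
                continue
            term, desc = parts[0], parts[1]
            terms[term] = frozenset(g for g in parts[2:] if g)
            descriptions[term] = desc
    return AnnotationSet(terms=terms, descriptions=descriptions)


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations.terms):
            desc = annotations.descriptions.get(term, "")
            genes = "\t".join(sorted(annotations.terms[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read the gene catalog TSV (columns gene, chromosome, census).

    The chromosome column must take values in 1..22, X, Y; census is 0/1.
    Returns a DataFrame indexed by gene.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str})
    required = {"gene", "chromosome", "census"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog {path} missing columns: {sorted(missing)}")
    bad = sorted(set(df["chromosome"]) - set(CHROMOSOMES))
    if bad:
        raise ValueError(f"invalid chromosome labels in {path}: {bad}")
    dups = df["gene"][df["gene"].duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"duplicate genes in catalog {path}: {dups}")
    if not df["census"].isin([0, 1]).all():
        raise ValueError(f"census column of {path} must be 0/1")
    return df.set_index("gene")[["chromosome", "census"]]


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index_label="gene")


def _canonical_edges(network: nx.Graph) -> list[tuple[str, str]]:
    edges = [tuple(sorted((str(u), str(v)))) for u, v in network.edges()]
    return sorted(edges)


def write_network(network: nx.Graph, path: str | Path,
                  format: str = "edgelist") -> None:
    """Write a network as canonical edge-list TSV or as GraphML.

    Edge-list rows hold the lexicographically smaller gene first and are
    sorted, so identical networks always serialize identically.  Isolated
    nodes are preserved via a trailing single-column block.
    """
    if format == "graphml":
        nx.write_graphml(network, path)
        return
    if format != "edgelist":
        raise ValueError(f"unknown network format {format!r}")
    isolated = sorted(str(n) for n in network.nodes() if network.degree(n) == 0)
    with open(path, "w") as fh:
        for u, v in _canonical_edges(network):
            fh.write(f"{u}\t{v}\n")
        for n in isolated:
            fh.write(f"{n}\n")


def read_network(path: str | Path, format: str = "edgelist") -> nx.Graph:
    """Read a network written by :func:`write_network`; self-loops rejected."""
    if format == "graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, str)
    elif format == "edgelist":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    g.add_node(parts[0])
                elif len(parts) >= 2:
                    g.add_edge(parts[0], parts[1])
    else:
        raise ValueError(f"unknown network format {format!r}")
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise ValueError(f"network {path} contains self-loops: {loops[:5]}")
    return g


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a one-gene-per-line list (e.g. the census gene set)."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
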