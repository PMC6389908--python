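"""Mutual-Rank co-expression networks and hub-gene detection.

The Mutual Rank (MR) of a gene pair is the geometric mean of the two
asymmetric co-expression ranks: rank_a(b) is the position of b in gene
a's list of partners sorted by decreasing Pearson correlation (self
excluded, rank 1 = most correlated, tied correlations receive average
ranks).  Lower MR means stronger co-expression.  Edges are kept when
MR < mr_max and PCC > pcc_min (both strict); hubs are nodes whose
degree in the filtered graph exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CoexpressionNetwork",
    "correlation_matrix",
    "mutual_rank",
    "filter_edges",
    "build_network",
    "find_hubs",
    "coexpression_network",
]


@dataclass
class CoexpressionNetwork:
    """Filtered MR/PCC graph with node degrees and hub list."""

    graph: nx.Graph
    edges: pd.DataFrame  # gene_a, gene_b, pcc, mr
    hubs: list[str]
    degree_threshold: int

    def node_table(self) -> pd.DataFrame:
        degrees = dict(self.graph.degree())
        return pd.DataFrame(
            {
                "gene": list(degrees),
                "degree": list(degrees.values()),
                "is_hub": [g in set(self.hubs) for g in degrees],
            }
        ).sort_values("degree", ascending=False, ignore_index=True)


def correlation_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between genes (columns of the matrix)."""
    corr = np.corrcoef(expression.to_numpy(dtype=float), rowvar=False)
    return pd.DataFrame(corr, index=expression.columns, columns=expression.columns)


def mutual_rank(correlation: pd.DataFrame) -> pd.DataFrame:
    """MR(a,b) = sqrt(rank_a(b) * rank_b(a)) for every gene pair.

    The diagonal is NaN (a gene has no rank with itself).
    """
    corr = np.asarray(correlation, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {corr.shape}")
    n = corr.shape[0]
    if n < 2:
        raise ValueError("at least two genes are required")
    ranks = np.full((n, n), np.nan)
    mask = ~np.eye(n, dtype=bool)
    for a in range(n):
        others = mask[a]
        # descending correlation, average ranks on ties
        ranks[a, others] = rankdata(-corr[a, others])
    mr = np.sqrt(ranks * ranks.T)
    if isinstance(correlation, pd.DataFrame):
        return pd.DataFrame(mr, index=correlation.index, columns=correlation.columns)
    return pd.DataFrame(mr)


def filter_edges(
    pcc: pd.DataFrame,
    mr: pd.DataFrame,
    mr_max: float = 20.0,
    pcc_min: float = 0.4,
) -> pd.DataFrame:
    """Gene pairs with MR < mr_max and PCC > pcc_min (both strict)."""
    if pcc.shape != mr.shape:
        raise ValueError("PCC and MR matrices must be aligned")
    genes = list(pcc.index)
    p = np.asarray(pcc, dtype=float)
    m = np.asarray(mr, dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = (m[iu, ju] < mr_max) & (p[iu, ju] > pcc_min)
    return pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu[keep]],
            "gene_b": [genes[j] for j in ju[keep]],
            "pcc": p[iu[keep], ju[keep]],
            "mr": m[iu[keep], ju[keep]],
        }
    )


def build_network(edges: pd.DataFrame, nodes: list[str] | None = None) -> nx.Graph:
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    for row in edges.itertuples(index=False):
        graph.add_edge(row.gene_a, row.gene_b, pcc=row.pcc, mr=row.mr)
    return graph


def find_hubs(graph: nx.Graph, degree_threshold: int = 25) -> list[str]:
    """Nodes with degree strictly above the threshold, sorted by degree
    descending (name ascending on ties)."""
    hubs = [(d, n) for n, d in graph.degree() if d > degree_threshold]
    return [n for d, n in sorted(hubs, key=lambda t: (-t[0], str(t[1])))]


def coexpression_network(
    expression_or_corr: pd.DataFrame,
    mr_max: float = 20.0,
    pcc_min: float = 0.4,
    degree_threshold: int = 25,
    is_correlation: bool = False,
) -> CoexpressionNetwork:
    """End-to-end network construction from expression (or a precomputed
    correlation matrix, with ``is_correlation=True``)."""
    pcc = (
        expression_or_corr
        if is_correlation
        else correlation_matrix(expression_or_corr)
    )
    mr = mutual_rank(pcc)
    edges = filter_edges(pcc, mr, mr_max=mr_max, pcc_min=pcc_min)
    graph = build_network(edges, nodes=list(pcc.index))
    hubs = find_hubs(graph, degree_threshold)
    return CoexpressionNetwork(
        graph=graph, edges=edges, hubs=hubs, degree_threshold=degree_threshold
    )
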