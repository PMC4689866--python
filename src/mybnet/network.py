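"""Signed Pearson co-expression networks, threshold diagnostics and mutual ranks.

An edge joins two genes when the magnitude of their Pearson correlation
(computed across samples on log2 values) exceeds the chosen cutoff; the
signed r is kept on the edge, so positively and negatively co-expressed
pairs are distinguishable downstream.  Threshold-sweep diagnostics (node
and edge counts, density 2E/(N(N-1)), scale-free fit R^2) support cutoff
selection, and the mutual-rank statistic MR(a,b) = sqrt(rank_a(b)*rank_b(a))
feeds guide-gene expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """All-vs-all Pearson correlations: symmetric, unit diagonal, |r| <= 1."""

    gene_ids: list[str]
    r_values: np.ndarray
    n_samples: int

    def __post_init__(self):
        r = np.asarray(self.r_values, float)
        if r.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("r_values shape does not match gene_ids")
        self.r_values = r

    def r(self, a: str, b: str) -> float:
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return float(self.r_values[i, j])


@dataclass
class SignedNetwork:
    """Undirected graph of genes whose |r| survived the cutoff; r on each edge."""

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def density(self) -> float:
        n = self.n_nodes()
        if n < 2:
            return 0.0
        return 2.0 * self.n_edges() / (n * (n - 1))


@dataclass
class MutualRankMatrix:
    """Symmetric mutual ranks, MR >= 1; MR = 1 means reciprocal best correlates."""

    gene_ids: list[str]
    mr_values: np.ndarray

    def mr(self, a: str, b: str) -> float:
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return float(self.mr_values[i, j])


def pearson_all_pairs(matrix: ExpressionMatrix) -> CorrelationMatrix:
    """Pairwise Pearson r over samples; zero-variance genes are excluded.

    Requires at least 3 samples.  Excluded genes are logged rather than
    producing undefined correlations.
    """
    values = matrix.values.to_numpy(float)
    if values.shape[1] < 3:
        raise ValueError("need >=3 samples for Pearson correlation")
    variances = values.var(axis=1)
    keep = variances > 0
    dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    if dropped:
        logger.info("pearson_all_pairs: excluded %d zero-variance genes: %s",
                    len(dropped), dropped[:5])
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    r = np.atleast_2d(np.corrcoef(values[keep]))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(gene_ids=genes, r_values=r, n_samples=values.shape[1])


def build_network(corr: CorrelationMatrix, cutoff: float, strict: bool = True) -> SignedNetwork:
    """Retain edges with |r| > cutoff (strict by default), sign preserved.

    Nodes are genes with at least one retained edge.  ``strict=False``
    switches the comparison to |r| >= cutoff for sensitivity analysis.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    r = corr.r_values
    absr = np.abs(r)
    mask = absr > cutoff if strict else absr >= cutoff
    np.fill_diagonal(mask, False)
    g = nx.Graph()
    ii, jj = np.nonzero(np.triu(mask, 1))
    for i, j in zip(ii, jj):
        g.add_edge(corr.gene_ids[i], corr.gene_ids[j], r=float(r[i, j]),
                   sign="+" if r[i, j] > 0 else "-")
    return SignedNetwork(graph=g, cutoff=cutoff)


def degree_frequency_r2(degrees) -> float:
    """R^2 of the OLS fit of log10(frequency of degree k) on log10(k).

    Raw degree-frequency spectrum (no binning, no cumulative transform)
    over observed degrees k >= 1.  NaN with fewer than 3 distinct degrees.
    """
    degrees = [d for d in degrees if d >= 1]
    if not degrees:
        return float("nan")
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        return float("nan")
    res = stats.linregress(np.log10(ks), np.log10(counts))
    return float(res.rvalue**2)


def scale_free_fit(network: SignedNetwork) -> float:
    """Scale-free topology diagnostic: degree-distribution power-law R^2."""
    return degree_frequency_r2([d for _, d in network.graph.degree()])


def sweep_thresholds(corr: CorrelationMatrix, cutoffs) -> "pd.DataFrame":
    """Network size/density/scale-free diagnostics over an increasing cutoff grid."""
    import pandas as pd

    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    rows = []
    for c in cutoffs:
        net = build_network(corr, c)
        rows.append(
            {
                "cutoff": c,
                "n_nodes": net.n_nodes(),
                "n_edges": net.n_edges(),
                "density": net.density(),
                "scale_free_r2": scale_free_fit(net),
            }
        )
    return pd.DataFrame(rows)


def mutual_ranks(corr: CorrelationMatrix) -> MutualRankMatrix:
    """Mutual rank MR(a,b) = sqrt(rank_a(b) * rank_b(a)).

    rank_a(b) is b's 1-based position among all genes != a ordered by
    decreasing r(a, .); ties are broken by gene-id order for determinism.
    """
    n = len(corr.gene_ids)
    if n < 3:
        raise ValueError("need >=3 genes for mutual ranks")
    id_order = np.argsort(np.argsort(corr.gene_ids))  # lexicographic rank per index
    ranks = np.zeros((n, n))
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        # sort by decreasing r then increasing gene id
        order = others[np.lexsort((id_order[others], -corr.r_values[i, others]))]
        ranks[i, order] = np.arange(1, n)
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, 0.0)
    return MutualRankMatrix(gene_ids=list(corr.gene_ids), mr_values=mr)
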