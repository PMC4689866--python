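"""Naive dense-matrix Markov-Clustering oracle, independent of mybnet.mcl.

Deliberately written down a different path from the package implementation:
no pruning during iteration, and clusters are read off as connected
components of the thresholded limit matrix instead of attractor-row
bookkeeping.  Used only to cross-check partitions on small graphs.
"""

import networkx as nx
import numpy as np


def reference_mcl(adjacency: np.ndarray, inflation: float,
                  max_iter: int = 300, tol: float = 1e-8) -> list[set]:
    a = np.array(adjacency, dtype=float)
    np.fill_diagonal(a, 1.0)  # same self-loop convention as the package
    m = a / a.sum(axis=0)
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = m ** inflation
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < tol:
            break
    g = nx.Graph()
    g.add_nodes_from(range(len(m)))
    for i, j in np.argwhere(m > 1e-5):
        if i != j:
            g.add_edge(int(i), int(j))
    return [set(c) for c in nx.connected_components(g)]


def partitions_agree(clusters_a, clusters_b, min_size: int = 3) -> bool:
    """Equality up to clusters below the size filter."""
    fa = {frozenset(c) for c in clusters_a if len(c) >= min_size}
    fb = {frozenset(c) for c in clusters_b if len(c) >= min_size}
    return fa == fb
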