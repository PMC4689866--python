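"""Degree-based hub calling and ego-subnetwork summaries.

A hub is a node with degree >= ``min_hub_degree`` (default 5) in the
thresholded co-expression network.  The report splits each hub's edges by
correlation sign and gives the mean |r| on each side, mirroring how
highly connected transcription factors are usually summarised.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .network import SignedNetwork


def find_hubs(network: SignedNetwork, min_hub_degree: int = 5,
              module_of: dict | None = None) -> pd.DataFrame:
    """All nodes with degree >= min_hub_degree, sorted by degree desc then id.

    Columns: gene, degree, positive_edges, negative_edges, mean_abs_r_pos,
    mean_abs_r_neg, module (NA without a module map).
    """
    rows = []
    for gene, deg in network.graph.degree():
        if deg < min_hub_degree:
            continue
        rs = [d["r"] for _, _, d in network.graph.edges(gene, data=True)]
        pos = [r for r in rs if r > 0]
        neg = [r for r in rs if r < 0]
        rows.append(
            {
                "gene": gene,
                "degree": deg,
                "positive_edges": len(pos),
                "negative_edges": len(neg),
                "mean_abs_r_pos": float(np.mean(np.abs(pos))) if pos else np.nan,
                "mean_abs_r_neg": float(np.mean(np.abs(neg))) if neg else np.nan,
                "module": module_of.get(gene) if module_of else pd.NA,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "degree", "positive_edges",
                                      "negative_edges", "mean_abs_r_pos",
                                      "mean_abs_r_neg", "module"])
    return out.sort_values(["degree", "gene"], ascending=[False, True],
                           ignore_index=True)


def ego_subnetwork(network: SignedNetwork, gene: str) -> SignedNetwork:
    """Induced subgraph on a gene and its first neighbors, signs preserved."""
    if gene not in network.graph:
        raise KeyError(f"gene {gene!r} not in network")
    sub = network.graph.subgraph(nx.ego_graph(network.graph, gene, radius=1).nodes)
    return SignedNetwork(graph=nx.Graph(sub), cutoff=network.cutoff)
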