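"""Guide-gene network expansion by mutual rank and correlation thresholds.

Starting from functionally characterised guide genes, the network is grown
breadth-first: a gene joins at level k when it is linked to a level-(k-1)
gene by an edge with mutual rank MR <= ``mr_max`` and Pearson r >=
``pcc_min``, up to ``hierarchy_depth`` levels (default 2).  A gene
reachable at several depths keeps its minimal level; all threshold-passing
edges among included genes are retained.  First neighbors (level 1)
carrying at least one MYB binding site in their promoter are nominated as
putative targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .motifs import DROUGHT_MBS_IDS
from .network import CorrelationMatrix, MutualRankMatrix


@dataclass
class GuideConfig:
    guides: tuple
    hierarchy_depth: int = 2
    mr_max: float = 5.0
    pcc_min: float = 0.6

    def __post_init__(self):
        self.guides = tuple(self.guides)
        if self.hierarchy_depth < 1:
            raise ValueError("hierarchy_depth must be >= 1")
        if self.mr_max < 1:
            raise ValueError("mr_max must be >= 1")
        if not 0 < self.pcc_min < 1:
            raise ValueError("pcc_min must be in (0, 1)")


@dataclass
class GuideNetwork:
    """Expansion result: nodes carry a ``level`` attribute (0 = guide)."""

    graph: nx.Graph
    config: GuideConfig

    def level_of(self, gene: str) -> int:
        return self.graph.nodes[gene]["level"]

    def first_neighbors(self) -> frozenset:
        return frozenset(g for g, d in self.graph.nodes(data=True) if d["level"] == 1)

    def guides(self) -> frozenset:
        return frozenset(g for g, d in self.graph.nodes(data=True) if d["level"] == 0)


def expand_from_guides(corr: CorrelationMatrix, mr: MutualRankMatrix,
                       config: GuideConfig) -> GuideNetwork:
    """Breadth-first MR/PCC-thresholded expansion from the guide genes."""
    if list(corr.gene_ids) != list(mr.gene_ids):
        raise ValueError("correlation and mutual-rank matrices disagree on genes")
    idx = {g: i for i, g in enumerate(corr.gene_ids)}
    unknown = [g for g in config.guides if g not in idx]
    if unknown:
        raise KeyError(f"guide genes absent from the matrices: {unknown}")

    passes = (mr.mr_values <= config.mr_max) & (corr.r_values >= config.pcc_min)
    np.fill_diagonal(passes, False)

    level = {g: 0 for g in config.guides}
    frontier = list(config.guides)
    for depth in range(1, config.hierarchy_depth + 1):
        nxt = []
        for g in frontier:
            for j in np.nonzero(passes[idx[g]])[0]:
                nb = corr.gene_ids[j]
                if nb not in level:  # minimal level kept
                    level[nb] = depth
                    nxt.append(nb)
        frontier = nxt

    graph = nx.Graph()
    for g, lv in level.items():
        graph.add_node(g, level=lv)
    members = sorted(level)
    for a_i, a in enumerate(members):
        for b in members[a_i + 1:]:
            i, j = idx[a], idx[b]
            if passes[i, j]:
                graph.add_edge(a, b, r=float(corr.r_values[i, j]),
                               mr=float(mr.mr_values[i, j]))
    return GuideNetwork(graph=graph, config=config)


def nominate_targets(guide_net: GuideNetwork, hits) -> pd.DataFrame:
    """Putative-target table: first neighbors with >= 1 MYB binding-site hit.

    One row per (guide, first neighbor, motif occurrence) for every
    guide--neighbor edge in the expansion; r is rounded to 1 decimal
    place in the table.  ``drought_mbs`` flags hits from the
    drought-inducibility MBS subset.
    """
    hits_by_gene: dict[str, list] = {}
    for h in hits:
        hits_by_gene.setdefault(h.gene, []).append(h)
    rows = []
    for guide in sorted(guide_net.guides()):
        for nb in sorted(guide_net.graph.neighbors(guide)):
            if guide_net.level_of(nb) != 1:
                continue
            r = guide_net.graph.edges[guide, nb]["r"]
            for h in sorted(hits_by_gene.get(nb, []),
                            key=lambda h: (h.position, h.motif_id)):
                rows.append(
                    {
                        "guide": guide,
                        "first_neighbor": nb,
                        "pcc": round(r, 1),
                        "motif": h.motif_id,
                        "strand": h.strand,
                        "position": h.position,
                        "drought_mbs": h.motif_id in DROUGHT_MBS_IDS,
                    }
                )
    return pd.DataFrame(rows, columns=["guide", "first_neighbor", "pcc", "motif",
                                       "strand", "position", "drought_mbs"])
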