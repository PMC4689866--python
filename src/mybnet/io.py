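"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV with a header row, FASTA (Biopython) for promoters, and
GraphML (networkx) for external network viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import AnnotationMap
from .expression import ExpressionMatrix
from .motifs import Motif, MotifDictionary, PromoterSet
from .network import SignedNetwork


def read_expression(expr_path, design_path=None) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    design = None
    if design_path is not None:
        design = pd.read_csv(design_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, design=design)


def write_expression(matrix: ExpressionMatrix, expr_path, design_path=None):
    matrix.values.to_csv(expr_path, sep="\t")
    if design_path is not None and matrix.design is not None:
        matrix.design.to_csv(design_path, sep="\t")


def read_annotations(path, universe=None) -> AnnotationMap:
    """Two-column TSV (gene, term).

    The universe is every gene seen in the file, extended by ``universe``
    when given (a flat file cannot carry annotatable-but-unannotated genes,
    so callers holding the expression matrix should pass its gene ids).
    """
    df = pd.read_csv(path, sep="\t")
    gene_col, term_col = df.columns[:2]
    terms: dict[str, set] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        terms.setdefault(str(term), set()).add(str(gene))
    full = frozenset(str(g) for g in df[gene_col]) | frozenset(universe or ())
    return AnnotationMap(term_to_genes={t: frozenset(g) for t, g in terms.items()},
                         universe=full)


def write_annotations(annotations: AnnotationMap, path):
    rows = [(g, t) for t in sorted(annotations.term_to_genes)
            for g in sorted(annotations.term_to_genes[t])]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def read_promoters(path, length: int | None = None) -> PromoterSet:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if length is None:
        length = max((len(s) for s in seqs.values()), default=0)
    return PromoterSet(sequences=seqs, length=length)


def write_promoters(promoters: PromoterSet, path):
    records = [SeqRecord(Seq(promoters.sequences[g]), id=g, description="")
               for g in sorted(promoters.sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_motif_dictionary(path) -> MotifDictionary:
    """TSV with columns id, consensus, category, description."""
    df = pd.read_csv(path, sep="\t")
    motifs = {}
    for _, row in df.iterrows():
        m = Motif(str(row["id"]), str(row["consensus"]), str(row["category"]),
                  str(row.get("description", "")))
        motifs[m.motif_id] = m
    return MotifDictionary(motifs)


def write_motif_dictionary(dictionary: MotifDictionary, path):
    rows = [(m.motif_id, m.consensus, m.category, m.description)
            for m in (dictionary[i] for i in dictionary.ids())]
    pd.DataFrame(rows, columns=["id", "consensus", "category", "description"]) \
        .to_csv(path, sep="\t", index=False)


def write_edge_list(network: SignedNetwork, path):
    rows = [(a, b, d["r"], d["sign"])
            for a, b, d in sorted(network.graph.edges(data=True))]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "sign"]) \
        .to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path):
    nx.write_graphml(graph, str(path))


def write_hits(hits, path):
    rows = [(h.gene, h.motif_id, h.strand, h.position, h.category) for h in hits]
    pd.DataFrame(rows, columns=["gene", "motif", "strand", "position", "category"]) \
        .to_csv(path, sep="\t", index=False)


def write_hits_bed(hits, promoter_length: int, path):
    """BED-like export (0-based half-open) — a distinct coordinate convention."""
    rows = [(h.gene, h.position - 1, h.position - 1 + _w(h), h.motif_id, 0, h.strand)
            for h in hits]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"]) \
        .to_csv(path, sep="\t", index=False, header=False)


def _w(hit):
    from .motifs import DEFAULT_MOTIFS
    return len(DEFAULT_MOTIFS[hit.motif_id].consensus) if hit.motif_id in DEFAULT_MOTIFS else 6


def read_guides(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_module_membership(partition, path):
    rows = [(g, mid, partition.inflation_used)
            for mid in sorted(partition.modules)
            for g in sorted(partition.modules[mid])]
    rows += [(g, "unassigned", partition.inflation_used)
             for g in sorted(partition.unassigned)]
    pd.DataFrame(rows, columns=["gene", "module_id", "inflation"]) \
        .to_csv(path, sep="\t", index=False)


def write_truth(truth, path):
    payload = {
        "module_of_gene": {g: m for g, m in truth.module_of_gene.items()},
        "deg_genes": sorted(truth.deg_genes),
        "term_of_module": {str(m): t for m, t in truth.term_of_module.items()},
        "planted_hits": [[h.gene, h.motif_id, h.strand, h.position]
                         for h in truth.planted_hits],
        "control_condition": truth.control_condition,
        "treatment_condition": truth.treatment_condition,
        "flipped_genes": sorted(truth.flipped_genes),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
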