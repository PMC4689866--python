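"""Hypergeometric term over-representation and the partition F-measure.

For a module of size n drawn from a universe of N genes of which K carry a
term, the enrichment P-value is the hypergeometric upper tail
P(X >= k).  P-values are Benjamini--Hochberg adjusted jointly over all
(module, term) tests of one partition, and a (module, term) pair is
significant when adjusted P < fdr_threshold and the module carries at
least two annotated genes.

Partition quality follows the specificity/sensitivity/F-measure scheme
used to tune graph-clustering granularity: specificity is the fraction of
retained modules enriched for >= 1 term, sensitivity the fraction of
terms enriched in >= 1 module, and F their harmonic mean (0 when both are
0).  Terms are opaque labels; users of real GO annotations must
pre-propagate them through the ontology.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    """term -> gene set, plus the annotation universe."""

    term_to_genes: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self):
        self.term_to_genes = {t: frozenset(g) for t, g in self.term_to_genes.items()}
        self.universe = frozenset(self.universe)
        stray = set().union(*self.term_to_genes.values(), set()) - self.universe
        if stray:
            raise ValueError(f"annotated genes outside the universe: {sorted(stray)[:5]}")

    def n_terms(self) -> int:
        return len(self.term_to_genes)


@dataclass
class EnrichmentRecord:
    module_id: int | str
    term: str
    k: int  # annotated genes in the module
    n: int  # module size
    K: int  # annotated genes in the universe
    N: int  # universe size
    p: float
    adjusted_p: float | None = None
    significant: bool = False


@dataclass
class ClusterQuality:
    inflation: float | None
    specificity: float
    sensitivity: float
    f_measure: float


def _hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    # P(X >= k) with X ~ Hypergeom(N, K, n)
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_module(module, annotations: AnnotationMap, fdr_threshold: float = 0.05):
    """Term over-representation for one module, BH-adjusted across its own terms.

    Only terms with k >= 1 overlap are tested (k = 0 gives p = 1 and only
    dilutes the correction).  For the partition-level score use
    :func:`enrich_partition`, which adjusts jointly.
    """
    records = _raw_records("module", frozenset(module), annotations)
    _adjust(records, fdr_threshold)
    return records


def _raw_records(module_id, module: frozenset, annotations: AnnotationMap):
    if not annotations.universe:
        raise ValueError("empty annotation universe")
    if not module <= annotations.universe:
        raise ValueError("module contains genes outside the universe")
    N = len(annotations.universe)
    n = len(module)
    out = []
    for term in sorted(annotations.term_to_genes):
        genes = annotations.term_to_genes[term]
        k = len(module & genes)
        if k < 1:
            continue
        p = _hypergeom_upper_tail(k, N, len(genes), n)
        out.append(EnrichmentRecord(module_id=module_id, term=term, k=k, n=n,
                                    K=len(genes), N=N, p=p))
    return out


def _adjust(records, fdr_threshold: float):
    if not records:
        return
    adj = multipletests([r.p for r in records], method="fdr_bh")[1]
    for r, a in zip(records, adj):
        r.adjusted_p = float(a)
        r.significant = bool(a < fdr_threshold and r.k >= 2)


def enrich_partition(partition, annotations: AnnotationMap, fdr_threshold: float = 0.05):
    """All (module, term) enrichments of a partition, BH-adjusted jointly."""
    records = []
    for mid in sorted(partition.modules):
        records.extend(_raw_records(mid, partition.modules[mid], annotations))
    _adjust(records, fdr_threshold)
    return records


def cluster_quality(partition, enrichments, annotations: AnnotationMap) -> ClusterQuality:
    """Specificity, sensitivity and their harmonic mean for one partition.

    A partition retaining 0 modules scores 0 on all three.
    """
    n_modules = partition.n_modules()
    n_terms = annotations.n_terms()
    if n_modules == 0 or n_terms == 0:
        return ClusterQuality(partition.inflation_used, 0.0, 0.0, 0.0)
    sig = [r for r in enrichments if r.significant]
    modules_hit = len({r.module_id for r in sig})
    terms_hit = len({r.term for r in sig})
    specificity = modules_hit / n_modules
    sensitivity = terms_hit / n_terms
    return ClusterQuality(
        inflation=partition.inflation_used,
        specificity=specificity,
        sensitivity=sensitivity,
        f_measure=f_measure(specificity, sensitivity),
    )


def f_measure(specificity: float, sensitivity: float) -> float:
    """Harmonic mean of specificity and sensitivity; 0 when both are 0."""
    if specificity + sensitivity == 0:
        return 0.0
    return 2 * specificity * sensitivity / (specificity + sensitivity)
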