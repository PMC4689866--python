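"""Promoter cis-element scanning against a MYB binding-site dictionary.

Promoters are 1 kb sequences written 5'->3' on the gene's coding strand,
ending immediately before the translational start codon (the anchor).
Scanning is exact-string matching of each consensus on the plus strand and
of its reverse complement (reported as strand '-'); hit positions are
1-based and give the leftmost base of the occurrence within the promoter
string.  'N' never matches.

The default dictionary carries the six classical MYB elements: CAACGG
(MYBHv1 / CCAAT-box), AACCTAA (MRE, light responsiveness), AAAAGTTAGTTA
(MBSII, flavonoid gene regulation), TAACTG and CAACTG (MBS,
drought-inducibility) and CGGTCA (generic MBS).  The drought-MBS subset
{TAACTG, CAACTG} drives the drought-target nomination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    motif_id: str
    consensus: str
    category: str
    description: str = ""

    def __post_init__(self):
        if len(self.consensus) < 4:
            raise ValueError("consensus must be >= 4 bases")
        if set(self.consensus) - set("ACGT"):
            raise ValueError("consensus must be over A,C,G,T")


@dataclass
class MotifDictionary:
    motifs: dict[str, Motif]

    def __post_init__(self):
        for mid, m in self.motifs.items():
            if mid != m.motif_id:
                raise ValueError("dictionary key must equal motif id")

    def __getitem__(self, motif_id: str) -> Motif:
        return self.motifs[motif_id]

    def __contains__(self, motif_id: str) -> bool:
        return motif_id in self.motifs

    def ids(self) -> list[str]:
        return sorted(self.motifs)


DEFAULT_MOTIFS = MotifDictionary(
    {
        m.motif_id: m
        for m in [
            Motif("MYBHv1_CAACGG", "CAACGG", "CCAAT-box",
                  "MYBHv1 binding site"),
            Motif("MRE_AACCTAA", "AACCTAA", "MRE-light",
                  "MYB binding site, light responsiveness"),
            Motif("MBSII_AAAAGTTAGTTA", "AAAAGTTAGTTA", "MBSII-flavonoid",
                  "MYB binding site, flavonoid biosynthetic gene regulation"),
            Motif("MBS_TAACTG", "TAACTG", "MBS-drought",
                  "MYB binding site, drought-inducibility"),
            Motif("MBS_CAACTG", "CAACTG", "MBS-drought",
                  "MYB binding site, drought-inducibility"),
            Motif("MBS_CGGTCA", "CGGTCA", "MBS-generic", "MYB binding site"),
        ]
    }
)

DROUGHT_MBS_IDS = frozenset({"MBS_TAACTG", "MBS_CAACTG"})


@dataclass
class PromoterSet:
    """gene -> promoter sequence (coding strand, ends at the start codon)."""

    sequences: dict[str, str]
    length: int = 1000

    def __post_init__(self):
        for g, s in self.sequences.items():
            if set(s) - set("ACGTN"):
                raise ValueError(f"promoter of {g} has characters outside ACGTN")


@dataclass(frozen=True)
class MotifHit:
    gene: str
    motif_id: str
    strand: str  # '+' or '-'
    position: int  # 1-based, leftmost base in the promoter string
    category: str


def _find_all(haystack: str, needle: str):
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i == -1:
            return
        yield i
        start = i + 1  # overlapping occurrences all reported


def scan_promoters(promoters: PromoterSet, dictionary: MotifDictionary = DEFAULT_MOTIFS):
    """Exact both-strand scan of every promoter; returns a list of MotifHit.

    A motif equal to its own reverse complement is reported once per
    position with strand '+'.
    """
    hits: list[MotifHit] = []
    for gene in sorted(promoters.sequences):
        seq = promoters.sequences[gene]
        for mid in dictionary.ids():
            motif = dictionary[mid]
            fwd = motif.consensus
            rev = reverse_complement(fwd)
            for i in _find_all(seq, fwd):
                hits.append(MotifHit(gene, mid, "+", i + 1, motif.category))
            if rev != fwd:  # palindrome rule: report once, strand '+'
                for i in _find_all(seq, rev):
                    hits.append(MotifHit(gene, mid, "-", i + 1, motif.category))
    return hits


def putative_target_filter(hits, genes=None):
    """Genes with >= 1 hit from the full dictionary, and the drought-MBS subset.

    Returns ``(myb_targets, drought_targets)``; ``genes`` optionally
    restricts the result to a candidate set.
    """
    myb = {h.gene for h in hits}
    drought = {h.gene for h in hits if h.motif_id in DROUGHT_MBS_IDS}
    if genes is not None:
        genes = set(genes)
        myb &= genes
        drought &= genes
    return frozenset(myb), frozenset(drought)


def motif_enrichment(hits, promoters: PromoterSet, motif_id: str,
                     dictionary: MotifDictionary = DEFAULT_MOTIFS):
    """Observed vs composition-expected occurrence count for one motif.

    The null model is per-position Bernoulli matching under the pooled
    observed base composition of the promoters; both strands are counted.
    Returns ``(observed, expected, p)`` with p the upper-tail binomial
    probability of observing at least the seen count.
    """
    if motif_id not in dictionary:
        raise KeyError(f"motif {motif_id!r} not in dictionary")
    motif = dictionary[motif_id]
    w = len(motif.consensus)
    counts = Counter()
    for seq in promoters.sequences.values():
        counts.update(seq)
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise ValueError("base composition not estimable (no ACGT bases)")
    freq = {b: counts[b] / total for b in "ACGT"}
    p_fwd = float(np.prod([freq[b] for b in motif.consensus]))
    p_rev = float(np.prod([freq[b] for b in reverse_complement(motif.consensus)]))
    n_positions = sum(max(len(s) - w + 1, 0) for s in promoters.sequences.values())
    expected = n_positions * (p_fwd + p_rev)
    observed = sum(1 for h in hits if h.motif_id == motif_id)
    p_per_site = (p_fwd + p_rev) / 2.0
    pval = float(binom.sf(observed - 1, 2 * n_positions, p_per_site)) if observed > 0 else 1.0
    return observed, expected, pval


def proximal_distal_split(hits, promoter_length: int = 1000, window: int = 200):
    """Fractions of hits proximal/distal to the promoter 3' end (TSS proxy).

    A hit is proximal iff its leftmost position lies within ``window``
    bases of the anchor end, i.e. position > promoter_length - window.
    """
    if not hits:
        return 0.0, 0.0
    prox = sum(1 for h in hits if h.position > promoter_length - window)
    n = len(hits)
    return prox / n, (n - prox) / n


def categorize_hits(hits, dictionary: MotifDictionary = DEFAULT_MOTIFS):
    """Hit counts per category, overall and per gene.

    Returns ``(overall, per_gene)`` where overall is a Counter over
    category labels and per_gene maps gene -> Counter.
    """
    overall: Counter = Counter()
    per_gene: dict[str, Counter] = {}
    for h in hits:
        if h.motif_id not in dictionary:
            raise KeyError(f"unknown motif id {h.motif_id!r}")
        overall[h.category] += 1
        per_gene.setdefault(h.gene, Counter())[h.category] += 1
    return overall, per_gene
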