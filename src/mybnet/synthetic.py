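"""Synthetic expression, annotation and promoter generator with known truth.

Every downstream stage (correlation network, MCL sweep, enrichment
F-measure, hubs, guide expansion, motif scanning) is testable against the
planted structure this module records:

* **Co-expression**: genes of module m share a latent standard-normal
  sample profile z_m and read x_g = s_g * lambda * z_m + eps with
  eps ~ N(0, noise_sd).  The loading lambda is calibrated so the expected
  within-module correlation hits the target:  for two members,
  r = lambda^2 / (lambda^2 + noise_sd^2), hence
  lambda = noise_sd * sqrt(r / (1 - r)).  A fraction of members get
  s_g = -1, producing the planted negatively co-expressed pairs.
  Background genes are pure noise.
* **Differential expression**: a chosen set of genes gets ``deg_effect``
  log2 units added in the designated treatment condition.
* **Annotations**: each module owns a dedicated term covering
  ``annotation_coverage`` of its genes, plus uniform noise terms.
* **Promoters**: iid sequences from ``base_composition`` with motifs from
  the MYB dictionary overwritten at recorded positions (minus-strand
  plants insert the reverse complement), so every plant is recoverable
  verbatim.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import AnnotationMap
from .expression import ExpressionMatrix
from .motifs import DEFAULT_MOTIFS, MotifDictionary, MotifHit, PromoterSet, reverse_complement


@dataclass
class SyntheticConfig:
    n_genes: int = 100
    n_background_genes: int = 30
    module_sizes: tuple = (10, 15, 20, 25)
    anticorrelated_fraction: float = 0.1
    n_conditions: int = 10
    replicates_per_condition: int = 3
    within_module_correlation: float = 0.9
    noise_sd: float = 1.0
    deg_effect: float = 2.0
    n_deg_genes: int = 10
    annotation_coverage: float = 0.8
    n_noise_terms: int = 10
    promoter_length: int = 1000
    planted_motifs: tuple = ()  # (gene, motif_id, strand, 1-based position)
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    seed: int = 0

    def __post_init__(self):
        self.module_sizes = tuple(self.module_sizes)
        self.planted_motifs = tuple(tuple(p) for p in self.planted_motifs)
        self.base_composition = tuple(self.base_composition)
        if sum(self.module_sizes) + self.n_background_genes != self.n_genes:
            raise ValueError("sum(module_sizes) + n_background_genes must equal n_genes")
        if any(s < 3 for s in self.module_sizes):
            raise ValueError("module sizes < 3 are rejected (the downstream "
                             "cluster-size filter would always erase them)")
        if not 0 <= self.anticorrelated_fraction <= 1:
            raise ValueError("anticorrelated_fraction must be in [0, 1]")
        if not 0 < self.within_module_correlation < 1:
            raise ValueError("within_module_correlation must be in (0, 1)")
        if not 0 <= self.annotation_coverage <= 1:
            raise ValueError("annotation_coverage must be in [0, 1]")
        if abs(sum(self.base_composition) - 1.0) > 1e-9 or len(self.base_composition) != 4:
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        if self.n_deg_genes > self.n_background_genes:
            raise ValueError("n_deg_genes must not exceed n_background_genes "
                             "(effects are planted on background genes to keep "
                             "module structure clean)")


@dataclass
class SyntheticTruth:
    module_of_gene: dict = field(default_factory=dict)  # gene -> module id or None
    deg_genes: frozenset = frozenset()
    term_of_module: dict = field(default_factory=dict)
    planted_hits: list = field(default_factory=list)
    control_condition: str = ""
    treatment_condition: str = ""
    flipped_genes: frozenset = frozenset()

    def module_labels(self, genes) -> list:
        """Planted labels for a gene subset: module id, or -1 for background."""
        return [self.module_of_gene[g] if self.module_of_gene[g] is not None else -1
                for g in genes]


_BASELINE = 8.0  # typical log2 microarray intensity offset


def generate_expression(config: SyntheticConfig):
    """Latent-factor expression matrix plus the truth record.

    Returns ``(ExpressionMatrix, SyntheticTruth)``.
    """
    rng = np.random.default_rng([config.seed, 0])
    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    conditions = [f"cond{c:02d}" for c in range(1, config.n_conditions + 1)]
    samples, design_rows = [], []
    for c in conditions:
        for r in range(1, config.replicates_per_condition + 1):
            samples.append(f"{c}_r{r}")
            design_rows.append({"sample": f"{c}_r{r}", "condition": c, "replicate": r})
    n_samples = len(samples)

    target_r = config.within_module_correlation
    lam = config.noise_sd * np.sqrt(target_r / (1.0 - target_r))

    module_of = {}
    flipped = set()
    values = np.empty((config.n_genes, n_samples))
    cursor = 0
    for m, size in enumerate(config.module_sizes, start=1):
        z = rng.standard_normal(n_samples)
        n_flip = int(round(config.anticorrelated_fraction * size))
        for k in range(size):
            g_idx = cursor + k
            module_of[genes[g_idx]] = m
            sign = -1.0 if k >= size - n_flip else 1.0
            if sign < 0:
                flipped.add(genes[g_idx])
            noise = rng.standard_normal(n_samples) * config.noise_sd
            signal = sign * (lam * z if config.noise_sd > 0 else z)
            values[g_idx] = _BASELINE + signal + noise
        cursor += size
    background = genes[cursor:]
    for g_idx in range(cursor, config.n_genes):
        module_of[genes[g_idx]] = None
        values[g_idx] = _BASELINE + rng.standard_normal(n_samples) * config.noise_sd

    deg_genes = sorted(rng.choice(background, size=config.n_deg_genes, replace=False)) \
        if config.n_deg_genes else []
    treatment = conditions[-1]
    control = conditions[0]
    trt_cols = [i for i, s in enumerate(samples) if s.startswith(treatment)]
    gene_index = {g: i for i, g in enumerate(genes)}
    for g in deg_genes:
        values[gene_index[g], trt_cols] += config.deg_effect

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        design=pd.DataFrame(design_rows).set_index("sample"),
    )
    truth = SyntheticTruth(
        module_of_gene=module_of,
        deg_genes=frozenset(deg_genes),
        control_condition=control,
        treatment_condition=treatment,
        flipped_genes=frozenset(flipped),
    )
    return matrix, truth


def generate_annotations(truth: SyntheticTruth, config: SyntheticConfig) -> AnnotationMap:
    """One dedicated term per planted module plus uniform noise terms.

    The dedicated term of module m annotates ``annotation_coverage`` of its
    genes (rounded); noise terms annotate uniformly random gene sets.
    The universe is every generated gene.
    """
    if config.annotation_coverage * min(config.module_sizes) < 2:
        warnings.warn("annotation_coverage * smallest module < 2: enrichment "
                      "needs >= 2 annotated genes per module", stacklevel=2)
    rng = np.random.default_rng([config.seed, 1])
    universe = frozenset(truth.module_of_gene)
    modules: dict[int, list] = {}
    for g, m in truth.module_of_gene.items():
        if m is not None:
            modules.setdefault(m, []).append(g)
    terms: dict[str, frozenset] = {}
    for m in sorted(modules):
        members = sorted(modules[m])
        k = int(round(config.annotation_coverage * len(members)))
        term = f"TERM_M{m}"
        terms[term] = frozenset(rng.choice(members, size=k, replace=False))
        truth.term_of_module[m] = term
    all_genes = sorted(universe)
    for t in range(1, config.n_noise_terms + 1):
        size = int(rng.integers(5, max(6, min(21, len(all_genes)))))
        terms[f"NOISE_T{t:02d}"] = frozenset(rng.choice(all_genes, size=size, replace=False))
    return AnnotationMap(term_to_genes=terms, universe=universe)


def generate_promoters(truth: SyntheticTruth, config: SyntheticConfig,
                       dictionary: MotifDictionary = DEFAULT_MOTIFS):
    """iid promoters with motif plants overwritten at recorded coordinates.

    Returns ``(PromoterSet, truth)`` with ``truth.planted_hits`` updated.
    Overlapping plants on one gene and out-of-bounds positions are rejected.
    """
    rng = np.random.default_rng([config.seed, 2])
    L = config.promoter_length
    bases = np.array(list("ACGT"))
    seqs = {}
    for g in sorted(truth.module_of_gene):
        seqs[g] = "".join(rng.choice(bases, size=L, p=config.base_composition))
    occupied: dict[str, list] = {}
    for gene, motif_id, strand, pos in config.planted_motifs:
        if gene not in seqs:
            raise KeyError(f"planted gene {gene!r} unknown")
        if motif_id not in dictionary:
            raise KeyError(f"planted motif {motif_id!r} not in dictionary")
        consensus = dictionary[motif_id].consensus
        w = len(consensus)
        if not 1 <= pos <= L - w + 1:
            raise ValueError(f"plant position {pos} out of bounds for width {w}")
        span = (pos, pos + w - 1)
        for lo, hi in occupied.get(gene, []):
            if span[0] <= hi and lo <= span[1]:
                raise ValueError(f"overlapping plants on {gene}")
        occupied.setdefault(gene, []).append(span)
        insert = consensus if strand == "+" else reverse_complement(consensus)
        s = seqs[gene]
        seqs[gene] = s[: pos - 1] + insert + s[pos - 1 + w:]
        truth.planted_hits.append(
            MotifHit(gene, motif_id, strand, pos, dictionary[motif_id].category))
    return PromoterSet(sequences=seqs, length=L), truth


def generate_all(config: SyntheticConfig):
    """Expression + truth + annotations + promoters in one call."""
    matrix, truth = generate_expression(config)
    annotations = generate_annotations(truth, config)
    promoters, truth = generate_promoters(truth, config)
    return matrix, annotations, promoters, truth
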