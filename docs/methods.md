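# Methods

## Scope and model

`mybnet` analyses a genes × samples matrix of log2 expression values (the
object a microarray workflow produces after RMA-style normalisation; the
package does not normalise). Two pipelines share the correlation layer:

1. **Top-down.** Probe-level rows are collapsed to genes by unweighted
   per-sample averaging. The all-vs-all Pearson correlation matrix is
   thresholded at |r| > τ (strict inequality; τ = 0.85 by default) into a
   signed network, clustered with Markov Clustering over an inflation grid,
   and each partition is scored by the GO-enrichment F-measure; hubs are
   nodes of degree ≥ 5.
2. **Guide-gene.** From user-chosen guide genes, a network is grown
   breadth-first along edges satisfying mutual rank MR ≤ 5 and r ≥ 0.6 up
   to depth 2; first-neighbour promoters are scanned against a MYB
   binding-site dictionary and neighbours with ≥ 1 hit become putative
   targets.

## Parameters that matter

| parameter | default | units / range | why |
|---|---|---|---|
| `pcc_cutoff` τ | 0.85 | \|r\| | stringent edge retention; strict `>` by convention, `>=` available |
| MCL inflation I | swept 1.1–3.0, step 0.1 | — | granularity control; argmax-F kept, ties to smallest I |
| `min_cluster_size` | 3 | genes | smaller clusters are rarely interpretable and cannot be enriched (k ≥ 2 rule) |
| `self_loop_weight` | 1.0 | \|r\| units | canonical MCL regularisation; damps parity oscillations |
| `prune_threshold` | 1e−6 | probability | sparsity control inside MCL |
| enrichment FDR | 0.05 | BH-adjusted P | joint BH over all (module, term) tests of one partition |
| `min_hub_degree` | 5 | edges | hub definition |
| `mr_max`, `pcc_min` | 5, 0.6 | MR, r | guide-expansion admission; both inclusive |
| `hierarchy_depth` | 2 | levels | guide expansion radius |
| DEG thresholds | \|log2 FC\| ≥ 1.5, adj. P < 0.05 | log2 units | fold-change read on the log2 scale |
| `proximal_window` | 200 | bp | hits within 200 bp of the promoter 3' end count as proximal |

## Numerical and design choices

* **Correlation.** Computed on log2 values; genes with zero variance are
  excluded up front rather than yielding undefined r. The matrix is
  symmetrised and clipped to [−1, 1] against floating-point drift.
* **MCL weights.** MCL requires non-negative weights, so edges enter as
  |r|; the sign lives on the network edge and resurfaces in hub summaries
  and target tables. Cluster read-off: attractor rows' support, with a gene
  claimed by several attractors assigned to the lowest-indexed one; a
  non-converged run (beyond 200 iterations) is interpreted as-is and
  flagged. Partitions retaining < 2 modules are unusable and score F = 0.
* **Modularity.** Newman–Girvan Q on the unweighted simple graph via
  networkx, with unassigned genes as singleton communities.
* **Mutual ranks.** rank_a(b) orders genes by decreasing r(a, ·) with ties
  broken lexicographically by gene id, so results are deterministic.
* **DEG test.** Pooled two-sample Student t rather than Welch: with 2–3
  replicates per group Welch's estimated degrees of freedom are unstable
  (anywhere between 2 and 4) and cost substantial power at fixed effect
  size, while the pooled test has known df = n₁ + n₂ − 2. Genes with zero
  variance in both groups are untestable and flagged, never called DE.
* **Enrichment.** Upper-tail hypergeometric P(X ≥ k); terms with k = 0 in a
  module are not tested (their P is 1 and they only dilute BH). A call
  additionally requires k ≥ 2 annotated genes. BH replaces the
  service-specific correction a web tool would apply. Terms are opaque
  labels — no ontology propagation; users of real GO data should
  pre-propagate annotations.
* **Scale-free fit.** OLS of log10 frequency on log10 degree over the raw
  observed degree spectrum (no binning, no cumulative transform); undefined
  (NaN) below 3 distinct degrees.
* **Motif scanning.** Exact string matching of concrete consensus elements
  (no IUPAC wildcards or PWMs), both strands, overlapping occurrences all
  reported, `N` never matches. Positions are 1-based at the hit's leftmost
  base within the promoter string; a BED-style export (0-based, half-open)
  is clearly separate. A palindromic motif is reported once per position on
  the plus strand (none of the six defaults are palindromic). Dictionary
  enrichment uses a per-position Bernoulli/binomial null under the pooled
  observed base composition — a deliberate, analytically transparent
  alternative to de novo discovery.
* **Proximal/distal.** The promoter 3' end (immediately upstream of the
  translational start) anchors the classification, serving as the TSS
  proxy when true TSS annotation is absent.
* **Guide thresholds.** MR ≤ 5 and r ≥ 0.6 are the defaults; both are
  configurable (e.g. MR < 10 with r > 0.64 reproduces a looser published
  variant of the same procedure). A gene reachable at several depths keeps
  its minimal level, which determines first-neighbour target eligibility.

## The synthetic generator

Genes of module m share one latent standard-normal sample profile z_m:
x_g = s_g·λ·z_m + ε, ε ~ N(0, σ²), with λ = σ·√(r/(1−r)) so the expected
within-module correlation equals the target r (default 0.9); s_g = −1 for
an `anticorrelated_fraction` (default 0.1) of members, producing planted
negative edges. Background genes are pure noise. Defaults — 4 modules of
10/15/20/25 genes plus 30 background genes, 10 conditions × 3 replicates
(30 samples), σ = 1 — give a network in which the 0.85 cutoff keeps most
module genes and essentially no background gene, so module recovery is
demanding but achievable. Differential expression adds `deg_effect`
(default 2.0) log2 units to `n_deg_genes` background genes in the last
condition. Annotations give each module a dedicated term covering 80% of
its genes plus 10 uniform noise terms (making the inflation sweep
non-trivial: a perfect partition scores F < 1 because noise terms stay
unenriched). Promoters are 1000 bp iid sequences from a configurable base
composition with motifs overwritten (not inserted) at recorded positions,
keeping length fixed; minus-strand plants insert the reverse complement.
All randomness flows from one integer seed through independent
sub-streams; identical configs are bit-identical.

What the generator does **not** emulate: probe-level array structure, batch
effects, heteroscedastic intensity-dependent noise, correlated background
genes, realistic GO term hierarchies, or promoter sequence composition
biases beyond a global base frequency. Passing tests therefore demonstrate
algorithmic correctness and calibration under the stated model, not
performance on real compendia.

## Problem sizes

The test suite and the reproduction script run the full inflation sweep on
50 simulated 100-gene datasets, DEG calibration on 100 simulated 200-gene
datasets, MCL cross-checks on 30 random graphs of up to 60 nodes, and
exhaustive hypergeometric enumeration up to a 25-gene universe — sizes at
which every check is exact or tightly calibrated while the whole suite
completes in well under a minute.

## Known limitations

* MCL here is dense-matrix; fine for the few-hundred-node networks this
  package targets, not for genome-scale graphs.
* The F-measure compares partitions at fixed annotations; it cannot rank
  partitions when no term is enrichable (all scores 0).
* Negative co-expression contributes |r| to clustering, i.e. strongly
  anti-correlated genes may cluster together by design.
* Promoter scanning is presence/absence; no affinity model.
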