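# mybnet

Co-expression and co-regulatory network analysis for plant MYB transcription
factors (and, with suitable inputs, any gene family), built around two
complementary strategies:

* **Top-down**: an all-vs-all signed Pearson correlation network over a
  genes × samples log2 expression matrix, module detection by Markov
  Clustering (MCL) with the inflation parameter tuned by a GO-enrichment
  F-measure, and degree-based hub calling.
* **Guide-gene**: breadth-first expansion from functionally characterised
  guide genes under mutual-rank and correlation thresholds, followed by
  promoter scanning against a MYB binding-site dictionary to nominate
  putative target genes (with special attention to the drought-inducibility
  MBS hexamers CAACTG and TAACTG).

Because real compendia (GEO microarray series, co-expression databases) need
downloads, the package ships a fully seeded synthetic-data generator that
plants known modules, differential-expression effects, annotation terms and
promoter motifs, so every stage is testable against ground truth.

## The statistics at the core

* Signed network: edge (a, b) retained iff |r(a, b)| > τ (default τ = 0.85),
  where r is the Pearson correlation of log2 profiles across samples; the
  sign of r is kept. Diagnostics over a τ grid report N, E, density
  2E/(N(N−1)) and the scale-free fit R² of log10 f(k) on log10 k.
* MCL: alternating expansion (M ← M²) and inflation (entrywise power I,
  column renormalisation) on the column-stochastic |r|-weighted adjacency
  with unit self-loops; clusters with < 3 genes are set aside.
* Partition score: specificity = fraction of modules with ≥ 1 enriched term,
  sensitivity = fraction of terms enriched in ≥ 1 module, at BH-FDR < 0.05
  with ≥ 2 annotated genes per call (hypergeometric upper-tail P);
  F = 2·spec·sens/(spec + sens). The sweep I ∈ {1.1, …, 3.0} keeps the
  argmax-F partition.
* Mutual rank: MR(a, b) = √(rank_a(b)·rank_b(a)); guide expansion admits a
  neighbour when MR ≤ 5 and r ≥ 0.6, to a hierarchy depth of 2.
* Hubs: degree ≥ 5 in the thresholded network.
* Differential expression: pooled two-sample t-test, BH adjustment,
  |log2 FC| ≥ 1.5 and adjusted P < 0.05.

## Worked example

```bash
mybnet simulate --seed 7 --outdir sim
printf 'g0001\ng0002\n' > sim/guides.txt
mybnet topdown --expression sim/expression.tsv --design sim/design.tsv \
    --annotations sim/annotations.tsv --outdir out_td
mybnet guidegene --expression sim/expression.tsv \
    --promoters sim/promoters.fasta --guides sim/guides.txt --outdir out_gg
```

`topdown` prints (seed 7):

```
n_nodes	70
n_edges	605
density	0.2505175983436853
best_inflation	1.1
n_modules	4
modularity	0.6406994057782939
f_measure	0.4444444444444445
n_hubs	69
```

and `guidegene` prints:

```
n_nodes	9
n_first_neighbors	5
n_putative_targets	3
n_drought_mbs_targets	3
drought_mbs_proximal_fraction	0.16666666666666666
drought_mbs_distal_fraction	0.8333333333333334
```

All four planted modules are recovered from the 70 genes that survive the
0.85 cutoff (the generator plants 4 modules in 100 genes); every module is
enriched for its dedicated term (specificity 1.0) while the 10 planted noise
terms stay unenriched (sensitivity 4/14), giving F = 0.44. The guide-gene
run expands the two guides into a 9-gene network whose 5 first neighbours
include 3 with at least one MYB binding site in their promoter (all 3 with a
drought-MBS hexamer); most drought-MBS hits sit distal to the promoter
3' end. Per-stage tables (edge lists, module membership, enrichment, hubs,
putative-target rows, motif hits) are written to the output directory
together with a run manifest.

The same functionality is available as a library:

```python
import mybnet as m
cfg = m.SyntheticConfig(seed=7)
matrix, annotations, promoters, truth = m.generate_all(cfg)
corr = m.pearson_all_pairs(matrix)
net = m.build_network(corr, 0.85)
best, table = m.inflation_sweep(net, annotations)
```

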