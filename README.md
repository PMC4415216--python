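# pathpanel

Design, validate, and apply **pathway reporter gene panels** — compact gene
sets whose expression indexes the activity of a catalog of signaling and
metabolic pathways ("molecular phenotyping"). Instead of profiling the whole
transcriptome, a few hundred well-chosen regulators and transcriptional
targets are quantified by targeted RNA counting and turned into per-pathway
activity read-outs.

The package is aimed at computational biologists who need (a) a reproducible
pipeline for selecting reporter genes from heterogeneous pathway knowledge,
and (b) the downstream statistics for reading pathway activity out of the
resulting count matrices.

## What it computes

**Panel design** runs in four stages over a knowledge base:

1. *Harmonization* — pathway–gene associations from multiple sources (GMT
   files) are merged into one bipartite graph; a directed transcriptional
   regulatory network (TSV edge list) is read alongside.
2. *Prioritization* — genes are ranked by PageRank centrality on the
   regulatory network: the stationary distribution of a damped random walk,
   π = d·Pᵀπ + (1−d)/n, with damping d = 0.85. Directed, reversed, and
   undirected walk modes are supported.
3. *Redundancy filtering* — gene pairs sharing significantly more pathways
   than a degree-preserving edge-swap null of the bipartite graph
   (empirical p = (1 + #{null ≥ observed}) / (1 + N), raw p < 0.05) are
   collapsed by removing the lower-centrality member; co-expression clusters
   (pairwise r > 0.90) are collapsed to their highest-centrality
   representative.
4. *Selection* — the top 20% of the remaining ranking is taken (capped at the
   assay capacity, default 1,200), with a per-gene audit trail.

**In-silico validation** compares the panel against random same-size gene
sets: one-sided Fisher enrichment of annotation terms with
Benjamini–Hochberg control, per-gene disease-association density with a
two-sample Kolmogorov–Smirnov test, PageRank medians on an independent
regulatory network, and interaction coverage with bootstrap percentile
intervals.

**Molecular phenotyping** converts a reporter count matrix to log₂ counts
per million, scores each pathway per sample by a mean-rank z statistic

    z = (R̄ − (G+1)/2) / √((G+1)(G−m) / (12 m))

(the mean rank of the pathway's m reporters among all G profiled genes,
standardized by its exact null variance), orders pathways by peak time,
tests per-pathway regulation with a one-sided Fisher test, and fits per-gene
polynomial (linear + quadratic) OLS trend tests over time or dose.

A synthetic-data module generates complete knowledge bases and
negative-binomial count matrices with planted hubs, redundant gene pairs,
co-expression clusters, enriched annotation terms, disease-dense genes, and
per-condition pathway activation, so the entire pipeline is testable without
external databases.

## Worked example

```python
import pathpanel as pp

kb = pp.simulate_knowledge_base(seed=7)          # 1,000 genes, 154 pathways, 50 hubs
result = pp.design_panel(
    kb.associations, kb.network,
    correlations=kb.correlations,
    n_permutations=1000, seed=7,
)
panel = result.panel
hubs = set(kb.truth.hub_genes)
print(f"panel size:          {len(panel)}")
print(f"redundant pairs:     {len(result.pairs)}")
print(f"hub recovery:        {100 * len(hubs & panel.gene_set) / len(hubs):.0f}%")

coverage = pp.pathway_coverage(panel, kb.associations)
print(f"uncovered pathways:  {len(coverage.uncovered_pathways)}")

independent = pp.simulate_regulatory_network(
    sorted(kb.associations.genes), sorted(hubs), seed=99
)
check = pp.centrality_crosscheck(sorted(panel.gene_set), independent)
print(f"median PageRank:     panel {check.median_panel:.1e} vs background {check.median_background:.1e}")
```

prints

```
panel size:          67
redundant pairs:     1686
hub recovery:        100%
uncovered pathways:  0
median PageRank:     panel 3.4e-03 vs background 7.1e-04
```

The 67-gene panel (top 20% of the non-redundant ranking) contains all 50
planted hub regulators, keeps at least one reporter for every one of the 154
pathways, and its genes remain ~5× more central than background on a
regulatory network regenerated independently of the one used for selection —
the hallmark behaviors of a sound reporter selection.

The same workflow is available from the shell:

```sh
pathpanel simulate --preset standard --seed 7 --outdir fixtures/
pathpanel build-panel --config pipeline.yaml --outdir run/
pathpanel score --counts counts.tsv --gmt panel_sets.gmt --meta meta.tsv --out scores.tsv
```

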