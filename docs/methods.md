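# Methods

This note documents the models, statistics, and design decisions behind
`pathpanel`: what each stage assumes, which parameters matter, and what the
synthetic data do and do not establish.

## Knowledge model

Pathway–gene associations form a bipartite graph: edges connect pathway
nodes to gene nodes only, each carrying a role (`regulator`, `target`, or
`unspecified`) and a provenance set of source labels. Harmonization is a
union: identical (pathway, gene, role) triples merge provenance, and
conflicting roles for the same pair are deliberately both retained — the
pipeline does not adjudicate between curated sources. Gene identifiers live
in a single symbol-like namespace; any cross-source identifier mapping is a
user-supplied two-column table applied at read time. Associations carry no
cell-type or tissue context by design: a reporter panel is meant to be
usable across biological systems.

The transcriptional regulatory network is a separate directed gene-only
graph (source regulates target). Self-loops are rejected at read time unless
explicitly permitted.

## PageRank prioritization

Gene importance is the stationary distribution of a damped random walk:
with probability d the walker follows a uniformly chosen out-edge, with
probability 1−d it teleports uniformly. Defaults: d = 0.85, L1 residual
tolerance 1e-10, at most 1,000 power iterations; dangling nodes redistribute
their mass uniformly; multi-edges collapse before iteration (unweighted
walk). Non-convergence raises an error carrying the last residual.

Because curated edge direction conventions vary, three modes are exposed:
`directed` (importance flows to regulatory targets), `reversed` (rewards
upstream regulators), and `undirected` (the network skeleton). The default
is `undirected`: it is the least committal reading of "the network's
backbone" and ranks genes by their embeddedness regardless of which
direction the curation happened to record. All results in the test-suite
use this default; the other modes are one flag away.

When the pipeline ranks a knowledge base whose genes are not all present in
the regulatory network, the missing genes receive centrality 0 — they rank
below every network gene but still pass through the redundancy filters and
appear in the audit trail.

## Redundancy filtering

Two genes associated with essentially the same pathways are informationally
redundant. The filter tests, for every gene pair sharing at least one
pathway, whether the shared-pathway count exceeds what a degree-preserving
null predicts. The null is an edge-swap Markov chain on the bipartite graph:
a swap picks two edges (g₁,p₁), (g₂,p₂) and rewires to (g₁,p₂), (g₂,p₁)
unless a duplicate edge would result, preserving both the gene and the
pathway degree sequences. After a burn-in of 10·k·E attempted swaps
(E = edge count, k = 3 by default), N states are sampled every k·E attempts
and the empirical p-value uses the add-one estimator
p = (1 + #{null ≥ observed}) / (1 + N).

Properties worth knowing:

* The p-value is **valid but conservative**: the shared-pathway count is a
  small discrete statistic, so P(p ≤ q) ≤ q holds over the set of all gene
  pairs (pairs sharing nothing have p = 1 by construction) with equality
  only at attainable levels. Over the *tested* subset (≥ 1 shared pathway)
  the ratio P(p ≤ q)/q can exceed 1 at small q — any calibration check must
  use the all-pairs reference set.
* Selection uses raw p < 0.05 with **no multiplicity adjustment**; this is
  the pipeline's operating rule, and it means the number of flagged pairs
  grows linearly with the number of pairs that share pathways by chance.
  With ~1,000 genes of membership degree ~4 over ~150 pathways, on the order
  of a thousand pairs are flagged, most of them chance sharers; because each
  flag removes only the lower-centrality member and already-removed genes
  skip subsequent pairs, the net effect is a broad pruning of low-centrality
  genes that the top of the ranking survives.
* Flagged pairs are resolved in ascending p (ties by pair key) so the
  strongest redundancies are honored first; centrality ties remove the
  lexicographically later gene. Fixing the seed fixes the output exactly.

Co-expression deduplication builds clusters as connected components of the
graph with edges where r > 0.90 (strictly; positive correlations only — an
anti-correlated gene pair is informative, not redundant) and keeps exactly
the highest-centrality member of each cluster.

## Panel selection

The top ⌈fraction · n⌉ genes of the non-redundant ranking (fraction 0.20 by
default) are truncated to the assay capacity (`max_size` 1,200) and an
exclusion list is removed afterwards **without backfilling**, mirroring how
vendor-rejected assays shrink a designed panel. Every candidate gene ends in
exactly one terminal audit state: `selected`, `pruned-redundant`,
`pruned-coexpression`, `below-cutoff`, or `excluded`.

## Validation statistics

* **Enrichment** — per annotation term, the one-sided (greater)
  hypergeometric tail of the 2×2 overlap table, restricted to
  experimentally evidenced annotations; Benjamini–Hochberg (step-up,
  implemented in-package) across terms. The universe defaults to all genes
  with at least one experimental annotation united with the panel.
* **Disease density** — the panel's per-gene disease-association counts
  against counts pooled over random same-size gene sets, two-sample
  Kolmogorov–Smirnov with the asymptotic p (sample sizes are hundreds or
  more); the mean-count ratio is reported alongside.
* **Centrality cross-check** — median PageRank of panel genes versus all
  other genes on a regulatory network *not used* for selection.
* **Interaction coverage** — fractions of network edges with a panel gene
  as source, as target, and as either endpoint ("involved" counts each edge
  once, so it is at most the source+target sum). The baseline is the
  2.5/97.5 percentile interval of involved fractions over random node sets
  of the panel's size (500 resamples by default). For a uniform random set
  of size s on n nodes the expected involved fraction is
  1 − (n−s)(n−s−1)/(n(n−1)).

## Phenotyping

Counts become log₂ counts-per-million with a 0.5 pseudocount and a +1
library-size offset: log₂((c+0.5)/(L+1)·10⁶). The transform is strictly
monotone within a sample; the pseudocount perturbs a depth-doubling by
roughly 0.5/(2·ln2·(c+0.5)) — below 0.01 once c ≥ 40.

The single-sample pathway activity score is a mean-rank z statistic: rank
all G profiled genes within the sample (ties averaged), take the mean rank
R̄ of the pathway's m reporters, and standardize by the exact null moments
of a mean of m ranks drawn without replacement from 1..G:

    z = (R̄ − (G+1)/2) / sqrt((G+1)(G−m)/(12m)).

This score is rank-based (invariant under any strictly monotone per-sample
transform), sign-interpretable (positive = reporters above the panel
average), and standardized under exchangeability. It is *not* the GSVA
kernel estimator: scores are comparable in distribution but not numerically
equal to GSVA's. Scores are computed per sample and averaged within
condition for display; heat-map style summaries row-z-score each pathway
(sample variance, ddof = 1; constant rows become zeros with a warning) and
sort pathways by the time point of maximal score, labeling first-peak /
interior-peak / last-peak profiles (the stem-cell / switch / lineage-specific
analogy).

The trend test is per-gene OLS on an orthonormalized polynomial basis of the
covariate: a joint F-test of the linear and quadratic contrasts (degree 2,
the default for time courses and dose series) or a two-sided t-test on the
slope (degree 1). Zero-variance genes get coefficient 0 and p = 1 by
convention; BH is applied across genes; direction is the sign of the linear
contrast. Differential expression calls combine BH-adjusted p < 0.05 with
|log₂ fold-change| ≥ 1, where the fold-change is the mean at the highest
covariate level minus the mean at the lowest. The per-pathway regulation
test is a one-sided Fisher test of DE-reporter overlap with the panel as
universe.

## Synthetic data: what it emulates and what it does not

The generator produces all pipeline inputs with planted truth, one RNG
stream per artifact derived from the master seed (network, associations,
annotations, diseases, correlations, counts), so any artifact can be
regenerated independently and byte-identically.

Default study conditions: 1,000 genes, a 154-pathway catalog, 50 hub genes
(5%), five cloned redundant pairs sharing six pathways, five co-expression
clusters of three genes (r in 0.92–0.99 against a background of |r| ≤ 0.85),
ten hub-enriched annotation terms among fifty (hit probability 0.6 on hubs
vs 0.02 background; 15% of rows carry a non-experimental evidence code to
exercise the filter), and 200 disease-dense genes at a three-fold Poisson
excess (mean 6 vs 2).

Two structural choices deserve emphasis:

* **Background membership degree is fixed at 4.** With four memberships
  over 154 pathways, a single chance shared pathway between background genes
  has null tail probability ~0.10 — unremarkable at the 0.05 rule — while
  cloned pairs sharing six pathways are detected at the permutation floor.
  Heavier or more variable membership noise shifts entire classes of gene
  pairs into the discrete rejection region of the raw-p rule and floods the
  filter with chance flags; the fixed degree keeps the planted truth
  self-consistent with the pipeline's stated operating rule.
* **Hub memberships use a bounded-overlap design** (six memberships each,
  pairwise intersection ≤ 1, jointly covering all pathways via
  least-covered-first assignment). Planted hubs model *distinct* pathway
  regulators; unconstrained random membership would plant hub pairs that
  genuinely share several pathways, which the redundancy filter would then
  correctly remove — the planted truth would contradict itself.

The regulatory network grows by preferential attachment (targets drawn
proportionally to in-degree + 1); non-hub genes emit 1 + Poisson(1) edges,
hubs emit 20 + Poisson(3), keeping hub out-degree at least five times the
background median.

Counts are negative-binomial with log-normal baseline abundances
(log₂ mean 6, sd 1.5), library sizes uniform in 0.8–1.2 million, and
dispersion 0.04 — a biological coefficient of variation of 0.2, the
standard working figure for replicate cultured-cell RNA counting.
Activated pathways shift member-gene means by per-condition log₂
fold-changes (summed over pathways for shared genes); planted profiles
include tri-phasic time courses (early / transient / late, peak log₂FC 1.5
over four time points) and single-pathway dose responses (log₂FC
proportional to dose, 2.0 at the top dose).

What passing tests on these data show: the pipeline recovers planted
structure — hubs, redundancy, coverage, enrichment, disease density,
activation patterns — under a generative model whose assumptions match the
methods' own (exchangeable ranks, NB counts, degree-preserving bipartite
null). What they do not show: robustness to curation biases of real pathway
databases, correlated annotation structure, batch effects, donor
variability beyond what NB dispersion absorbs, or the behavior of the raw
p < 0.05 redundancy rule on bipartite graphs much denser than the
conditions above.

## Numerical notes

* PageRank iterates to an L1 residual below 1e-10 and renormalizes the sum
  to 1 to remove float drift; scores agree with a dense-matrix oracle to
  1e-8 on graphs of ≤ 50 nodes.
* BH adjustment is the exact step-up with a final cap at 1, restoring
  input order.
* The trend test is vectorized closed-form OLS across genes (QR-orthonormal
  basis), numerically identical to per-gene regression fits to ~1e-10 in p.
* Problem sizes in the test-suite and acceptance script (1,000 permutations,
  20–50 simulation replicates, 5,000-gene null panels) are chosen so the
  whole suite completes in a few minutes on a single core while keeping
  Monte-Carlo error well inside each asserted margin.
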