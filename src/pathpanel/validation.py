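"""In-silico validation of a reporter panel.

A well-chosen panel should (a) be enriched for annotated biological-process
effectors relative to random gene sets of the same size, (b) carry more
disease associations per gene than random sets, (c) rank centrally in an
*independent* regulatory network that was not used to build it, and (d) sit
on a disproportionate share of the annotated gene-gene interactions.  The
operations here compute each of those statistics together with random-set
baselines and bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import pagerank
from .knowledge import AnnotationTable, DiseaseTable, RegulatoryNetwork


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # step-up: enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-term 2x2 overlap counts with one-sided Fisher p and BH q."""

    frame: pd.DataFrame
    # columns: term, set_in_term, set_not_term, universe_in_term_not_set,
    #          remainder, odds_ratio, p, q
    universe_size: int

    def significant_terms(self, alpha: float = 0.05) -> list[str]:
        return self.frame.loc[self.frame["q"] < alpha, "term"].tolist()


def fisher_enrichment(
    gene_set: set[str] | frozenset[str],
    annotations: AnnotationTable,
    universe: set[str] | frozenset[str],
    experimental_only: bool = True,
) -> EnrichmentTable:
    """One-sided (greater) Fisher's exact test of term overrepresentation.

    For each term with annotated genes in the universe, the 2x2 table of
    (in set / not in set) x (in term / not in term) is tested with the
    hypergeometric upper tail; BH adjustment is applied across all tested
    terms.  By default only experimentally evidenced annotations count.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    gene_set = frozenset(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    table = annotations.experimental_only() if experimental_only else annotations
    n_univ = len(universe)
    n_set = len(gene_set)
    rows = []
    for term, genes in sorted(table.term_to_genes().items()):
        term_genes = genes & universe
        k = len(term_genes)
        x = len(term_genes & gene_set)
        # one-sided p = P[overlap >= x] under Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(x - 1, n_univ, k, n_set))
        a = x
        b = n_set - x
        c = k - x
        d = n_univ - n_set - c
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append(
            {
                "term": term,
                "set_in_term": a,
                "set_not_term": b,
                "universe_in_term_not_set": c,
                "remainder": d,
                "odds_ratio": odds,
                "p": min(p, 1.0),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "term", "set_in_term", "set_not_term", "universe_in_term_not_set",
            "remainder", "odds_ratio", "p",
        ],
    )
    frame["q"] = bh_adjust(frame["p"].to_numpy()) if len(frame) else []
    return EnrichmentTable(frame=frame, universe_size=n_univ)


def significant_term_count(table: EnrichmentTable, alpha: float = 0.05) -> int:
    """Number of terms with BH-adjusted p below alpha."""
    if len(table.frame) == 0:
        return 0
    return int((table.frame["q"] < alpha).sum())


@dataclass(frozen=True)
class BaselineDistribution:
    """Statistic values over random same-size gene sets."""

    values: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    seed: int

    @property
    def median(self) -> float:
        return float(np.median(self.values))


def random_set_baseline(
    universe: Sequence[str],
    size: int,
    n_sets: int,
    statistic: Callable[[frozenset[str]], float],
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> BaselineDistribution:
    """Evaluate a statistic over ``n_sets`` uniform without-replacement draws
    of ``size`` genes from the universe; percentile CI of the distribution."""
    universe = sorted(set(universe))
    if size > len(universe):
        raise ValueError(f"size {size} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(seed)
    values = np.empty(n_sets)
    arr = np.array(universe, dtype=object)
    for i in range(n_sets):
        draw = frozenset(rng.choice(arr, size=size, replace=False).tolist())
        values[i] = statistic(draw)
    lo, hi = np.percentile(values, ci)
    return BaselineDistribution(
        values=values, mean=float(values.mean()), ci_low=float(lo), ci_high=float(hi),
        seed=seed,
    )


@dataclass(frozen=True)
class DiseaseDensityResult:
    panel_counts: np.ndarray
    baseline_counts: np.ndarray
    ks_statistic: float
    ks_p: float
    mean_ratio: float


def disease_density_comparison(
    panel_genes: Sequence[str],
    diseases: DiseaseTable,
    n_random: int = 1000,
    seed: int = 0,
    universe: Sequence[str] | None = None,
) -> DiseaseDensityResult:
    """Compare the panel's per-gene disease-association counts with those of
    random same-size gene sets (counts pooled over all random sets), by a
    two-sample Kolmogorov-Smirnov test (asymptotic p).

    The sampling universe defaults to all genes in the disease table united
    with the panel.  Genes without any recorded association count zero.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    panel_genes = sorted(set(panel_genes))
    if universe is None:
        universe = sorted(diseases.genes | set(panel_genes))
    else:
        universe = sorted(set(universe))
    count_map = diseases.counts_per_gene(universe)
    counts_arr = count_map.to_numpy()
    rng = np.random.default_rng(seed)
    size = len(panel_genes)
    n_univ = len(universe)
    draws = np.empty((n_random, size), dtype=np.int64)
    for i in range(n_random):
        draws[i] = rng.choice(n_univ, size=size, replace=False)
    baseline = counts_arr[draws].ravel()
    panel_counts = diseases.counts_per_gene(panel_genes).to_numpy()
    res = stats.ks_2samp(panel_counts, baseline, method="asymp")
    ks_stat, ks_p = float(res.statistic), float(res.pvalue)
    base_mean = baseline.mean()
    ratio = float(panel_counts.mean() / base_mean) if base_mean > 0 else np.inf
    return DiseaseDensityResult(
        panel_counts=panel_counts,
        baseline_counts=baseline,
        ks_statistic=ks_stat,
        ks_p=ks_p,
        mean_ratio=ratio,
    )


@dataclass(frozen=True)
class CrosscheckResult:
    median_panel: float
    median_background: float
    ratio: float


def centrality_crosscheck(
    panel_genes: Sequence[str],
    independent_network: RegulatoryNetwork,
    mode: str = "undirected",
    damping: float = 0.85,
) -> CrosscheckResult:
    """Median PageRank of panel genes vs. all other genes on a regulatory
    network that was not used for panel construction."""
    scores = pagerank(independent_network, mode=mode, damping=damping)
    panel_set = set(panel_genes)
    in_panel = scores.scores[scores.scores.index.isin(panel_set)]
    background = scores.scores[~scores.scores.index.isin(panel_set)]
    if len(background) == 0:
        raise ValueError("panel covers every network node; background median undefined")
    if len(in_panel) == 0:
        raise ValueError("no panel gene occurs in the independent network")
    mp = float(in_panel.median())
    mb = float(background.median())
    return CrosscheckResult(median_panel=mp, median_background=mb, ratio=mp / mb)


@dataclass(frozen=True)
class CoverageReport:
    """Interaction-level coverage of a gene set on a regulatory network."""

    upstream_fraction: float  # edges whose source is a panel gene
    downstream_fraction: float  # edges whose target is a panel gene
    involved_fraction: float  # edges with either endpoint in the panel
    n_source_genes: int
    n_target_genes: int
    n_edges: int
    baseline_mean: float
    baseline_ci: tuple[float, float]
    n_boot: int


def interaction_coverage(
    panel_genes: Sequence[str],
    network: RegulatoryNetwork,
    n_boot: int = 500,
    seed: int = 0,
) -> CoverageReport:
    """Fractions of regulatory interactions with a panel gene as source,
    target, or either endpoint, plus a random-set percentile baseline.

    The baseline draws ``n_boot`` gene sets of the panel's size (restricted
    to genes occurring in the network) uniformly from the network's nodes and
    reports the mean and 2.5/97.5 percentile interval of their involved
    fractions.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    pairs = network.edge_pairs()
    n_edges = len(pairs)
    if n_edges == 0:
        raise ValueError("network has no edges")
    panel_set = set(panel_genes)
    src = np.array([s for s, _ in pairs], dtype=object)
    tgt = np.array([t for _, t in pairs], dtype=object)
    in_src = np.fromiter((s in panel_set for s in src), bool, n_edges)
    in_tgt = np.fromiter((t in panel_set for t in tgt), bool, n_edges)
    upstream = in_src.mean()
    downstream = in_tgt.mean()
    involved = (in_src | in_tgt).mean()

    nodes = sorted(network.nodes)
    node_idx = {g: i for i, g in enumerate(nodes)}
    si = np.array([node_idx[s] for s in src])
    ti = np.array([node_idx[t] for t in tgt])
    size = min(len(panel_set), len(nodes))
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        member = np.zeros(len(nodes), dtype=bool)
        member[rng.choice(len(nodes), size=size, replace=False)] = True
        boot[b] = (member[si] | member[ti]).mean()
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return CoverageReport(
        upstream_fraction=float(upstream),
        downstream_fraction=float(downstream),
        involved_fraction=float(involved),
        n_source_genes=len(panel_set & set(src.tolist())),
        n_target_genes=len(panel_set & set(tgt.tolist())),
        n_edges=n_edges,
        baseline_mean=float(boot.mean()),
        baseline_ci=(float(lo), float(hi)),
        n_boot=n_boot,
    )
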