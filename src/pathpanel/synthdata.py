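"""Synthetic knowledge bases and expression data with planted ground truth.

The pipeline's real inputs (curated pathway-gene associations, a proprietary
regulatory network, co-expression snapshots, annotation and disease tables,
targeted RNA count matrices) are emulated here so every stage is testable
end-to-end.  All planted structure is recorded in :class:`SyntheticTruth`:

* **hub genes** — designated regulators with high out-degree in the
  regulatory network and broad pathway membership;
* **redundant pairs** — non-hub gene pairs cloned to identical pathway
  membership (the redundancy filter should collapse them);
* **co-expression clusters** — gene groups with pairwise correlation above
  the dedup threshold;
* **enriched terms** — annotation terms concentrated on hub genes;
* **high-disease genes** — genes carrying a k-fold excess of disease
  associations;
* **activation profiles** — per-condition log2 fold-changes of pathway
  member genes in simulated count matrices.

Hub pathway memberships use a bounded-overlap design (any two hubs share at
most ``hub_max_overlap`` pathways): planted hubs model *distinct* pathway
regulators, which by construction must not be informationally redundant with
one another — unconstrained random membership would plant hub pairs that the
redundancy filter is then right to remove, contradicting the planted truth.

One RNG stream per artifact (network / associations / annotations / diseases
/ correlations / counts) is derived from the master seed, so components can
be regenerated independently and byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .knowledge import (
    AnnotationTable,
    AssociationEdge,
    DiseaseTable,
    PathwayGeneAssociations,
    RegulatoryNetwork,
)

_STREAMS = ("network", "assoc", "annotations", "diseases", "correlations", "counts")


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic knowledge base."""

    hub_genes: list[str]
    redundant_pairs: list[tuple[str, str]]
    coexpression_clusters: list[list[str]]
    enriched_terms: list[str]
    high_disease_genes: list[str]
    activation_profiles: dict[str, dict[str, float]] = field(default_factory=dict)
    pathway_groups: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["redundant_pairs"] = [list(p) for p in self.redundant_pairs]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["redundant_pairs"] = [tuple(p) for p in payload["redundant_pairs"]]
        return cls(**payload)


@dataclass
class KnowledgeBase:
    """A complete synthetic knowledge base plus its planted truth."""

    associations: PathwayGeneAssociations
    network: RegulatoryNetwork
    annotations: AnnotationTable
    diseases: DiseaseTable
    correlations: pd.DataFrame  # gene_a, gene_b, r
    truth: SyntheticTruth


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _pathway_ids(n: int) -> list[str]:
    return [f"PW{i:03d}" for i in range(n)]


def simulate_regulatory_network(
    genes: Sequence[str],
    hub_genes: Sequence[str],
    seed: int,
    hub_out_degree: int = 20,
    background_rate: float = 1.0,
) -> RegulatoryNetwork:
    """Directed network by preferential attachment with designated hubs.

    Non-hub genes emit ``1 + Poisson(background_rate)`` edges (median out-
    degree 2); hubs emit ``hub_out_degree + Poisson(3)`` edges, at least five
    times the background median.  Targets are drawn proportionally to current
    in-degree + 1 (rich-get-richer), excluding self-loops and duplicates.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    hubs = set(hub_genes)
    n = len(genes)
    gidx = {g: i for i, g in enumerate(genes)}
    indeg = np.ones(n)  # +1 smoothing for attachment weights
    edges: set[tuple[str, str, str]] = set()
    order = rng.permutation(n)
    for i in order:
        g = genes[i]
        k = hub_out_degree + rng.poisson(3) if g in hubs else 1 + rng.poisson(background_rate)
        k = min(k, n - 1)
        w = indeg.copy()
        w[i] = 0.0
        targets = rng.choice(n, size=k, replace=False, p=w / w.sum())
        for t in targets:
            edges.add((g, genes[t], "regulates"))
            indeg[t] += 1
    return RegulatoryNetwork(frozenset(edges))


def _bounded_overlap_memberships(
    n_sets: int,
    set_size: int,
    n_pathways: int,
    max_overlap: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """``set_size``-subsets of pathways with pairwise intersection bounded by
    ``max_overlap``, preferring the least-covered pathways so the union
    covers every pathway as soon as the slot budget allows.

    Greedy with restarts: each pathway added to a set must not push the
    overlap with any earlier set past the bound.
    """
    chosen: list[set[int]] = []
    cover = np.zeros(n_pathways, dtype=int)
    for _ in range(n_sets):
        for _attempt in range(100):
            current: set[int] = set()
            while len(current) < set_size:
                forbidden = set(current)
                for prev in chosen:
                    if len(prev & current) >= max_overlap:
                        forbidden |= prev
                cands = [p for p in range(n_pathways) if p not in forbidden]
                if not cands:
                    break  # dead end; restart this set
                low = min(cover[p] for p in cands)
                pool = [p for p in cands if cover[p] == low]
                current.add(int(pool[rng.integers(len(pool))]))
            if len(current) == set_size:
                break
        else:
            raise RuntimeError(
                "could not satisfy the hub membership overlap bound; "
                "increase n_pathways or max_overlap"
            )
        chosen.append(current)
        cover[list(current)] += 1
    return [np.array(sorted(s)) for s in chosen]


def simulate_knowledge_base(
    n_genes: int = 1000,
    n_pathways: int = 154,
    hub_fraction: float = 0.05,
    n_redundant_pairs: int = 5,
    redundant_shared: int = 6,
    n_coexpression_clusters: int = 5,
    coexpression_cluster_size: int = 3,
    n_terms: int = 50,
    n_enriched_terms: int = 10,
    n_diseases: int = 300,
    disease_mean: float = 2.0,
    disease_excess: float = 3.0,
    n_high_disease: int = 200,
    hub_pathway_degree: int = 6,
    hub_max_overlap: int = 1,
    background_pathway_degree: int = 4,
    seed: int = 0,
) -> KnowledgeBase:
    """Generate a complete synthetic knowledge base with planted truth.

    Defaults define the standard study conditions: 1,000 genes, a 154-pathway
    catalog, 50 hubs (5%), five cloned redundant pairs sharing six pathways,
    five co-expression clusters of three genes, ten hub-enriched annotation
    terms among fifty, and 200 genes with a three-fold excess of disease
    associations (the hubs plus random fill).

    Background genes each join exactly ``background_pathway_degree`` pathways:
    at four memberships over 154 pathways, a chance single shared pathway
    between two background genes is unremarkable under the degree-preserving
    null (tail probability ~0.10), so the redundancy filter's flags
    concentrate on the planted clones rather than on membership noise.  Hub
    memberships are pairwise near-disjoint (``hub_max_overlap``) and jointly
    cover every pathway: planted hubs model distinct pathway regulators.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_pathways < 2:
        raise ValueError("n_pathways must be >= 2")
    if redundant_shared > n_pathways:
        raise ValueError("redundant_shared cannot exceed n_pathways")
    n_hubs = int(round(hub_fraction * n_genes))
    if n_hubs + 2 * n_redundant_pairs + n_coexpression_clusters * coexpression_cluster_size > n_genes:
        raise ValueError("planted structure does not fit into n_genes")

    streams = _rng_streams(seed)
    genes = _gene_ids(n_genes)
    pathways = _pathway_ids(n_pathways)

    rng = streams["assoc"]
    perm = rng.permutation(n_genes)
    hub_idx = perm[:n_hubs]
    hubs = sorted(genes[i] for i in hub_idx)
    pool = [genes[i] for i in perm[n_hubs:]]  # non-hub genes, shuffled
    red_members = pool[: 2 * n_redundant_pairs]
    redundant_pairs = [
        tuple(sorted((red_members[2 * i], red_members[2 * i + 1])))
        for i in range(n_redundant_pairs)
    ]
    co_start = 2 * n_redundant_pairs
    clusters = [
        sorted(pool[co_start + i * coexpression_cluster_size:
                    co_start + (i + 1) * coexpression_cluster_size])
        for i in range(n_coexpression_clusters)
    ]

    # hub memberships: broad, bounded pairwise overlap (distinct regulators)
    edges: list[AssociationEdge] = []
    hub_sets = _bounded_overlap_memberships(
        len(hubs), hub_pathway_degree, n_pathways, hub_max_overlap, rng
    )
    for hub, pset in zip(hubs, hub_sets):
        for pi in pset:
            edges.append(AssociationEdge(pathways[pi], hub, "regulator", frozenset({"synthetic"})))

    # redundant pairs: both members get one identical membership set
    red_in_pair = set(red_members)
    for a, b in redundant_pairs:
        shared = rng.choice(n_pathways, size=redundant_shared, replace=False)
        for g in (a, b):
            for pi in shared:
                edges.append(AssociationEdge(pathways[pi], g, "target", frozenset({"synthetic"})))

    # remaining non-hub genes: fixed-size random memberships
    k_bg = min(background_pathway_degree, n_pathways)
    for g in pool:
        if g in red_in_pair:
            continue
        for pi in rng.choice(n_pathways, size=k_bg, replace=False):
            edges.append(AssociationEdge(pathways[pi], g, "target", frozenset({"synthetic"})))
    associations = PathwayGeneAssociations(edges)

    network = simulate_regulatory_network(
        genes, hubs, seed=int(streams["network"].integers(2**31))
    )

    # annotations: enriched terms concentrate on hubs
    hub_set = set(hubs)
    annotations, enriched = simulate_annotation_table(
        genes, hubs,
        n_terms=n_terms, n_enriched_terms=n_enriched_terms,
        seed=int(streams["annotations"].integers(2**31)),
    )

    # diseases: planted genes carry `disease_excess`-fold associations
    rng_d = streams["diseases"]
    n_high = min(n_high_disease, n_genes)
    extra = [g for g in genes if g not in hub_set]
    rng_d.shuffle(extra)
    high_disease = sorted(set(hubs) | set(extra[: max(0, n_high - len(hubs))]))
    diseases = simulate_disease_table(
        genes, high_disease,
        n_diseases=n_diseases, mean_count=disease_mean, excess=disease_excess,
        seed=int(rng_d.integers(2**31)),
    )

    # correlations: planted clusters above the dedup threshold, mixed background
    rng_c = streams["correlations"]
    crows = []
    for cluster in clusters:
        for i in range(len(cluster)):
            for j in range(i + 1, len(cluster)):
                crows.append(
                    {"gene_a": cluster[i], "gene_b": cluster[j],
                     "r": float(rng_c.uniform(0.92, 0.99))}
                )
    cluster_genes = {g for c in clusters for g in c}
    n_background_pairs = 10 * n_genes
    ia = rng_c.integers(0, n_genes, size=n_background_pairs)
    ib = rng_c.integers(0, n_genes, size=n_background_pairs)
    for i, j in zip(ia, ib):
        if i == j:
            continue
        a, b = sorted((genes[i], genes[j]))
        if a in cluster_genes and b in cluster_genes:
            continue
        crows.append({"gene_a": a, "gene_b": b, "r": float(rng_c.uniform(-0.5, 0.85))})
    correlations = pd.DataFrame(crows, columns=["gene_a", "gene_b", "r"]).drop_duplicates(
        ["gene_a", "gene_b"]
    ).reset_index(drop=True)

    truth = SyntheticTruth(
        hub_genes=hubs,
        redundant_pairs=redundant_pairs,
        coexpression_clusters=clusters,
        enriched_terms=enriched,
        high_disease_genes=high_disease,
        params={
            "n_genes": n_genes,
            "n_pathways": n_pathways,
            "hub_fraction": hub_fraction,
            "n_redundant_pairs": n_redundant_pairs,
            "redundant_shared": redundant_shared,
            "n_terms": n_terms,
            "n_enriched_terms": n_enriched_terms,
            "n_diseases": n_diseases,
            "disease_mean": disease_mean,
            "disease_excess": disease_excess,
            "hub_pathway_degree": hub_pathway_degree,
            "hub_max_overlap": hub_max_overlap,
            "background_pathway_degree": background_pathway_degree,
        },
        seed=seed,
    )
    return KnowledgeBase(
        associations=associations,
        network=network,
        annotations=annotations,
        diseases=diseases,
        correlations=correlations,
        truth=truth,
    )


def simulate_annotation_table(
    genes: Sequence[str],
    target_genes: Sequence[str],
    n_terms: int = 50,
    n_enriched_terms: int = 10,
    p_target: float = 0.6,
    p_background: float = 0.02,
    p_base: float = 0.05,
    frac_experimental: float = 0.85,
    seed: int = 0,
) -> tuple[AnnotationTable, list[str]]:
    """Annotation table where the first ``n_enriched_terms`` terms annotate
    ``target_genes`` with probability ``p_target`` and everything else at
    background rates.  A ``1 - frac_experimental`` share of rows carries the
    non-experimental IEA code (exercising the evidence filter).

    Returns (table, enriched term ids).
    """
    rng = np.random.default_rng(seed)
    terms = [f"T{i:04d}" for i in range(n_terms)]
    enriched = terms[:n_enriched_terms]
    target = set(target_genes)
    exp_codes = np.array(["EXP", "IDA", "IMP"])
    rows = []
    for term in terms:
        p_t, p_b = (p_target, p_background) if term in enriched else (p_base, p_base)
        for g in genes:
            if rng.random() < (p_t if g in target else p_b):
                evidence = str(rng.choice(exp_codes)) if rng.random() < frac_experimental else "IEA"
                rows.append({"gene": g, "term": term, "evidence": evidence})
    table = AnnotationTable(pd.DataFrame(rows, columns=["gene", "term", "evidence"]))
    return table, enriched


def simulate_disease_table(
    genes: Sequence[str],
    high_genes: Sequence[str],
    n_diseases: int = 300,
    mean_count: float = 2.0,
    excess: float = 3.0,
    seed: int = 0,
) -> DiseaseTable:
    """Disease-association table where ``high_genes`` carry ``excess``-fold
    the background Poisson mean of associations per gene."""
    rng = np.random.default_rng(seed)
    disease_ids = [f"D{i:04d}" for i in range(n_diseases)]
    high = set(high_genes)
    rows = []
    for g in genes:
        lam = mean_count * excess if g in high else mean_count
        k = min(int(rng.poisson(lam)), n_diseases)
        for d in rng.choice(n_diseases, size=k, replace=False):
            rows.append({"gene": g, "disease": disease_ids[d]})
    return DiseaseTable(pd.DataFrame(rows, columns=["gene", "disease"]))


# ---------------------------------------------------------------------------
# expression simulation


def triphasic_activation(
    pathways: Sequence[str],
    conditions: Sequence[str],
    amplitude: float = 1.5,
    seed: int = 0,
) -> tuple[dict[str, dict[str, float]], dict[str, str]]:
    """Assign each pathway an early / transient / late activation profile.

    Early pathways peak at the first condition and decay; transient pathways
    peak at an interior condition; late pathways ramp up to the final
    condition.  ``amplitude`` is the peak log2 fold-change.
    """
    if len(conditions) < 3:
        raise ValueError("need at least 3 ordered conditions for three phases")
    rng = np.random.default_rng(seed)
    n_cond = len(conditions)
    profiles: dict[str, dict[str, float]] = {}
    groups: dict[str, str] = {}
    for pw in pathways:
        group = ("early", "transient", "late")[rng.integers(3)]
        lfc = np.zeros(n_cond)
        if group == "early":
            lfc[0] = amplitude
            lfc[1] = amplitude / 2
        elif group == "late":
            lfc[-1] = amplitude
            lfc[-2] = amplitude / 2
        else:
            peak = int(rng.integers(1, n_cond - 1))
            lfc[peak] = amplitude
            lfc[min(peak + 1, n_cond - 1)] = amplitude / 3
        profiles[pw] = {c: float(v) for c, v in zip(conditions, lfc)}
        groups[pw] = group
    return profiles, groups


def dose_response_activation(
    pathway: str,
    doses: Sequence[float],
    max_lfc: float = 2.0,
) -> dict[str, dict[str, float]]:
    """Single-pathway activation scaling linearly with dose (conditions are
    the stringified doses)."""
    top = max(doses)
    return {
        pathway: {str(d): float(max_lfc * d / top) for d in doses}
    }


def simulate_expression(
    genes: Sequence[str],
    gene_sets: PathwayGeneAssociations | Mapping[str, frozenset[str] | set[str]],
    design: Sequence[tuple[str, float, int]],
    activation: Mapping[str, Mapping[str, float]] | None = None,
    libsize_range: tuple[float, float] = (8e5, 1.2e6),
    dispersion: float = 0.04,
    baseline_log2_mean: float = 6.0,
    baseline_log2_sd: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted pathway activation.

    ``design`` lists (condition label, covariate value, n_replicates).
    Per-gene baseline abundances are log-normal; in each condition, member
    genes of an activated pathway have their means shifted by the planted
    log2 fold-change (summed over pathways for shared genes).  Library sizes
    are uniform in ``libsize_range``; counts are NB with the given dispersion
    (variance = mu + dispersion * mu^2).

    Returns (counts genes x samples, sample metadata with columns
    ``sample, condition, covariate, replicate``).
    """
    if not design:
        raise ValueError("design is empty")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    genes = list(genes)
    rng = np.random.default_rng(seed)
    sets = (
        gene_sets.membership()
        if isinstance(gene_sets, PathwayGeneAssociations)
        else {p: frozenset(g) for p, g in gene_sets.items()}
    )
    activation = activation or {}
    gidx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    base = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)

    # per-condition log2 shifts, summed over activated pathways
    cond_lfc: dict[str, np.ndarray] = {}
    for cond, _, _ in design:
        lfc = np.zeros(n_genes)
        for pw, profile in activation.items():
            eff = profile.get(cond, 0.0)
            if eff == 0.0 or pw not in sets:
                continue
            for g in sets[pw]:
                if g in gidx:
                    lfc[gidx[g]] += eff
        cond_lfc[cond] = lfc

    columns, meta_rows = [], []
    data = []
    r = 1.0 / dispersion
    for cond, covariate, n_rep in design:
        weights = base * 2.0 ** cond_lfc[cond]
        rel = weights / weights.sum()
        for rep in range(1, n_rep + 1):
            lib = rng.uniform(*libsize_range)
            mu = rel * lib
            counts = rng.negative_binomial(r, r / (r + mu))
            sample = f"{cond}_r{rep}"
            columns.append(sample)
            data.append(counts)
            meta_rows.append(
                {"sample": sample, "condition": cond, "covariate": covariate, "replicate": rep}
            )
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return counts, meta


def write_knowledge_base(kb: KnowledgeBase, outdir: str | Path) -> dict[str, Path]:
    """Write all knowledge-base artifacts in the formats the pipeline reads."""
    from .knowledge import write_edge_list, write_gene_sets

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gmt": outdir / "associations.gmt",
        "network": outdir / "network.tsv",
        "annotations": outdir / "annotations.tsv",
        "diseases": outdir / "diseases.tsv",
        "correlations": outdir / "correlations.tsv",
        "truth": outdir / "truth.json",
    }
    write_gene_sets(kb.associations, paths["gmt"])
    write_edge_list(kb.network, paths["network"])
    kb.annotations.frame.to_csv(paths["annotations"], sep="\t", index=False)
    kb.diseases.frame.to_csv(paths["diseases"], sep="\t", index=False)
    kb.correlations.to_csv(paths["correlations"], sep="\t", index=False)
    kb.truth.to_json(paths["truth"])
    return paths
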