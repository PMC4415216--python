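"""Redundancy filtering of candidate reporter genes.

Two genes that report on essentially the same pathways carry redundant
information; keeping both wastes panel capacity.  Two filters are applied:

1.  A permutation test on the bipartite pathway-gene graph flags gene pairs
    that share significantly more pathways than expected under a
    degree-preserving null (edge-swap randomization).  From each flagged
    pair the lower-PageRank member is removed.
2.  Genes belonging to one strong co-expression cluster (pairwise correlation
    above a threshold, 0.90 by default) are collapsed to the single
    highest-PageRank representative.

The permutation p-value uses the add-one estimator
``p = (1 + #{null >= observed}) / (1 + N)``; it is valid but conservative for
the discrete shared-pathway count.  No multiplicity adjustment is applied to
pair p-values: the selection rule is raw p below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import CentralityScores
from .knowledge import PathwayGeneAssociations


@dataclass(frozen=True)
class RedundantPairs:
    """Gene pairs sharing significantly more pathways than the null model."""

    frame: pd.DataFrame  # columns: gene_a, gene_b, shared, p  (gene_a < gene_b)
    n_permutations: int
    alpha: float
    seed: int

    def __len__(self) -> int:
        return len(self.frame)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.frame["gene_a"], self.frame["gene_b"]))


@dataclass(frozen=True)
class CoexpressionClusters:
    """Partition of genes into strong co-expression clusters."""

    assignment: dict[str, str]  # gene -> cluster id
    r_min: float

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, cid in self.assignment.items():
            out.setdefault(cid, []).append(gene)
        return {cid: sorted(genes) for cid, genes in out.items()}


def _biadjacency(assoc: PathwayGeneAssociations):
    genes = sorted(assoc.genes)
    pathways = sorted(assoc.pathways)
    gidx = {g: i for i, g in enumerate(genes)}
    pidx = {p: i for i, p in enumerate(pathways)}
    pairs = {(gidx[g], pidx[p]) for p, g, _ in assoc._edges}  # roles collapse
    edge_g = np.fromiter((g for g, _ in pairs), dtype=np.int64, count=len(pairs))
    edge_p = np.fromiter((p for _, p in pairs), dtype=np.int64, count=len(pairs))
    return genes, pathways, edge_g, edge_p


def _membership_matrix(n_genes: int, n_pathways: int, edge_g, edge_p) -> np.ndarray:
    B = np.zeros((n_genes, n_pathways), dtype=bool)
    B[edge_g, edge_p] = True
    return B


def shared_pathway_counts(assoc: PathwayGeneAssociations) -> pd.DataFrame:
    """Count shared pathway neighbors for every unordered gene pair with at
    least one shared pathway.

    Returns a frame with columns ``gene_a, gene_b, shared`` (gene_a < gene_b).
    """
    if len(assoc) == 0:
        raise ValueError("associations are empty")
    genes, pathways, edge_g, edge_p = _biadjacency(assoc)
    B = _membership_matrix(len(genes), len(pathways), edge_g, edge_p)
    S = B.astype(np.int32) @ B.T.astype(np.int32)
    ia, ib = np.triu_indices(len(genes), k=1)
    shared = S[ia, ib]
    keep = shared > 0
    return pd.DataFrame(
        {
            "gene_a": [genes[i] for i in ia[keep]],
            "gene_b": [genes[i] for i in ib[keep]],
            "shared": shared[keep].astype(int),
        }
    )


def _edge_swap(edge_g, edge_p, n_attempts: int, n_pathways: int, rng: np.random.Generator):
    """In-place degree-preserving edge swaps on the bipartite edge list.

    A swap picks two edges (g1,p1), (g2,p2) and rewires to (g1,p2), (g2,p1)
    unless that would create a duplicate edge.  Both gene and pathway degree
    sequences are invariant.
    """
    m = len(edge_g)
    present = set((edge_g * n_pathways + edge_p).tolist())
    picks = rng.integers(0, m, size=(n_attempts, 2))
    for e1, e2 in picks:
        g1, p1 = edge_g[e1], edge_p[e1]
        g2, p2 = edge_g[e2], edge_p[e2]
        if g1 == g2 or p1 == p2:
            continue
        k1 = g1 * n_pathways + p2
        k2 = g2 * n_pathways + p1
        if k1 in present or k2 in present:
            continue
        present.discard(g1 * n_pathways + p1)
        present.discard(g2 * n_pathways + p2)
        present.add(k1)
        present.add(k2)
        edge_p[e1], edge_p[e2] = p2, p1


def pair_null_pvalues(
    assoc: PathwayGeneAssociations,
    n_permutations: int = 1000,
    seed: int = 0,
    swap_factor: int = 3,
) -> pd.DataFrame:
    """Empirical p-values for all gene pairs sharing at least one pathway.

    The null is an edge-swap Markov chain over bipartite graphs with the
    observed degree sequences: after a burn-in of ``10 * swap_factor * E``
    attempted swaps, ``n_permutations`` states are sampled every
    ``swap_factor * E`` attempts and each pair's shared-pathway count is
    compared with its observed value using the add-one estimator.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    obs = shared_pathway_counts(assoc)
    genes, pathways, edge_g, edge_p = _biadjacency(assoc)
    gidx = {g: i for i, g in enumerate(genes)}
    n_path = len(pathways)
    ia = np.array([gidx[g] for g in obs["gene_a"]], dtype=np.int64)
    ib = np.array([gidx[g] for g in obs["gene_b"]], dtype=np.int64)
    observed = obs["shared"].to_numpy()

    rng = np.random.default_rng(seed)
    edge_g = edge_g.copy()
    edge_p = edge_p.copy()
    m = len(edge_g)
    _edge_swap(edge_g, edge_p, 10 * swap_factor * m, n_path, rng)  # burn-in
    ge_count = np.zeros(len(obs), dtype=np.int64)
    for _ in range(n_permutations):
        _edge_swap(edge_g, edge_p, swap_factor * m, n_path, rng)
        B = _membership_matrix(len(genes), n_path, edge_g, edge_p)
        null_shared = np.sum(B[ia] & B[ib], axis=1)
        ge_count += null_shared >= observed
    out = obs.copy()
    out["p"] = (1.0 + ge_count) / (1.0 + n_permutations)
    return out


def sicore_pairs(
    assoc: PathwayGeneAssociations,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    swap_factor: int = 3,
) -> RedundantPairs:
    """Gene pairs sharing significantly more pathways than the degree-
    preserving null, at raw empirical p < alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    table = pair_null_pvalues(assoc, n_permutations=n_permutations, seed=seed,
                              swap_factor=swap_factor)
    sig = table.loc[table["p"] < alpha].reset_index(drop=True)
    return RedundantPairs(frame=sig, n_permutations=n_permutations, alpha=alpha, seed=seed)


def prune_by_pairs(ranking: CentralityScores, pairs: RedundantPairs) -> list[str]:
    """Resolve redundant pairs: remove the lower-centrality member of each.

    Pairs are processed in ascending p (ties: ascending (gene_a, gene_b) key)
    so the strongest redundancies are honored first; a pair is skipped if
    either member was already removed.  Centrality ties remove the
    lexicographically later gene.  Returns the retained genes in the
    ranking's descending-score order.
    """
    order = ranking.rank_order()
    frame = pairs.frame.sort_values(["p", "gene_a", "gene_b"], kind="mergesort")
    removed: set[str] = set()
    for _, row in frame.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        for g in (a, b):
            if g not in ranking:
                raise KeyError(f"pair member {g!r} missing from ranking")
        if a in removed or b in removed:
            continue
        sa, sb = ranking[a], ranking[b]
        if sa > sb:
            removed.add(b)
        elif sb > sa:
            removed.add(a)
        else:
            removed.add(max(a, b))
    return [g for g in order if g not in removed]


def coexpression_clusters(correlations: pd.DataFrame, r_min: float = 0.90) -> CoexpressionClusters:
    """Connected components of the gene graph with edges where r > r_min.

    ``correlations`` has columns ``gene_a, gene_b, r``.  Only positive
    correlations strictly above the threshold link genes; all genes appearing
    in the table are covered (singletons get their own cluster).
    """
    r = correlations["r"].to_numpy(dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlation values must lie in [-1, 1]")
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for _, row in correlations.iterrows():
        for g in (row["gene_a"], row["gene_b"]):
            parent.setdefault(g, g)
        if row["r"] > r_min:
            ra, rb = find(row["gene_a"]), find(row["gene_b"])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    components: dict[str, list[str]] = {}
    for g in parent:
        components.setdefault(find(g), []).append(g)
    assignment: dict[str, str] = {}
    for i, root in enumerate(sorted(components)):
        cid = f"C{i:05d}"
        for g in components[root]:
            assignment[g] = cid
    return CoexpressionClusters(assignment=assignment, r_min=r_min)


def coexpression_dedup(
    genes: list[str],
    clusters: CoexpressionClusters,
    ranking: CentralityScores,
) -> list[str]:
    """Keep one representative per co-expression cluster.

    From each cluster intersected with the input list exactly the maximum-
    centrality gene is retained (ties keep the lexicographically earlier id);
    genes outside any cluster pass through.  Input order is preserved.
    """
    by_cluster: dict[str, list[str]] = {}
    for g in genes:
        cid = clusters.assignment.get(g)
        if cid is not None:
            if g not in ranking:
                raise KeyError(f"gene {g!r} missing from ranking")
            by_cluster.setdefault(cid, []).append(g)
    removed: set[str] = set()
    for members in by_cluster.values():
        if len(members) < 2:
            continue
        # highest score wins; score ties keep the lexicographically earlier id
        keep = sorted(members, key=lambda g: (-ranking[g], g))[0]
        removed.update(m for m in members if m != keep)
    return [g for g in genes if g not in removed]
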