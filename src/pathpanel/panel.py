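"""Assembly of the final reporter-gene panel.

After redundancy filtering, the top fraction (20% by default) of the ranked
non-redundant genes is taken, truncated to the assay's capacity, and a
user-supplied exclusion list (e.g. vendor-rejected, ubiquitously high
expressed genes) is removed without backfilling.  Every candidate gene of the
knowledge base receives an audit record with a terminal status so that the
fate of each gene is traceable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .centrality import CentralityScores
from .knowledge import PathwayGeneAssociations

#: terminal audit statuses
STATUS_SELECTED = "selected"
STATUS_PRUNED_REDUNDANT = "pruned-redundant"
STATUS_PRUNED_COEXPRESSION = "pruned-coexpression"
STATUS_BELOW_CUTOFF = "below-cutoff"
STATUS_EXCLUDED = "excluded"


@dataclass(frozen=True)
class Panel:
    """Ordered reporter-gene panel with a per-gene audit trail."""

    genes: tuple[str, ...]  # descending centrality, ties by gene id
    audit: pd.DataFrame  # columns: gene, score, rank, status
    fraction: float
    max_size: int
    exclusions: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def to_frame(self) -> pd.DataFrame:
        sub = self.audit.set_index("gene").loc[list(self.genes)].reset_index()
        return sub[["gene", "rank", "score"]]


def select_panel(
    ranked: list[str],
    scores: CentralityScores,
    fraction: float = 0.20,
    max_size: int = 1200,
    exclusions: frozenset[str] | set[str] = frozenset(),
    pruned_redundant: set[str] | None = None,
    pruned_coexpression: set[str] | None = None,
) -> Panel:
    """Take the top ``ceil(fraction * n)`` of the ranked non-redundant genes,
    truncate to ``max_size``, then drop exclusion-list members (no backfill).

    ``ranked`` is the post-filter gene list in descending centrality order.
    ``pruned_redundant`` / ``pruned_coexpression`` are genes removed by the
    upstream filters; they only feed the audit trail.
    """
    if not ranked:
        raise ValueError("ranked gene list is empty")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if max_size < 1:
        raise ValueError(f"max_size must be >= 1, got {max_size}")
    exclusions = frozenset(exclusions)
    pruned_redundant = set(pruned_redundant or ())
    pruned_coexpression = set(pruned_coexpression or ())

    n_take = min(math.ceil(fraction * len(ranked)), max_size)
    top = ranked[:n_take]
    selected = [g for g in top if g not in exclusions]

    status: dict[str, str] = {}
    for g in pruned_redundant:
        status[g] = STATUS_PRUNED_REDUNDANT
    for g in pruned_coexpression:
        status[g] = STATUS_PRUNED_COEXPRESSION
    for g in ranked:
        status[g] = STATUS_BELOW_CUTOFF
    for g in top:
        status[g] = STATUS_EXCLUDED if g in exclusions else STATUS_SELECTED

    rank_of = {g: i + 1 for i, g in enumerate(ranked)}
    all_genes = sorted(status)
    audit = pd.DataFrame(
        {
            "gene": all_genes,
            "score": [scores[g] if g in scores else float("nan") for g in all_genes],
            "rank": [rank_of.get(g, -1) for g in all_genes],
            "status": [status[g] for g in all_genes],
        }
    )
    return Panel(
        genes=tuple(selected),
        audit=audit,
        fraction=fraction,
        max_size=max_size,
        exclusions=exclusions,
    )


@dataclass(frozen=True)
class CoverageCounts:
    """Reporter counts per pathway and pathway counts per reporter."""

    reporters_per_pathway: pd.Series  # index pathway
    pathways_per_gene: pd.Series  # index panel gene
    uncovered_pathways: tuple[str, ...]


def pathway_coverage(panel: Panel, assoc: PathwayGeneAssociations) -> CoverageCounts:
    """Count panel reporters per pathway and pathways per panel gene; flag
    pathways left without any reporter."""
    membership = assoc.membership()
    panel_set = panel.gene_set
    rpp = pd.Series(
        {p: len(genes & panel_set) for p, genes in membership.items()}, dtype=int
    ).sort_index()
    gm = assoc.gene_membership()
    ppg = pd.Series(
        {g: len(gm.get(g, frozenset())) for g in sorted(panel_set)}, dtype=int
    )
    uncovered = tuple(sorted(p for p, c in rpp.items() if c == 0))
    return CoverageCounts(
        reporters_per_pathway=rpp, pathways_per_gene=ppg, uncovered_pathways=uncovered
    )
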