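"""End-to-end panel design pipeline with provenance.

Stages run in the fixed order: harmonize -> centrality -> redundancy
(pair test, then co-expression dedup) -> panel selection -> validation.
Every stage parameter and seed is recorded in a run manifest so a rerun with
the same config and inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .centrality import CentralityScores, pagerank
from .knowledge import (
    PathwayGeneAssociations,
    read_annotation_table,
    read_disease_table,
    read_edge_list,
    read_gene_sets,
    harmonize,
)
from .panel import Panel, pathway_coverage, select_panel
from .redundancy import (
    RedundantPairs,
    coexpression_clusters,
    coexpression_dedup,
    prune_by_pairs,
    sicore_pairs,
)
from .validation import (
    centrality_crosscheck,
    disease_density_comparison,
    fisher_enrichment,
    interaction_coverage,
    significant_term_count,
)

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "gmt_paths", "network_path", "correlations_path", "annotations_path",
    "diseases_path", "independent_network_path", "mode", "damping", "tol",
    "max_iter", "n_permutations", "alpha", "r_min", "fraction", "max_size",
    "exclusions", "n_random", "n_boot", "seed",
}


@dataclass
class PipelineConfig:
    """All file paths and stage parameters of one pipeline run."""

    gmt_paths: list[str] = field(default_factory=list)
    network_path: str | None = None
    correlations_path: str | None = None
    annotations_path: str | None = None
    diseases_path: str | None = None
    independent_network_path: str | None = None
    mode: str = "undirected"
    damping: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000
    n_permutations: int = 1000
    alpha: float = 0.05
    r_min: float = 0.90
    fraction: float = 0.20
    max_size: int = 1200
    exclusions: list[str] = field(default_factory=list)
    n_random: int = 1000
    n_boot: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.gmt_paths:
            raise ValueError("config must list at least one GMT source (gmt_paths)")
        if self.network_path is None:
            raise ValueError("config must provide network_path (centrality stage)")
        for p in [*self.gmt_paths, self.network_path, self.correlations_path,
                  self.annotations_path, self.diseases_path,
                  self.independent_network_path]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def parameter_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PanelDesignResult:
    """In-memory result of the design stages (no file I/O)."""

    scores: CentralityScores
    pairs: RedundantPairs
    after_pair_prune: list[str]
    after_dedup: list[str]
    panel: Panel


def design_panel(
    associations: PathwayGeneAssociations,
    network,
    correlations: pd.DataFrame | None = None,
    mode: str = "undirected",
    damping: float = 0.85,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    r_min: float = 0.90,
    fraction: float = 0.20,
    max_size: int = 1200,
    exclusions: frozenset[str] | set[str] = frozenset(),
    seed: int = 0,
) -> PanelDesignResult:
    """Run centrality -> redundancy -> panel selection in memory.

    Knowledge-base genes absent from the regulatory network receive
    centrality 0 (ranked below every network gene) so that the redundancy
    filters and the audit trail cover the full candidate list.
    """
    scores = pagerank(network, mode=mode, damping=damping)
    candidates = sorted(associations.genes)
    extended = scores.scores.reindex(
        sorted(set(scores.scores.index) | set(candidates)), fill_value=0.0
    )
    ranking = CentralityScores(
        scores=extended, damping=scores.damping, mode=scores.mode,
        iterations=scores.iterations, residual=scores.residual,
    )

    pairs = sicore_pairs(associations, n_permutations=n_permutations, alpha=alpha, seed=seed)
    retained = prune_by_pairs(ranking, pairs)
    pruned_redundant = set(ranking.scores.index) - set(retained)
    # restrict the ranked list to knowledge-base candidates
    retained = [g for g in retained if g in set(candidates)]

    if correlations is not None and len(correlations):
        clusters = coexpression_clusters(correlations, r_min=r_min)
        deduped = coexpression_dedup(retained, clusters, ranking)
    else:
        deduped = retained
    pruned_coexpr = set(retained) - set(deduped)

    panel = select_panel(
        deduped,
        ranking,
        fraction=fraction,
        max_size=max_size,
        exclusions=exclusions,
        pruned_redundant=pruned_redundant & set(candidates),
        pruned_coexpression=pruned_coexpr,
    )
    return PanelDesignResult(
        scores=ranking,
        pairs=pairs,
        after_pair_prune=retained,
        after_dedup=deduped,
        panel=panel,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the configured pipeline and write all outputs to ``outdir``.

    Returns the run manifest (also written as ``manifest.json``).  A stage
    failure aborts with the stage name in the raised exception.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "harmonize"
    try:
        sources = [read_gene_sets(p) for p in config.gmt_paths]
        associations = harmonize(sources)
        network = read_edge_list(config.network_path)
        correlations = (
            pd.read_csv(config.correlations_path, sep="\t")
            if config.correlations_path
            else None
        )
        stage = "design"
        result = design_panel(
            associations,
            network,
            correlations=correlations,
            mode=config.mode,
            damping=config.damping,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            r_min=config.r_min,
            fraction=config.fraction,
            max_size=config.max_size,
            exclusions=frozenset(config.exclusions),
            seed=config.seed,
        )

        stage = "write-outputs"
        result.scores.to_frame().to_csv(outdir / "scores.tsv", sep="\t", index=False)
        result.pairs.frame.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        result.panel.to_frame().to_csv(outdir / "panel.tsv", sep="\t", index=False)
        result.panel.audit.to_csv(outdir / "audit.tsv", sep="\t", index=False)

        stage = "validation"
        report: dict[str, Any] = {
            "panel_size": len(result.panel),
            "n_redundant_pairs": len(result.pairs),
            "n_candidates": len(associations.genes),
        }
        coverage = pathway_coverage(result.panel, associations)
        report["uncovered_pathways"] = list(coverage.uncovered_pathways)
        if config.annotations_path:
            annotations = read_annotation_table(config.annotations_path)
            universe = sorted(annotations.experimental_only().genes | result.panel.gene_set)
            table = fisher_enrichment(result.panel.gene_set, annotations, set(universe))
            report["significant_terms"] = significant_term_count(table, alpha=0.05)
        if config.diseases_path:
            diseases = read_disease_table(config.diseases_path)
            dd = disease_density_comparison(
                sorted(result.panel.gene_set), diseases,
                n_random=config.n_random, seed=config.seed,
            )
            report["disease_ks_p"] = dd.ks_p
            report["disease_mean_ratio"] = dd.mean_ratio
        if config.independent_network_path:
            independent = read_edge_list(config.independent_network_path)
            cc = centrality_crosscheck(
                sorted(result.panel.gene_set), independent,
                mode=config.mode, damping=config.damping,
            )
            report["crosscheck_median_ratio"] = cc.ratio
            cov = interaction_coverage(
                sorted(result.panel.gene_set), independent,
                n_boot=config.n_boot, seed=config.seed,
            )
            report["involved_fraction"] = cov.involved_fraction
            report["involved_baseline_ci"] = list(cov.baseline_ci)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "parameter_hash": config.parameter_hash(),
        "seed": config.seed,
        "outputs": ["scores.tsv", "pairs.tsv", "panel.tsv", "audit.tsv", "report.json"],
        "report": report,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
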