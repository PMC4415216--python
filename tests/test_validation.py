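"""In-silico validation statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from pathpanel.knowledge import AnnotationTable, DiseaseTable, RegulatoryNetwork
from pathpanel.validation import (
    bh_adjust,
    centrality_crosscheck,
    disease_density_comparison,
    fisher_enrichment,
    interaction_coverage,
    random_set_baseline,
    significant_term_count,
)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_capped(self):
        assert bh_adjust([1.0]).tolist() == [1.0]

    def test_sorted_input_gives_nondecreasing_output(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=40))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.uniform(size=int(rng.integers(1, 60)))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def annotation_table(term_genes):
    rows = [
        {"gene": g, "term": t, "evidence": "EXP"}
        for t, genes in term_genes.items()
        for g in genes
    ]
    return AnnotationTable(pd.DataFrame(rows, columns=["gene", "term", "evidence"]))


def hypergeom_tail_oracle(N, K, n, x):
    """Exact one-sided p by enumeration of the hypergeometric point masses."""
    total = 0.0
    for i in range(x, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return total


class TestFisherEnrichment:
    def test_worked_example(self):
        universe = {f"G{i}" for i in range(10)}
        term_genes = {"T1": ["G0", "G1", "G2", "G3"]}
        table = fisher_enrichment(
            {"G0", "G1", "G2", "G3", "G4"}, annotation_table(term_genes), universe
        )
        p = float(table.frame["p"].iloc[0])
        assert p == pytest.approx(6 / 252, abs=1e-12)

    def test_empty_term_and_universe_set(self):
        universe = {"G0", "G1", "G2"}
        table = fisher_enrichment(
            {"G0"}, annotation_table({"T1": []}), universe
        )
        # T1 annotates nothing in the universe -> it is absent from the table
        assert len(table.frame) == 0 or (table.frame["p"] == 1.0).all()

    def test_set_equals_universe_is_degenerate(self):
        universe = {"G0", "G1", "G2", "G3"}
        table = fisher_enrichment(
            universe, annotation_table({"T1": ["G0", "G1"]}), universe
        )
        assert (table.frame["p"] == 1.0).all()

    def test_matches_enumeration_oracle_small_universes(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            N = int(rng.integers(2, 31))
            universe = [f"G{i}" for i in range(N)]
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            term = list(rng.choice(universe, size=K, replace=False))
            gene_set = set(rng.choice(universe, size=n, replace=False))
            table = fisher_enrichment(
                gene_set, annotation_table({"T": term}), set(universe)
            )
            if K == 0:
                continue
            x = len(set(term) & gene_set)
            assert float(table.frame["p"].iloc[0]) == pytest.approx(
                hypergeom_tail_oracle(N, K, n, x), abs=1e-12
            )

    def test_counts_sum_to_universe(self):
        universe = {f"G{i}" for i in range(20)}
        table = fisher_enrichment(
            {f"G{i}" for i in range(5)},
            annotation_table({"T1": [f"G{i}" for i in range(8)]}),
            universe,
        )
        row = table.frame.iloc[0]
        total = (
            row["set_in_term"] + row["set_not_term"]
            + row["universe_in_term_not_set"] + row["remainder"]
        )
        assert total == 20

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), annotation_table({"T": []}), set())


def test_significant_term_count():
    from pathpanel.validation import EnrichmentTable

    frame = pd.DataFrame({"term": ["a", "b"], "p": [0.001, 0.2], "q": [0.01, 0.2]})
    assert significant_term_count(EnrichmentTable(frame, 10), alpha=0.05) == 1
    empty = EnrichmentTable(pd.DataFrame(columns=["term", "p", "q"]), 10)
    assert significant_term_count(empty) == 0


class TestRandomSetBaseline:
    universe = [f"G{i}" for i in range(100)]

    def test_constant_statistic(self):
        base = random_set_baseline(self.universe, 10, 50, statistic=len, seed=0)
        assert base.mean == 10 and base.ci_low == base.ci_high == 10

    def test_same_seed_reproducible(self):
        stat = lambda s: sum(hash(g) % 7 for g in s)
        a = random_set_baseline(self.universe, 10, 30, stat, seed=5)
        b = random_set_baseline(self.universe, 10, 30, stat, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_half_universe_overlap_matches_hypergeometric_mean(self):
        half = set(self.universe[:50])
        base = random_set_baseline(
            self.universe, 20, 500, statistic=lambda s: len(s & half), seed=2
        )
        assert base.mean == pytest.approx(10.0, abs=0.5)

    def test_oversized_draw_errors(self):
        with pytest.raises(ValueError):
            random_set_baseline(self.universe, 101, 5, statistic=len)


class TestDiseaseDensity:
    def table(self, counts):
        rows = [
            {"gene": g, "disease": f"D{i}"}
            for g, k in counts.items()
            for i in range(k)
        ]
        return DiseaseTable(pd.DataFrame(rows, columns=["gene", "disease"]))

    def test_identical_distributions_give_zero_statistic(self):
        # every gene in the universe has exactly 2 associations
        counts = {f"G{i}": 2 for i in range(40)}
        result = disease_density_comparison(
            [f"G{i}" for i in range(10)], self.table(counts), n_random=20, seed=0
        )
        assert result.ks_statistic == 0.0
        assert result.ks_p == pytest.approx(1.0)

    def test_disjoint_supports_give_statistic_one(self):
        counts = {f"P{i}": 3 for i in range(10)}
        counts.update({f"B{i}": 1 for i in range(40)})
        result = disease_density_comparison(
            [f"P{i}" for i in range(10)], self.table(counts), n_random=20, seed=0,
            universe=[f"B{i}" for i in range(40)],
        )
        assert result.ks_statistic == 1.0
        assert result.mean_ratio == pytest.approx(3.0)


class TestCrosscheck:
    def test_uniform_graph_ratio_one(self):
        pairs = [(f"N{i}", f"N{(i + 1) % 8}") for i in range(8)]
        result = centrality_crosscheck(["N0", "N1"], RegulatoryNetwork.from_pairs(pairs))
        assert result.ratio == pytest.approx(1.0, abs=1e-9)

    def test_panel_covering_all_nodes_errors(self):
        net = RegulatoryNetwork.from_pairs([("A", "B")])
        with pytest.raises(ValueError):
            centrality_crosscheck(["A", "B"], net)

    def test_planted_hubs_score_above_background(self, small_kb):
        from pathpanel.synthdata import simulate_regulatory_network

        independent = simulate_regulatory_network(
            sorted(small_kb.associations.genes), small_kb.truth.hub_genes, seed=99
        )
        result = centrality_crosscheck(small_kb.truth.hub_genes, independent)
        assert result.ratio > 1.0


class TestInteractionCoverage:
    def chain(self):
        return RegulatoryNetwork.from_pairs([("A", "B"), ("B", "C"), ("C", "D")])

    def test_toy_fractions(self):
        report = interaction_coverage(["A", "D"], self.chain(), n_boot=10, seed=0)
        assert report.upstream_fraction == pytest.approx(1 / 3)
        assert report.downstream_fraction == pytest.approx(1 / 3)
        assert report.involved_fraction == pytest.approx(2 / 3)

    def test_disjoint_panel_gives_zero(self):
        report = interaction_coverage(["X", "Y"], self.chain(), n_boot=10, seed=0)
        assert report.involved_fraction == 0.0

    def test_involved_bounded_by_role_sum(self, small_kb):
        hubs = small_kb.truth.hub_genes
        report = interaction_coverage(hubs, small_kb.network, n_boot=50, seed=1)
        assert report.involved_fraction <= (
            report.upstream_fraction + report.downstream_fraction + 1e-12
        )
        assert 0.0 <= report.involved_fraction <= 1.0

    def test_full_coverage_panel_excludes_baseline(self):
        report = interaction_coverage(
            ["A", "B", "C", "D"], self.chain(), n_boot=100, seed=0
        )
        assert report.involved_fraction == 1.0
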