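"""Expression normalization, activity scores, and trend tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pathpanel.phenotyping import (
    activity_scores,
    call_de_genes,
    log2_cpm,
    pathway_regulation_test,
    peak_time_ordering,
    row_zscore,
    trend_test,
    variance_explained_fraction,
)


class TestLog2Cpm:
    def test_formula_substitution(self):
        counts = pd.DataFrame({"s1": [1, 3]}, index=["g1", "g2"])
        out = log2_cpm(counts)
        assert out.loc["g1", "s1"] == pytest.approx(np.log2(1.5 / 5 * 1e6))
        assert out.loc["g2", "s1"] == pytest.approx(np.log2(3.5 / 5 * 1e6))

    def test_monotone_within_sample(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            {"s": np.sort(rng.integers(0, 500, size=30))},
            index=[f"g{i}" for i in range(30)],
        )
        values = log2_cpm(counts)["s"].to_numpy()
        assert (np.diff(values) >= 0).all()

    def test_depth_doubling_is_stable_for_expressed_genes(self):
        # the pseudocount perturbs log2-cpm by ~0.5/(2 ln2 (c+0.5)) under a
        # depth doubling: below 0.01 once c >= 40
        counts = pd.DataFrame({"s": [40, 100, 1000, 10000]}, index=list("abcd"))
        doubled = counts * 2
        delta = (log2_cpm(doubled) - log2_cpm(counts)).abs()
        assert (delta["s"] < 0.01).all()

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="library"):
            log2_cpm(counts)


class TestActivityScores:
    def expr_with_ranks(self, order):
        """Expression where gene order equals rank order (1=lowest)."""
        return pd.DataFrame(
            {"s1": np.arange(1.0, len(order) + 1.0)}, index=order
        )

    def test_top_ranked_pair_closed_form(self):
        expr = self.expr_with_ranks(["a", "b", "c", "d", "e"])
        scores = activity_scores(expr, {"P": {"d", "e"}})  # ranks 4, 5
        assert scores.frame.loc["P", "s1"] == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_bottom_ranked_pair_is_mirror(self):
        expr = self.expr_with_ranks(["a", "b", "c", "d", "e"])
        scores = activity_scores(expr, {"P": {"a", "b"}})
        assert scores.frame.loc["P", "s1"] == pytest.approx(-np.sqrt(3.0), abs=1e-12)

    def test_null_scores_standardized(self):
        rng = np.random.default_rng(1)
        G = 200
        expr = pd.DataFrame(
            rng.normal(size=(G, 50)),
            index=[f"g{i}" for i in range(G)],
            columns=[f"s{j}" for j in range(50)],
        )
        sets = {
            f"P{k}": set(rng.choice(expr.index, size=10, replace=False))
            for k in range(200)
        }
        values = activity_scores(expr, sets).frame.to_numpy().ravel()
        assert abs(values.mean()) < 0.05
        assert abs(values.var() - 1.0) < 0.1

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.normal(size=(30, 4)), index=[f"g{i}" for i in range(30)]
        )
        sets = {"P": set(expr.index[:7]), "Q": set(expr.index[10:15])}
        a = activity_scores(expr, sets).frame
        b = activity_scores(np.exp(expr / 3.0), sets).frame
        pd.testing.assert_frame_equal(a, b)

    def test_full_coverage_set_errors_and_empty_set_skipped(self, caplog):
        expr = self.expr_with_ranks(["a", "b", "c"])
        with pytest.raises(ValueError):
            activity_scores(expr, {"P": {"a", "b", "c"}})
        with caplog.at_level("WARNING"):
            scores = activity_scores(expr, {"P": {"a"}, "Q": {"zz"}})
        assert list(scores.frame.index) == ["P"]


class TestRowZscore:
    def scores_of(self, rows, columns):
        from pathpanel.phenotyping import ActivityScores

        frame = pd.DataFrame(rows, columns=columns)
        return ActivityScores(frame=frame, method="meanrank-z",
                              set_sizes=pd.Series(dtype=int))

    def test_simple_row(self):
        z = row_zscore(self.scores_of({0: [1.0], 1: [2.0], 2: [3.0]}, None))
        assert np.allclose(z.frame.iloc[0], [-1.0, 0.0, 1.0])

    def test_constant_row_becomes_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            z = row_zscore(self.scores_of({0: [5.0], 1: [5.0], 2: [5.0]}, None))
        assert (z.frame.iloc[0] == 0.0).all()
        assert "constant" in caplog.text

    def test_rows_are_standardized(self):
        rng = np.random.default_rng(3)
        z = row_zscore(
            self.scores_of({i: rng.normal(size=8) for i in range(8)}, None)
        )
        assert z.frame.mean(axis=1).abs().max() < 1e-12
        assert (z.frame.var(axis=1, ddof=1) - 1.0).abs().max() < 1e-9


class TestPeakOrdering:
    def scores(self, rows):
        from pathpanel.phenotyping import ActivityScores

        frame = pd.DataFrame(rows, index=["t0", "t1", "t2"]).T
        return ActivityScores(frame=frame, method="meanrank-z",
                              set_sizes=pd.Series(dtype=int))

    def test_sorts_by_peak_time(self):
        ordering = peak_time_ordering(
            self.scores({"late": [0, 1, 2], "early": [2, 1, 0]}),
            ["t0", "t1", "t2"],
        )
        assert ordering.order == ("early", "late")
        assert ordering.groups["early"] == "early"
        assert ordering.groups["late"] == "late"

    def test_all_peaking_first_keeps_id_order(self):
        ordering = peak_time_ordering(
            self.scores({"a": [3, 1, 0], "b": [2, 1, 0], "c": [9, 0, 0]}),
            ["t0", "t1", "t2"],
        )
        assert ordering.order == ("a", "b", "c")

    def test_interior_peak_labeled_transient(self):
        ordering = peak_time_ordering(
            self.scores({"x": [0, 5, 1]}), ["t0", "t1", "t2"]
        )
        assert ordering.groups["x"] == "transient"


class TestVarianceExplained:
    def expr(self):
        rng = np.random.default_rng(4)
        return pd.DataFrame(
            rng.normal(size=(50, 12)), index=[f"g{i}" for i in range(50)]
        )

    def test_full_subset_varsum_is_one(self):
        expr = self.expr()
        frac, _ = variance_explained_fraction(expr, list(expr.index), "varsum")
        assert frac == pytest.approx(1.0)

    def test_constant_subset_is_zero(self):
        expr = self.expr()
        expr.loc["g0"] = 1.0
        expr.loc["g1"] = 2.0
        frac, _ = variance_explained_fraction(expr, ["g0", "g1"], "varsum")
        assert frac == 0.0

    def test_planted_high_variance_subset_beats_baseline(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.normal(size=(200, 10)), index=[f"g{i}" for i in range(200)]
        )
        planted = [f"g{i}" for i in range(10)]
        expr.loc[planted] *= np.sqrt(3.0)
        frac, base = variance_explained_fraction(
            expr, planted, "varsum", n_random=100, seed=6
        )
        # planted genes inflate the denominator, so the expected ratio is
        # 3 / mean-variance = 3/1.1, minus sampling noise
        assert 2.0 < frac / base.mean < 4.0
        assert frac > base.ci_high

    def test_projection_of_full_rank_subset_is_one(self):
        expr = self.expr().iloc[:20]
        frac, _ = variance_explained_fraction(expr, list(expr.index), "projection")
        assert frac == pytest.approx(1.0, abs=1e-9)


class TestPathwayRegulation:
    def test_exact_hypergeometric_example(self):
        panel = [f"g{i}" for i in range(10)]
        sets = {"P": set(panel[:4])}
        table = pathway_regulation_test(panel[:4], panel, sets)
        assert float(table["p"].iloc[0]) == pytest.approx(1 / 210, abs=1e-12)

    def test_no_de_genes_gives_unit_pvalues(self):
        panel = [f"g{i}" for i in range(10)]
        table = pathway_regulation_test([], panel, {"P": set(panel[:4])})
        assert (table["p"] == 1.0).all()

    def test_de_outside_panel_errors(self):
        with pytest.raises(ValueError):
            pathway_regulation_test(["zz"], ["g1"], {"P": {"g1"}})

    def test_type_one_error_under_permuted_labels(self):
        rng = np.random.default_rng(7)
        panel = [f"g{i}" for i in range(200)]
        sets = {f"P{k}": set(rng.choice(panel, size=8, replace=False)) for k in range(50)}
        rejections = total = 0
        for _ in range(40):
            de = list(rng.choice(panel, size=10, replace=False))
            table = pathway_regulation_test(de, panel, sets)
            rejections += int((table["p"] < 0.05).sum())
            total += len(table)
        rate = rejections / total
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)


class TestTrendTest:
    def test_constant_gene_convention(self):
        expr = pd.DataFrame([[5.0] * 6], index=["g0"])
        result = trend_test(expr, [0, 1, 2, 3, 4, 5], degree=2)
        row = result.frame.iloc[0]
        assert row["p"] == 1.0 and row["linear"] == 0.0 and row["direction"] == 0

    def test_decreasing_response_has_negative_slope(self):
        expr = pd.DataFrame([[10.0, 8.0, 5.5, 4.0, 2.0, 1.0]], index=["g0"])
        result = trend_test(expr, [0, 1, 2, 3, 4, 5], degree=1)
        assert result.frame.iloc[0]["direction"] == -1

    @pytest.mark.parametrize("degree", [1, 2])
    def test_matches_statsmodels_ols(self, degree):
        rng = np.random.default_rng(8)
        x = np.array([0.0, 0.0, 1.0, 1.0, 3.0, 3.0, 10.0, 10.0, 10.0])
        expr = pd.DataFrame(
            rng.normal(size=(20, len(x))) + np.outer(rng.normal(size=20), x / 5),
            index=[f"g{i}" for i in range(20)],
        )
        result = trend_test(expr, x, degree=degree)
        from pathpanel.phenotyping import _orthonormal_poly

        Q = _orthonormal_poly(x, degree)
        for i, gene in enumerate(expr.index):
            fit = sm.OLS(expr.iloc[i].to_numpy(), sm.add_constant(Q)).fit()
            if degree == 2:
                ref_p = fit.f_pvalue
            else:
                ref_p = fit.pvalues[1]
            row = result.frame.iloc[i]
            assert row["p"] == pytest.approx(ref_p, abs=1e-10)
            assert row["linear"] == pytest.approx(fit.params[1], abs=1e-10)

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(
            rng.normal(size=(2000, 8)), index=[f"g{i}" for i in range(2000)]
        )
        result = trend_test(expr, np.arange(8.0), degree=2)
        from scipy import stats

        ks = stats.kstest(result.frame["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_constant_covariate_errors(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"])
        with pytest.raises(ValueError):
            trend_test(expr, [2, 2, 2, 2])


def test_call_de_genes_thresholds():
    rng = np.random.default_rng(10)
    x = np.repeat([0.0, 1.0, 3.0, 10.0], 3)
    expr = pd.DataFrame(
        rng.normal(scale=0.1, size=(30, 12)), index=[f"g{i}" for i in range(30)]
    )
    expr.loc["g0"] += 0.25 * x  # lfc 2.5 at top dose
    expr.loc["g1"] += 0.05 * x  # strong trend but lfc 0.5 < threshold
    de, frame = call_de_genes(expr, x, degree=2, lfc_threshold=1.0, alpha=0.05)
    assert "g0" in de
    assert "g1" not in de
    assert frame.set_index("gene").loc["g0", "lfc"] == pytest.approx(2.5, abs=0.3)
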