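import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import epimetab as em
from epimetab.datatypes import ExpressionMatrix, ValidationError
from epimetab.diffexpr import (bh_fdr, call_degs, call_degs_geo,
                               estimate_background_sd, filter_low_expression,
                               recurrence_filter, regularized_t,
                               restrict_to_metabolic, signed_fold_change)


def _expr(rows, genes=None, samples=None):
    arr = np.asarray(rows, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        out = filter_low_expression(_expr([[0, 0, 0], [5, 5, 5]]), 1.0)
        assert out.gene_ids == ["G1"]

    def test_mean_exactly_one_retained(self):
        out = filter_low_expression(_expr([[1.0, 1.0, 1.0]]), 1.0)
        assert out.gene_ids == ["G0"]

    def test_three_gene_means(self):
        out = filter_low_expression(
            _expr([[0.5, 0.5], [1.0, 1.0], [10, 10]]), 1.0)
        assert out.gene_ids == ["G1", "G2"]

    def test_log_input_rejected(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0]], index=["G0"],
                                          columns=["S0"]),
                             log_transformed=True)
        with pytest.raises(ValidationError):
            filter_low_expression(m, 1.0)


class TestSignedFoldChange:
    @pytest.mark.parametrize("a,b,expected", [
        (3.0, 3.0, 1.0),
        (2.0, 1.0, 2.0),
        (1.0, 2.0, -2.0),
        (3.0, 7.5, -2.5),
    ])
    def test_values(self, a, b, expected):
        assert signed_fold_change(a, b) == pytest.approx(expected)

    def test_both_zero_errors(self):
        with pytest.raises(ValidationError):
            signed_fold_change(0.0, 0.0)

    def test_magnitude_at_least_one(self, rng):
        a, b = rng.random(200) * 10 + 0.01, rng.random(200) * 10 + 0.01
        assert (np.abs(signed_fold_change(a, b)) >= 1).all()

    def test_scale_invariant_without_pseudocount(self, rng):
        a, b = rng.random(50) + 0.1, rng.random(50) + 0.1
        np.testing.assert_allclose(signed_fold_change(2 * a, 2 * b),
                                   signed_fold_change(a, b))


class TestRegularizedT:
    def test_prior_zero_equals_plain_t(self, rng):
        a = rng.normal(0, 1, size=(50, 8))
        b = rng.normal(0.5, 1.3, size=(50, 6))
        t, df, p = regularized_t(a, b, np.ones(50), np.ones(50), prior_df=0)
        ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-12)
        assert (df == a.shape[1] + b.shape[1] - 2).all()

    def test_identical_groups_null(self):
        x = np.array([[1.0, 2.0, 3.0]])
        t, df, p = regularized_t(x, x, 0.5, 0.5, prior_df=4)
        assert t[0] == 0.0 and p[0] == pytest.approx(1.0)

    def test_hand_computed_posterior_variance(self):
        """{1,2,3} vs {4,5,6}, background SD = sample SD (=1), prior_df = 4:
        direct evaluation of the shrinkage formula."""
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0])
        prior_df, n = 4, 3
        # per-group: v = (4*1 + 2*1) / (4 + 3 - 1) = 1
        v = (prior_df * 1.0 + (n - 1) * 1.0) / (prior_df + n - 1)
        w = prior_df + n - 1
        pooled = (w * v + w * v) / (2 * w)
        se = np.sqrt(pooled * (1 / 3 + 1 / 3))
        expected_t = (2.0 - 5.0) / se
        expected_df = 3 + 3 - 2 + 2 * prior_df
        expected_p = 2 * stats.t.sf(abs(expected_t), expected_df)
        t, df, p = regularized_t(a[None, :], b[None, :], 1.0, 1.0, prior_df=4)
        assert t[0] == pytest.approx(expected_t, rel=1e-12)
        assert df[0] == expected_df
        assert p[0] == pytest.approx(expected_p, rel=1e-12)

    def test_degenerate_unequal_means(self):
        t, df, p = regularized_t(np.array([[1.0, 1.0]]), np.array([[2.0, 2.0]]),
                                 0.0, 0.0, prior_df=0)
        assert np.isinf(t[0]) and p[0] == 0.0

    def test_shift_invariance_on_log_scale(self, rng):
        """Doubling all TPM shifts log2 values by 1 and leaves t unchanged."""
        a = rng.normal(3, 1, size=(20, 10))
        b = rng.normal(3, 1, size=(20, 10))
        t1, _, _ = regularized_t(a, b, 1.0, 1.0, prior_df=6)
        t2, _, _ = regularized_t(a + 1, b + 1, 1.0, 1.0, prior_df=6)
        np.testing.assert_allclose(t1, t2, rtol=1e-12)

    def test_prior_zero_needs_two_obs(self):
        with pytest.raises(ValidationError):
            regularized_t(np.array([[1.0]]), np.array([[1.0, 2.0]]),
                          1.0, 1.0, prior_df=0)


class TestBackgroundSD:
    def test_homoscedastic_genes(self):
        base = np.array([1.0, 2.0, 4.0])  # variance 7/3 for every row
        rows = [base + shift for shift in (0.0, 1.0, 2.0, 5.0, 9.0)]
        df = pd.DataFrame(rows, index=[f"G{i}" for i in range(5)])
        bg = estimate_background_sd(df, 3)
        np.testing.assert_allclose(bg.to_numpy(),
                                   np.sqrt(base.var(ddof=1)), rtol=1e-12)

    def test_global_window_pools_everything(self, rng):
        df = pd.DataFrame(rng.normal(size=(7, 5)))
        bg = estimate_background_sd(df, 7)
        assert np.ptp(bg.to_numpy()) == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(
            bg.iloc[0], np.sqrt(df.var(axis=1, ddof=1).mean()), rtol=1e-12)

    def test_center_gene_window_pooling(self):
        # five genes, means strictly increasing with row index
        rows = [[0, 0, 0.1], [1, 1, 1.3], [2, 2, 2.9], [3, 3, 4.1], [4, 4, 6.0]]
        df = pd.DataFrame(np.array(rows, dtype=float),
                          index=[f"G{i}" for i in range(5)])
        bg = estimate_background_sd(df, 3)
        window_vars = df.var(axis=1, ddof=1).iloc[1:4]
        assert bg["G2"] == pytest.approx(np.sqrt(window_vars.mean()))

    def test_too_few_genes(self, rng):
        with pytest.raises(ValidationError):
            estimate_background_sd(pd.DataFrame(rng.normal(size=(2, 4))), 3)


class TestBHFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_hand_step_up(self, rng):
        p = rng.random(37)
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            hand[idx] = running
        np.testing.assert_allclose(bh_fdr(p), hand, rtol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.permutations(list(range(8))))
    def test_permutation_equivariant(self, perm):
        p = np.linspace(0.001, 0.9, 8)
        perm = np.array(perm)
        np.testing.assert_allclose(bh_fdr(p[perm]), bh_fdr(p)[perm])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(100)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])


class TestCallDegs:
    def _table(self, fdr, fc):
        return pd.DataFrame({"gene": ["g"], "fdr": [fdr], "fc_signed": [fc]})

    @pytest.mark.parametrize("fdr,fc,expected", [
        (0.04, 1.6, "up"),
        (0.04, 1.4, "ns"),
        (0.06, 3.0, "ns"),
        (0.04, 1.5, "up"),     # |FC| boundary is inclusive
        (0.04, -1.5, "down"),
        (0.05, 1.6, "ns"),     # FDR boundary is strict
    ])
    def test_boundaries(self, fdr, fc, expected):
        out = call_degs(self._table(fdr, fc), 0.05, 1.5)
        assert out.at[0, "direction"] == expected

    def test_monotone_in_thresholds(self, rng):
        table = pd.DataFrame({"gene": [f"g{i}" for i in range(100)],
                              "fdr": rng.random(100),
                              "fc_signed": rng.normal(0, 3, 100)})
        strict = (call_degs(table, 0.01, 2.0)["direction"] != "ns").sum()
        loose = (call_degs(table, 0.10, 1.2)["direction"] != "ns").sum()
        assert loose >= strict

    def test_geo_profile_logfc_cutoff(self):
        # |log2 FC| > 1 means |FC| > 2 strictly
        t = pd.DataFrame({"gene": ["a", "b"], "fdr": [0.01, 0.01],
                          "fc_signed": [2.0, 2.1]})
        out = call_degs_geo(t, 0.05, 1.0)
        assert list(out["direction"]) == ["ns", "up"]


class TestRecurrence:
    def _cohorts(self, n_called, n_total=11, direction="up"):
        cohorts = {}
        for i in range(n_total):
            d = direction if i < n_called else "ns"
            cohorts[f"C{i}"] = pd.DataFrame({"gene": ["g"], "direction": [d]})
        return cohorts

    def test_nine_of_eleven_retained(self):
        assert recurrence_filter(self._cohorts(9), 8) == ["g"]

    def test_seven_of_eleven_dropped(self):
        assert recurrence_filter(self._cohorts(7), 8) == []

    def test_min_one(self):
        assert recurrence_filter(self._cohorts(1), 1) == ["g"]

    def test_min_exceeds_cohorts(self):
        with pytest.raises(ValidationError):
            recurrence_filter(self._cohorts(1, n_total=3), 8)

    def test_direction_agnostic_by_default(self):
        cohorts = {f"C{i}": pd.DataFrame(
            {"gene": ["g"], "direction": ["up" if i % 2 else "down"]})
            for i in range(8)}
        assert recurrence_filter(cohorts, 8) == ["g"]
        assert recurrence_filter(cohorts, 8, consistent_direction=True) == []


class TestRestrictToMetabolic:
    def _results(self):
        return pd.DataFrame({"gene": [f"G{i}" for i in range(8)]
                             + ["ACLY", "DNMT3B"]})

    def test_subset(self):
        out = restrict_to_metabolic(self._results(), ["ACLY", "DNMT3B"])
        assert sorted(out["gene"]) == ["ACLY", "DNMT3B"]

    def test_unmatched_reported_not_error(self):
        out = restrict_to_metabolic(self._results(), ["ACLY", "NOPE"])
        assert out.attrs["unmatched"] == ["NOPE"]
        assert list(out["gene"]) == ["ACLY"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            restrict_to_metabolic(self._results(), [])

    def test_empty_intersection_ok(self):
        out = restrict_to_metabolic(self._results(), ["ZZZ"])
        assert out.empty


class TestDifferentialExpressionModel:
    def test_planted_genes_recovered(self, small_cohort):
        res = em.DifferentialExpression(small_cohort.expression,
                                        small_cohort.annotation).fit()
        truth = small_cohort.truth.de_genes.set_index("gene")["true_fc"]
        table = res.table.set_index("gene")
        hits = 0
        for gene, fc in truth.items():
            if gene in table.index:
                d = table.at[gene, "direction"]
                hits += (fc > 0 and d == "up") or (fc < 0 and d == "down")
        assert hits / len(truth) >= 0.9

    def test_sample_order_invariance(self, small_cohort, rng):
        expr = small_cohort.expression
        perm = list(rng.permutation(expr.sample_ids))
        res1 = em.DifferentialExpression(expr, small_cohort.annotation).fit()
        res2 = em.DifferentialExpression(expr.subset_samples(perm),
                                         small_cohort.annotation).fit()
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_fdr_at_least_p(self, small_cohort):
        res = em.DifferentialExpression(small_cohort.expression,
                                        small_cohort.annotation).fit()
        assert (res.table["fdr"] >= res.table["p"] - 1e-15).all()
        assert (np.abs(res.table["fc_signed"]) >= 1).all()

    def test_summary_mentions_counts(self, small_cohort):
        res = em.DifferentialExpression(small_cohort.expression,
                                        small_cohort.annotation).fit()
        assert "up:" in res.summary()
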