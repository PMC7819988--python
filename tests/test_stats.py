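"""Differential statistics, FDR control, correlation and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from msimet.preprocess import FeatureMatrix
from msimet.stats import (
    adjust_benjamini_yekutieli,
    adjust_pvalues,
    differential_analysis,
    differential_test,
    hierarchical_cluster,
    log_transform,
    spearman_matrix,
)


def make_matrix(values, groups=None, ages=None, log=True):
    values = np.atleast_2d(np.asarray(values, float))
    n = values.shape[1]
    sample_ids = [f"S{i}" for i in range(n)]
    if groups is None:
        groups = ["control"] * (n // 2) + ["patient"] * (n - n // 2)
    if ages is None:
        ages = [40.0] * (n // 2) + [6.0] * (n - n // 2)
    return FeatureMatrix(
        intensities=pd.DataFrame(
            values,
            index=pd.Index([f"f{i}" for i in range(len(values))], name="feature"),
            columns=sample_ids,
        ),
        features=pd.DataFrame(
            {"mz": 500.0 + np.arange(len(values)), "mode": "positive"},
            index=pd.Index([f"f{i}" for i in range(len(values))], name="feature"),
        ),
        samples=pd.DataFrame(
            {"group": groups, "age": ages}, index=pd.Index(sample_ids, name="sample")
        ),
        log=log,
    )


class TestLogTransform:
    def test_natural_log_cells(self):
        fm = make_matrix([[np.e, 1.0, 4.0, 4.0]], log=False)
        out = log_transform(fm)
        assert out.log
        np.testing.assert_allclose(
            out.intensities.to_numpy(), [[1.0, 0.0, np.log(4), np.log(4)]]
        )

    def test_zero_variance_feature_preserved(self):
        fm = make_matrix([[2.0, 2.0, 2.0, 2.0]], log=False)
        assert log_transform(fm).intensities.std(axis=1).iloc[0] == 0.0

    def test_non_positive_cell_names_location(self):
        fm = make_matrix([[1.0, 0.0, 2.0, 3.0]], log=False)
        with pytest.raises(ValueError, match="'f0'.*'S1'"):
            log_transform(fm)

    def test_double_log_rejected(self):
        with pytest.raises(ValueError):
            log_transform(make_matrix([[1.0, 1.0]], log=True))


class TestDifferentialTest:
    def random_matrix(self, seed=0, n_features=12, effect=0.0):
        rng = np.random.default_rng(seed)
        groups = ["control"] * 9 + ["patient"] * 9
        ages = np.r_[rng.uniform(28, 58, 9), rng.normal(5.5, 1.9, 9)]
        y = rng.normal(9.0, 0.3, size=(n_features, 18))
        y[: n_features // 2, 9:] += effect
        return make_matrix(y, groups=groups, ages=ages.tolist())

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        fm = self.random_matrix(seed=3, effect=0.4)
        res = differential_test(fm)
        X = sm.add_constant(
            pd.DataFrame(
                {
                    "g": (fm.samples["group"] == "patient").astype(float),
                    "age": fm.samples["age"],
                }
            )
        )
        for fid in fm.intensities.index:
            fit = sm.OLS(fm.intensities.loc[fid].to_numpy(), X.to_numpy()).fit()
            assert res.loc[fid, "estimate"] == pytest.approx(fit.params[1], rel=1e-10)
            assert res.loc[fid, "t"] == pytest.approx(fit.tvalues[1], rel=1e-10)
            assert res.loc[fid, "p"] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_without_covariate_equals_pooled_t_test(self):
        fm = self.random_matrix(seed=4, effect=0.5)
        res = differential_test(fm, covariates=())
        pat = fm.intensities.loc[:, (fm.samples["group"] == "patient").to_numpy()]
        ctl = fm.intensities.loc[:, (fm.samples["group"] == "control").to_numpy()]
        t = sps.ttest_ind(pat, ctl, axis=1)
        np.testing.assert_allclose(res["t"], t.statistic, rtol=1e-10)
        np.testing.assert_allclose(res["p"], t.pvalue, rtol=1e-8)

    def test_type_one_error_calibrated(self):
        # 2000 null features, balanced ages: empirical alpha within the
        # binomial band around 0.05
        rng = np.random.default_rng(12)
        groups = ["control"] * 9 + ["patient"] * 9
        ages = rng.uniform(28, 58, 18).tolist()
        y = rng.normal(0.0, 1.0, size=(2000, 18))
        res = differential_test(make_matrix(y, groups=groups, ages=ages))
        rate = float((res["p"] < 0.05).mean())
        band = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert rate == pytest.approx(0.05, abs=band)

    def test_constant_feature_gives_null_result(self):
        fm = make_matrix([[5.0] * 18], groups=["control"] * 9 + ["patient"] * 9,
                         ages=list(range(18)))
        res = differential_test(fm)
        assert res["estimate"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_singular_design_flags_missing(self):
        fm = make_matrix([[1.0, 2.0, 3.0, 2.5, 1.5, 2.2]],
                         groups=["control"] * 3 + ["patient"] * 3,
                         ages=[1, 1, 1, 2, 2, 2])  # age == group indicator
        with pytest.warns(UserWarning, match="singular"):
            res = differential_test(fm)
        assert res["p"].isna().all()

    def test_requires_two_groups_with_replicates(self):
        with pytest.raises(ValueError):
            differential_test(make_matrix([[1, 2, 3]], groups=["a", "a", "a"],
                                          ages=[1, 2, 3]))


class TestBenjaminiYekutieli:
    def test_hand_computed_three_vector(self):
        # BH on (0.01, 0.02, 0.04) is (0.03, 0.03, 0.04); BY inflates by
        # c(3) = 11/6
        adj = adjust_benjamini_yekutieli([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.055, 0.055, 11 / 6 * 0.04], rtol=1e-12)

    def test_single_p_unchanged(self):
        assert adjust_benjamini_yekutieli([0.05])[0] == pytest.approx(0.05)

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(adjust_benjamini_yekutieli([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_and_is_excluded_from_m(self):
        adj = adjust_pvalues([0.01, np.nan, 0.02, 0.04], method="by")
        assert np.isnan(adj[1])
        np.testing.assert_allclose(
            adj[[0, 2, 3]], adjust_benjamini_yekutieli([0.01, 0.02, 0.04])
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_benjamini_yekutieli([0.5, 1.5])
        with pytest.raises(ValueError):
            adjust_pvalues([0.1], method="holm")

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_by_dominates_bh_and_raw(self, ps):
        by = adjust_pvalues(ps, method="by")
        bh = adjust_pvalues(ps, method="bh")
        assert np.all(by >= bh - 1e-12)
        assert np.all(by >= np.asarray(ps) - 1e-12)
        assert np.all(by <= 1.0)

    def test_matches_explicit_step_up(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 25)
        m = len(p)
        cm = np.sum(1.0 / np.arange(1, m + 1))
        order = np.argsort(p)
        stepped = p[order] * m * cm / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adjust_benjamini_yekutieli(p), expected, rtol=1e-12)


class TestSpearman:
    def test_diagonal_and_monotone_pairs(self):
        fm = make_matrix([[1, 2, 3, 4], [10, 9, 3, 1], [2, 4, 9, 11]])
        rho = spearman_matrix(fm)
        assert np.allclose(np.diag(rho), 1.0)
        assert rho.loc["f0", "f1"] == pytest.approx(-1.0)
        assert rho.loc["f0", "f2"] == pytest.approx(1.0)
        assert rho.equals(rho.T)

    def test_matches_rank_formula_on_five_samples(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            y = rng.normal(size=(4, 5))
            rho = spearman_matrix(make_matrix(y))
            for i in range(4):
                for j in range(4):
                    ri = sps.rankdata(y[i])
                    rj = sps.rankdata(y[j])
                    expected = np.corrcoef(ri, rj)[0, 1]
                    assert rho.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_feature_reported_missing(self):
        fm = make_matrix([[1, 2, 3, 4], [5, 5, 5, 5]])
        rho = spearman_matrix(fm)
        assert rho.loc["f1"].isna().all()
        assert rho["f1"].isna().all()
        assert rho.loc["f0", "f0"] == 1.0

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            spearman_matrix(make_matrix([[1, 2], [3, 4]]))


class TestHierarchicalCluster:
    def test_separated_groups_split_at_k2(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0.0, 0.1, size=(10, 12))
        y[:, 6:] += 5.0
        groups = ["control"] * 6 + ["patient"] * 6
        fm = make_matrix(y, groups=groups, ages=[30] * 6 + [6] * 6)
        cl = hierarchical_cluster(fm)
        from sklearn.metrics import adjusted_rand_score

        true = [fm.samples.loc[s, "group"] for s in cl.sample_ids]
        assert adjusted_rand_score(true, cl.labels) == 1.0
        assert np.all(np.diff(cl.heights) >= -1e-12)

    def test_duplicate_samples_merge_at_height_zero(self):
        fm = make_matrix([[1.0, 1.0, 5.0, 6.0], [2.0, 2.0, 7.0, 8.0]])
        cl = hierarchical_cluster(fm)
        assert cl.heights[0] == 0.0

    def test_single_constant_feature_all_heights_zero(self):
        fm = make_matrix([[3.0, 3.0, 3.0, 3.0]])
        cl = hierarchical_cluster(fm)
        assert np.all(cl.heights == 0.0)

    def test_newick_is_parseable_with_all_leaves(self):
        import dendropy

        fm = make_matrix(np.random.default_rng(0).normal(size=(3, 6)))
        cl = hierarchical_cluster(fm)
        tree = dendropy.Tree.get(data=cl.to_newick(), schema="newick")
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        assert leaves == set(cl.sample_ids)

    def test_requires_two_samples(self):
        fm = make_matrix([[1.0]], groups=["control"], ages=[1.0])
        with pytest.raises(ValueError):
            hierarchical_cluster(fm)


class TestDifferentialAnalysis:
    def test_flags_and_directions(self):
        rng = np.random.default_rng(9)
        groups = ["control"] * 9 + ["patient"] * 9
        ages = rng.uniform(28, 58, 18).tolist()
        y = rng.normal(0.0, 0.1, size=(6, 18))
        y[0, 9:] += 3.0
        y[1, 9:] -= 3.0
        res = differential_analysis(make_matrix(y, groups=groups, ages=ages))
        assert bool(res.loc["f0", "significant"]) and res.loc["f0", "direction"] == "up"
        assert bool(res.loc["f1", "significant"]) and res.loc["f1", "direction"] == "down"
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        assert res["p_adj"].between(0, 1).all()
        assert not res.loc["f2":, "significant"].any()

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            differential_analysis(make_matrix([[1.0] * 6]), alpha=1.5)
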