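"""Core-vs-entire representativeness metrics, diversity, tests, and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import salicore as sc


def _table(values, traits=None):
    values = np.asarray(values, dtype=float)
    traits = traits or [f"T{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=traits,
                      index=[f"g{i}" for i in range(len(values))])
    return sc.TraitTable(df, {t: "positive" for t in traits})


class TestRepresentativenessMetrics:
    def test_core_equal_entire_is_the_identity(self, panel300):
        report = sc.representativeness_metrics(panel300, panel300)
        pt = report.per_trait
        np.testing.assert_allclose(pt["md_pct"], 0.0, atol=1e-10)
        np.testing.assert_allclose(pt["vd_pct"], 0.0, atol=1e-10)
        np.testing.assert_allclose(pt["cr_pct"], 100.0, atol=1e-10)
        np.testing.assert_allclose(pt["vr_pct"], 100.0, atol=1e-10)
        assert (pt[["p_mean", "p_levene", "p_wilcoxon"]] > 0.99).all().all()
        assert report.verdicts["md_below_20"] and report.verdicts["cr_above_80"]

    def test_toy_metrics_by_direct_arithmetic(self):
        entire = _table(np.arange(1.0, 11.0).reshape(-1, 1), ["X"])
        core = entire.subset(["g0", "g4", "g9"])  # values 1, 5, 10
        report = sc.representativeness_metrics(entire, core)
        row = report.per_trait.loc["X"]
        e, c = np.arange(1.0, 11.0), np.array([1.0, 5.0, 10.0])
        cv = lambda v: v.std(ddof=1) / v.mean()
        assert row["md_pct"] == pytest.approx(abs(c.mean() - e.mean()) / e.mean() * 100)
        assert row["cr_pct"] == pytest.approx(100.0)
        assert row["vr_pct"] == pytest.approx(cv(c) / cv(e) * 100)
        assert row["vd_pct"] == pytest.approx((cv(c) - cv(e)) / cv(c) * 100)

    def test_strict_subset_cannot_exceed_full_range(self, panel300):
        core = panel300.subset(panel300.genotype_ids[:60])
        report = sc.representativeness_metrics(panel300, core)
        assert (report.per_trait["cr_pct"] <= 100.0 + 1e-12).all()

    def test_vd_vr_identity_whenever_core_more_variable(self, panel300):
        core = panel300.subset(panel300.genotype_ids[::5])
        report = sc.representativeness_metrics(panel300, core)
        pt = report.per_trait
        more_variable = pt["vr_pct"] > 100
        lhs = pt.loc[more_variable, "vd_pct"]
        rhs = (pt.loc[more_variable, "vr_pct"] - 100) / pt.loc[more_variable, "vr_pct"] * 100
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestShannonWeaver:
    def test_identical_values_have_zero_diversity(self):
        assert sc.shannon_weaver([2.0] * 50) == 0.0

    def test_all_distinct_values_reach_log_n(self):
        h = sc.shannon_weaver(np.arange(318.0))
        assert h == pytest.approx(np.log(318))

    def test_closed_form_frequencies(self):
        h = sc.shannon_weaver([1.0, 1.0, 2.0, 3.0])  # p = 1/2, 1/4, 1/4
        assert h == pytest.approx(1.0397, abs=1e-4)

    def test_bounded_by_log_sample_size(self, rng):
        v = rng.integers(0, 5, size=40).astype(float)
        assert sc.shannon_weaver(v) <= np.log(40) + 1e-12

    def test_fixed_bins_scheme(self, rng):
        v = rng.uniform(size=200)
        h = sc.shannon_weaver(v, scheme="fixed_bins", bins=10)
        assert 0 < h <= np.log(10) + 1e-12


class TestDistributionTests:
    def test_identical_samples_give_p_one(self, rng):
        v = rng.normal(size=50)
        out = sc.distribution_tests(v, v)
        assert out["p_mean"] == pytest.approx(1.0, abs=1e-9)
        assert out["p_levene"] == pytest.approx(1.0, abs=1e-9)
        assert out["p_wilcoxon"] == pytest.approx(1.0, abs=0.01)

    def test_mean_test_equals_pooled_t(self, rng):
        a, b = rng.normal(size=60), rng.normal(0.3, 1, size=25)
        out = sc.distribution_tests(a, b)
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert out["p_mean"] == pytest.approx(t_p, abs=1e-9)

    def test_null_pvalues_are_uniform(self):
        """Under equal populations, each test's p-values pass a KS uniformity check."""
        rng = np.random.default_rng(1234)
        ps = {"p_mean": [], "p_levene": [], "p_wilcoxon": []}
        for _ in range(500):
            e = rng.normal(size=300)
            c = rng.normal(size=64)
            out = sc.distribution_tests(e, c)
            for key in ps:
                ps[key].append(out[key])
        for key, values in ps.items():
            assert stats.kstest(values, "uniform").pvalue > 0.01, key

    def test_five_sd_shift_is_detected(self, rng):
        a = rng.normal(0, 1, size=100)
        b = rng.normal(5, 1, size=40)
        assert sc.distribution_tests(a, b)["p_mean"] < 1e-6


class TestCorrelationPreservation:
    @staticmethod
    def _correlated_pair(n, r, rng):
        cov = np.array([[1, r], [r, 1]])
        return rng.multivariate_normal([0, 0], cov, size=n)

    def test_core_equal_entire_has_zero_discrepancy(self, panel300):
        cmp_ = sc.correlation_preservation(panel300, panel300)
        assert cmp_.max_abs_difference == pytest.approx(0.0, abs=1e-12)
        assert cmp_.sign_agreement == 1.0

    def test_random_half_estimates_planted_correlation(self, rng):
        entire = _table(self._correlated_pair(120, 0.7, rng))
        core = entire.subset(list(rng.choice(entire.genotype_ids, 60, replace=False)))
        cmp_ = sc.correlation_preservation(entire, core)
        assert cmp_.entire_corr.iloc[0, 1] == pytest.approx(0.7, abs=0.15)
        assert cmp_.core_corr.iloc[0, 1] == pytest.approx(0.7, abs=0.15)

    def test_sign_agreement_on_strong_structure(self, rng):
        z = rng.multivariate_normal(
            np.zeros(3), np.array([[1, 0.6, -0.5], [0.6, 1, -0.45], [-0.5, -0.45, 1]]),
            size=120)
        entire = _table(z)
        core = entire.subset(list(rng.choice(entire.genotype_ids, 60, replace=False)))
        assert sc.correlation_preservation(entire, core).sign_agreement == 1.0

    def test_constant_column_is_masked(self, rng):
        values = np.column_stack([rng.normal(size=30), np.full(30, 3.0)])
        table = _table(values)
        cmp_ = sc.correlation_preservation(table, table)
        assert np.isnan(cmp_.entire_corr.iloc[0, 1])


class TestPCACompare:
    def test_two_trait_closed_form(self, rng):
        values = TestCorrelationPreservation._correlated_pair(5000, 0.9, rng)
        table = _table(values)
        out = sc.pca_compare(table, table, n_components=2)
        # correlation-matrix PCA of 2 traits: PC1 share = (1+r)/2
        r = table.data.corr().iloc[0, 1]
        assert out["entire"].variance_explained_pct[0] == pytest.approx(
            (1 + r) / 2 * 100, abs=1e-9)
        assert abs(out["entire"].variance_explained_pct[0] - 95.0) < 1.5

    def test_loadings_orthonormal_and_variance_ordered(self, panel300):
        out = sc.pca_compare(panel300, panel300, n_components=5)
        res = out["entire"]
        v = res.loadings.to_numpy()
        np.testing.assert_allclose(v.T @ v, np.eye(5), atol=1e-9)
        assert (np.diff(res.variance_explained_pct) <= 1e-12).all()
        assert res.cumulative_pct[-1] <= 100 + 1e-9

    def test_invariant_to_affine_trait_rescaling(self, panel300, rng):
        scaled = sc.TraitTable(panel300.data.copy(), dict(panel300.directions))
        scaled.data["SNC"] = scaled.data["SNC"] * 3.7 + 12.0
        a = sc.pca_compare(panel300, panel300)["entire"]
        b = sc.pca_compare(scaled, scaled)["entire"]
        np.testing.assert_allclose(a.variance_explained_pct, b.variance_explained_pct,
                                   atol=1e-9)

    def test_excess_components_truncated_with_warning(self, rng):
        table = _table(rng.normal(size=(30, 3)))
        with pytest.warns(UserWarning, match="truncated"):
            out = sc.pca_compare(table, table, n_components=7)
        assert out["entire"].loadings.shape[1] == 3


def test_diversity_loss_from_mean_indices():
    assert sc.diversity_loss_pct(5.72, 4.10) == pytest.approx(28.32, abs=0.005)
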