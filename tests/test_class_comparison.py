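import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from mirtlda.class_comparison import (
    RvmHyperparameters,
    bh_fdr,
    compare_classes,
    fit_rvm,
    global_permutation_test,
    multiclass_f_test,
    multivariate_permutation_select,
    pooled_t_stats,
    rvm_shrunken_variance,
    rvm_t,
    two_sample_t,
    univariate_permutation_p,
)
from mirtlda.errors import ValidationError


class TestTwoSampleT:
    def test_closed_form_example(self):
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742, abs=1e-4)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_equal_means_give_zero_t(self):
        t, _ = two_sample_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.normal(size=rng.integers(3, 12))
            y = rng.normal(loc=rng.normal(), size=rng.integers(3, 12))
            t, p = two_sample_t(x, y)
            ref = stats.ttest_ind(x, y, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_zero_variance_flagged_p1(self):
        t, p = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)


class TestRvm:
    def test_parameter_recovery_simulation(self):
        rng = np.random.default_rng(42)
        a_true, b_true, n = 3.0, 1.5, 18
        prec = rng.gamma(a_true, b_true, size=5000)
        s2 = (1.0 / prec) * rng.chisquare(n, size=5000) / n
        h = fit_rvm(s2, np.full(5000, float(n)))
        assert h.a == pytest.approx(a_true, rel=0.10)
        assert h.b == pytest.approx(b_true, rel=0.10)

    def test_equal_variances_drive_total_shrinkage(self):
        h = fit_rvm(np.full(200, 0.25), np.full(200, 10.0))
        shrunk = rvm_shrunken_variance(np.array([0.1, 0.25, 0.9]), 10.0, h)
        # huge prior weight: every shrunken variance collapses to the common value
        assert np.ptp(shrunk) / np.mean(shrunk) < 0.01

    def test_heavy_tailed_variances_fit_finite(self):
        rng = np.random.default_rng(5)
        s2 = stats.lomax.rvs(0.8, size=500, random_state=rng) + 1e-3
        h = fit_rvm(s2, np.full(500, 8.0))
        assert np.isfinite(h.a) and np.isfinite(h.b) and h.a > 0

    def test_vanishing_prior_recovers_plain_t(self):
        hyper = RvmHyperparameters(a=1e-9, b=1e12, log_likelihood=0.0)
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=8)
        t_r, p_r = rvm_t(x, y, hyper)
        t0, p0 = two_sample_t(x, y)
        assert t_r == pytest.approx(t0, abs=1e-8)
        assert p_r == pytest.approx(p0, abs=1e-8)

    def test_small_n_power_gain_over_plain_t(self):
        """With a planted 1-cycle effect at n=10 per group, variance
        sharing should detect at least as many assays as the plain t."""
        rng = np.random.default_rng(8)
        G, n = 2000, 10
        prec = rng.gamma(3.0, 1.5, size=G)
        X = rng.normal(size=(G, 2 * n)) * np.sqrt(1.0 / prec)[:, None]
        X[:, :n] += 1.0
        i1, i2 = np.arange(n), np.arange(n, 2 * n)
        _, p_t, df, sp2, *_ = pooled_t_stats(X, i1, i2)
        h = fit_rvm(sp2, df)
        from mirtlda.class_comparison import rvm_t_stats

        _, p_r, _ = rvm_t_stats(X, i1, i2, h)
        assert (p_r < 0.05).mean() >= (p_t < 0.05).mean()


class TestBhFdr:
    def _oracle(self, p):
        """Brute-force step-up: adj_(i) = min over j>=i of p_(j)*m/j."""
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            adj[order[rank]] = running
        return adj

    def test_simple_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            np.testing.assert_allclose(bh_fdr(p), self._oracle(p), atol=1e-12)

    def test_invariant_under_input_permutation(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=31)
        perm = rng.permutation(31)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-14)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])


class TestUnivariatePermutation:
    def test_exhaustive_matches_enumeration_oracle(self):
        """3 vs 3: all C(6,3)=20 assignments enumerated; p must equal an
        independent scipy-based enumeration exactly."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 6))
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        p = univariate_permutation_p(X, labels, B=1000, seed=0)

        def oracle(row):
            t_obs = abs(stats.ttest_ind(row[:3], row[3:], equal_var=True).statistic)
            count = 0
            for combo in itertools.combinations(range(6), 3):
                rest = [i for i in range(6) if i not in combo]
                t_b = abs(
                    stats.ttest_ind(row[list(combo)], row[rest], equal_var=True).statistic
                )
                count += t_b >= t_obs - 1e-12
            return count / comb(6, 3)

        expected = np.array([oracle(X[i]) for i in range(10)])
        np.testing.assert_allclose(p, expected, atol=1e-12)

    def test_well_separated_3v3_attains_minimum_p(self):
        X = np.array([[0.0, 0.1, -0.1, 5.0, 5.1, 4.9]])
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        assert univariate_permutation_p(X, labels, B=100)[0] == pytest.approx(0.1)

    def test_zero_statistic_gives_p_one(self):
        X = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        assert univariate_permutation_p(X, labels, B=100)[0] == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 16))
        labels = np.array(["a"] * 8 + ["b"] * 8, dtype=object)
        p1 = univariate_permutation_p(X, labels, B=200, seed=7)
        p2 = univariate_permutation_p(X, labels, B=200, seed=7)
        np.testing.assert_array_equal(p1, p2)
        assert np.all(p1 >= 1.0 / 201.0)


class TestGlobalPermutation:
    def test_b1_p_is_zero_or_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 12))
        labels = np.array(["a"] * 6 + ["b"] * 6, dtype=object)
        assert global_permutation_test(X, labels, B=1, seed=1) in (0.0, 1.0)

    def test_planted_signal_detected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(666, 20))
        X[:50, :10] += 3.0
        labels = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        p = global_permutation_test(X, labels, alpha=0.001, B=199, seed=2)
        assert p <= 1.0 / 199.0

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(2)
        ps = []
        for i in range(20):
            X = rng.normal(size=(100, 12))
            labels = np.array(["a"] * 6 + ["b"] * 6, dtype=object)
            ps.append(global_permutation_test(X, labels, alpha=0.05, B=49, seed=i))
        assert 0.2 < np.mean(ps) < 0.8


class TestMultivariateSelection:
    def test_threshold_monotonicity(self, two_group_dataset):
        ctm, annotations, _ = two_group_dataset
        from mirtlda.normalization import normalize

        norm = normalize(ctm)
        X = -norm.values_nan()
        labels = np.array([a.group for a in annotations], dtype=object)
        res = multivariate_permutation_select(
            X, labels, B=100, seed=3, assay_ids=norm.assay_ids
        )
        assert len(res.selected_assays) > 0
        _, _, df, sp2, *_ = pooled_t_stats(X, np.arange(10), np.arange(10, 20))
        h = fit_rvm(sp2, df)
        from mirtlda.class_comparison import rvm_t_stats

        p = rvm_t_stats(X, np.arange(10), np.arange(10, 20), h)[1]
        sel = set(res.selected_assays)
        p_sel = [p[i] for i, a in enumerate(norm.assay_ids) if a in sel]
        assert max(p_sel) <= res.p_cutoff + 1e-12

    def test_confidence_zero_uses_expected_count(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 20))
        X[:20, :10] += 3.0
        labels = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        res = multivariate_permutation_select(X, labels, confidence=0.0, B=100, seed=1)
        assert len(res.selected_assays) >= 18

    def test_insufficient_permutations_rejected(self):
        X = np.zeros((20, 8))
        labels = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        with pytest.raises(ValidationError):
            multivariate_permutation_select(X, labels, B=50)


class TestMulticlassF:
    def test_two_classes_f_equals_t_squared(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 14))
        labels = np.array(["a"] * 7 + ["b"] * 7, dtype=object)
        F, pF = multiclass_f_test(X, labels)
        t, pt, *_ = pooled_t_stats(X, np.arange(7), np.arange(7, 14))
        np.testing.assert_allclose(F, t**2, atol=1e-10)
        np.testing.assert_allclose(pF, pt, atol=1e-10)

    def test_matches_scipy_f_oneway_four_classes(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 26))
        labels = np.array(
            ["a"] * 8 + ["b"] * 8 + ["c"] * 5 + ["d"] * 5, dtype=object
        )
        F, p = multiclass_f_test(X, labels)
        groups = [X[:, labels == c] for c in ("a", "b", "c", "d")]
        ref = stats.f_oneway(*[g.T for g in groups])
        np.testing.assert_allclose(F, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-10)

    def test_singleton_class_contributes_between_term(self):
        x = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0, 10.0])
        labels = np.array(["a"] * 3 + ["b"] * 3 + ["c"], dtype=object)
        F, p = multiclass_f_test(x, labels)
        assert np.isfinite(F) and F > 0 and 0 < p < 1

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            multiclass_f_test(np.zeros((2, 4)), np.array(["a"] * 4))


class TestCompareClasses:
    def test_null_contrast_calibrated(self, study_norm, study_dataset):
        """Nevus 60 vs Nevus 30 carries no planted effect: roughly 5% of
        assays should reach p<0.05."""
        _, annotations, _ = study_dataset
        res = compare_classes(study_norm, annotations, ("Nevus 60", "Nevus 30"), mode="I")
        frac = np.mean([r.p < 0.05 for r in res])
        assert frac < 0.12

    def test_planted_effects_recovered_mode_I(self, study_norm, study_dataset):
        _, annotations, truth = study_dataset
        res = compare_classes(study_norm, annotations, ("Mel 60", "Mel 30"), mode="I")
        strong = set(truth.loc[truth.log2_effect.abs() >= 1.0, "assay_id"])
        sig = {r.assay_id for r in res if r.p < 0.05}
        assert len(strong & sig) / len(strong) >= 0.9

    def test_mode_II_reports_intensity_means_consistent_with_fc(
        self, study_norm, study_dataset
    ):
        _, annotations, _ = study_dataset
        res = compare_classes(study_norm, annotations, ("Mel 60", "Mel 30"), mode="II")
        for r in res[:20]:
            gm = r.class_means
            assert r.fc == pytest.approx(gm["Mel 60"] / gm["Mel 30"], rel=1e-10)

    def test_output_sorted_and_deterministic(self, study_norm, study_dataset):
        _, annotations, _ = study_dataset
        r1 = compare_classes(study_norm, annotations, ("Mel 60", "Mel 30"), mode="II",
                             n_permutations=50, seed=3)
        r2 = compare_classes(study_norm, annotations, ("Mel 60", "Mel 30"), mode="II",
                             n_permutations=50, seed=3)
        assert [r.assay_id for r in r1] == [r.assay_id for r in r2]
        assert [r.perm_p for r in r1] == [r.perm_p for r in r2]
        ps = [r.p for r in r1]
        assert ps == sorted(ps)

    def test_four_class_contrast_runs_f_test(self, study_norm, study_dataset):
        _, annotations, _ = study_dataset
        groups = {}
        for a in annotations:
            groups.setdefault(a.group, []).append(a.sample_id)
        res = compare_classes(study_norm, annotations, groups, mode="II")
        assert len(res) == len(study_norm.assay_ids)
        assert set(res[0].class_means) == set(groups)

    def test_empty_contrast_group_rejected(self, study_norm, study_dataset):
        _, annotations, _ = study_dataset
        sub = [a for a in annotations if a.group != "Nevus 60"]
        with pytest.raises(ValidationError):
            compare_classes(study_norm, sub, ("Nevus 60", "Mel 30"), mode="I")
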