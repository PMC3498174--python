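"""Profile statistics: norms, individual comparison, permutation inference."""

import numpy as np
import pytest

import tractprof as tp
from tractprof.stats import _pvalues_from_perm_stats, _two_group_permutations

COV = tp.smooth_node_covariance(100, sd=0.05, length_scale=10.0)


def _cohort(n, seed=0, mean=0.5, **kw):
    spec = tp.CohortSpec(
        n_subjects=n, mean_profile=np.full(100, mean), node_covariance=COV, seed=seed, **kw
    )
    return tp.simulate_profile_cohort(spec)


class TestStandardize:
    def test_identical_profiles_zero_sd(self):
        X = np.tile(np.linspace(0.3, 0.6, 100), (5, 1))
        norm = tp.standardize(X, metric="FA")
        assert np.allclose(norm.sd, 0.0)
        for q in (5, 25, 95):
            assert np.allclose(norm.percentiles[q], norm.mean)

    def test_large_cohort_recovers_truth(self):
        X, _ = _cohort(2000, seed=1)
        norm = tp.standardize(X, metric="FA")
        assert np.abs(norm.mean - 0.5).max() < 0.005
        assert np.abs(norm.sd - 0.05).max() < 0.005

    def test_band_nesting(self):
        X, _ = _cohort(200, seed=2)
        norm = tp.standardize(X, metric="FA")
        for lo, hi in [(5, 10), (10, 25), (25, 75), (75, 90), (90, 95)]:
            assert (norm.percentiles[lo] <= norm.percentiles[hi] + 1e-12).all()

    def test_ten_ninety_band_coverage(self):
        X, _ = _cohort(2000, seed=3)
        norm = tp.standardize(X, metric="FA")
        fresh, _ = _cohort(500, seed=4)
        inside = (fresh >= norm.percentiles[10]) & (fresh <= norm.percentiles[90])
        assert abs(inside.mean() - 0.80) < 0.03

    def test_single_subject_raises(self):
        with pytest.raises(ValueError, match="2 subjects"):
            tp.standardize(np.ones((1, 100)), metric="FA")


class TestCompareIndividual:
    def test_mean_profile_zero_z(self):
        X, _ = _cohort(100, seed=5)
        norm = tp.standardize(X, metric="FA")
        z, pct = tp.compare_individual(norm.mean, norm)
        assert np.abs(z).max() < 1e-12
        assert (np.abs(z) < 3 / np.sqrt(norm.n_subjects)).all()

    def test_one_sd_offset(self):
        X, _ = _cohort(100, seed=6)
        norm = tp.standardize(X, metric="FA")
        z, _ = tp.compare_individual(norm.mean + norm.sd, norm)
        assert np.allclose(z, 1.0, atol=1e-12)

    def test_planted_focal_deficit_localized(self):
        X, _ = _cohort(2000, seed=7)
        norm = tp.standardize(X, metric="FA")
        patient = norm.mean.copy()
        patient[40:61] -= 3 * norm.sd[40:61]
        z, _ = tp.compare_individual(patient, norm)
        hot = np.flatnonzero(np.abs(z) > 2)
        assert hot.min() >= 38 and hot.max() <= 62
        assert set(range(40, 61)) <= set(hot)

    def test_zero_sd_flagged(self):
        X = np.full((5, 100), 0.5)
        norm = tp.standardize(X, metric="FA")
        with pytest.warns(UserWarning, match="zero normative SD"):
            z, _ = tp.compare_individual(X[0] + 0.1, norm)
        assert np.isnan(z).all()


class TestFlagAbnormal:
    def _norm(self):
        X, _ = _cohort(500, seed=8)
        return tp.standardize(X, metric="FA")

    def test_inside_band_not_flagged(self):
        norm = self._norm()
        flagged, spans = tp.flag_abnormal(norm.mean, norm, band=(10, 90), min_run=10)
        assert not flagged and spans == []

    def test_long_excursion_flagged(self):
        norm = self._norm()
        patient = norm.mean.copy()
        patient[30:60] = norm.percentiles[5][30:60] - 0.1
        flagged, spans = tp.flag_abnormal(patient, norm, band=(5, 95), min_run=10)
        assert flagged and len(spans) == 1
        assert spans[0] == (30, 60)

    def test_single_node_excursion_ignored(self):
        norm = self._norm()
        patient = norm.mean.copy()
        patient[50] = norm.percentiles[95][50] + 1.0
        flagged, spans = tp.flag_abnormal(patient, norm, band=(5, 95), min_run=10)
        assert not flagged


class TestGroupTest:
    def test_identical_cohorts_zero_t(self):
        X, _ = _cohort(24, seed=9)
        res = tp.pointwise_group_test(X, X.copy(), nperm=200, rng_seed=0)
        assert np.allclose(res.statistic, 0.0)
        assert not res.significant.any()

    def test_planted_effect_localizes(self):
        effect = np.where((np.arange(100) >= 45) & (np.arange(100) <= 55), 0.05, 0.0)
        spec = tp.CohortSpec(
            n_subjects=48, mean_profile=np.full(100, 0.5), node_covariance=COV,
            group_effect=effect, seed=10,
        )
        X, meta = tp.simulate_profile_cohort(spec)
        res = tp.pointwise_group_test(X[meta["group"] == 0], X[meta["group"] == 1], nperm=1000, rng_seed=1)
        sig = np.flatnonzero(res.significant)
        assert sig.size > 0
        assert sig.min() >= 40 and sig.max() <= 60
        null_nodes = np.concatenate([np.arange(0, 40), np.arange(61, 100)])
        assert res.significant[null_nodes].mean() < 0.05

    def test_corrected_geq_uncorrected(self):
        X, _ = _cohort(20, seed=11)
        res = tp.pointwise_group_test(X[:10], X[10:], nperm=300, rng_seed=2)
        assert (res.p_corrected >= res.p_uncorrected - 1e-15).all()

    def test_exhaustive_enumeration_small_n(self):
        rng = np.random.default_rng(0)
        A, B = rng.normal(size=(3, 5)), rng.normal(size=(3, 5))
        perms = _two_group_permutations(3, 3, 100, rng)
        assert perms.shape[0] == 20  # C(6,3)
        assert perms[0, :3].all() and not perms[0, 3:].any()
        # all rows distinct
        assert len({tuple(r) for r in perms}) == 20

    def test_pooled_t_matches_scipy(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(1)
        A, B = rng.normal(0, 1, (12, 100)), rng.normal(0.3, 1, (14, 100))
        res = tp.pointwise_group_test(A, B, nperm=100, rng_seed=0)
        ref = ttest_ind(A, B, axis=0, equal_var=True).statistic
        assert np.allclose(res.statistic, ref, atol=1e-10)


class TestCorrelation:
    def test_perfect_node_correlation(self):
        X, _ = _cohort(20, seed=12)
        behavior = X[:, 30].copy()
        res = tp.pointwise_correlation(X, behavior, nperm=200, rng_seed=0)
        assert res.statistic[30] == pytest.approx(1.0, abs=1e-10)

    def test_null_behavior_fwer(self):
        hits = 0
        for i in range(200):
            X, _ = _cohort(26, seed=2000 + i)
            rng = np.random.default_rng(5000 + i)
            res = tp.pointwise_correlation(X, rng.normal(size=26), nperm=300, rng_seed=i)
            hits += int(res.significant.any())
        rate = hits / 200
        se = np.sqrt(0.05 * 0.95 / 200)
        assert rate <= 0.05 + 3 * se

    def test_generative_recovery_at_node_50(self):
        errs = []
        for i in range(10):
            X, meta = _cohort(
                26, seed=100 + i, behavior_slope=0.55,
                behavior_noise_sd=np.sqrt(1 - 0.55**2),
            )
            res = tp.pointwise_correlation(X, meta["behavior"], nperm=200, rng_seed=i)
            errs.append(abs(res.statistic[50] - 0.55))
        assert np.median(errs) < 0.15

    def test_partial_correlation_removes_confound(self):
        rng = np.random.default_rng(13)
        n = 40
        age = rng.normal(0, 1, n)
        X = 0.5 + 0.05 * age[:, None] + rng.normal(0, 0.01, (n, 100))
        behavior = 2.0 * age + rng.normal(0, 0.1, n)
        raw = tp.pointwise_correlation(X, behavior, nperm=200, rng_seed=0)
        part = tp.pointwise_correlation(X, behavior, nperm=200, rng_seed=0, partial=age)
        assert np.abs(raw.statistic).mean() > 0.8  # confounded
        assert np.abs(part.statistic).mean() < 0.5  # mostly explained by age

    def test_zero_variance_behavior_raises(self):
        X, _ = _cohort(10, seed=14)
        with pytest.raises(ValueError, match="variance"):
            tp.pointwise_correlation(X, np.ones(10), nperm=100)


class TestPermutationCorrection:
    def test_single_node_reduces_to_permutation_p(self):
        rng = np.random.default_rng(0)
        A, B = rng.normal(0, 1, (10, 1)), rng.normal(1.0, 1, (10, 1))
        res = tp.pointwise_group_test(A, B, nperm=500, rng_seed=1)
        assert res.p_corrected[0] == pytest.approx(res.p_uncorrected[0])

    def test_identical_nodes_no_multiplicity_penalty(self):
        # perfectly correlated nodes: corrected p equals the single-node p,
        # unlike Bonferroni's x100 inflation
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.9, 1, 12)
        A = np.tile(a[:, None], (1, 100))
        B = np.tile(b[:, None], (1, 100))
        res = tp.pointwise_group_test(A, B, nperm=500, rng_seed=3)
        res1 = tp.pointwise_group_test(a[:, None], b[:, None], nperm=500, rng_seed=3)
        assert np.allclose(res.p_corrected, res1.p_corrected[0])

    def test_monotone_rescaling_invariance(self):
        # p-values depend on the statistic only through its ordering
        rng = np.random.default_rng(4)
        stats = rng.normal(size=(301, 50))
        p1 = _pvalues_from_perm_stats(stats)
        p2 = _pvalues_from_perm_stats(np.sign(stats) * np.abs(stats) ** 3)
        assert np.array_equal(p1[0], p2[0]) and np.array_equal(p1[1], p2[1])

    def test_generic_interface_respects_row_zero(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=20)
        data[:10] += 1.5
        labels = _two_group_permutations(10, 10, 300, rng)

        def stat(row):
            return np.array([data[row].mean() - data[~row].mean()])

        obs, p_unc, p_cor = tp.permutation_max_correct(stat, labels)
        assert obs[0] == pytest.approx(data[:10].mean() - data[10:].mean())
        assert p_cor[0] >= p_unc[0] - 1e-15
        assert p_cor[0] < 0.05

    def test_determinism_under_seed(self):
        X, _ = _cohort(20, seed=15)
        r1 = tp.pointwise_group_test(X[:10], X[10:], nperm=400, rng_seed=7)
        r2 = tp.pointwise_group_test(X[:10], X[10:], nperm=400, rng_seed=7)
        assert np.array_equal(r1.p_corrected, r2.p_corrected)
        assert np.array_equal(r1.statistic, r2.statistic)
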