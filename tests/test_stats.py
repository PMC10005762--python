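"""Permutation tests, effect sizes, mixed models, FDR, histogram binning."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from aperiodic_ei.stats import (adaptive_fdr, cohens_d_paired, fd_bin_count,
                                lme_random_intercept, paired_permutation_ttest,
                                paired_permutation_ttest_family, spearman_corr)


def exact_signflip_p(d: np.ndarray) -> float:
    """Exhaustive sign-flip two-sided p for small n (oracle)."""
    n = d.size

    def tstat(v):
        sd = v.std(ddof=1)
        return 0.0 if sd == 0 else v.mean() / (sd / np.sqrt(n))

    t_obs = abs(tstat(d))
    count = 0
    total = 2 ** n
    for signs in itertools.product((1, -1), repeat=n):
        if abs(tstat(d * np.array(signs))) >= t_obs - 1e-12:
            count += 1
    return count / total


class TestPairedPermutation:
    def test_identical_samples_degenerate(self):
        x = np.arange(10.0)
        res = paired_permutation_ttest(x, x, n_perms=100, seed=0)
        assert res.t == 0.0 and res.p == 1.0

    def test_symmetric_differences_give_zero_t(self):
        d = np.tile([1.0, -1.0], 5)
        res = paired_permutation_ttest(d, np.zeros(10), n_perms=500, seed=0)
        assert res.t == 0.0

    def test_matches_exhaustive_signflip_oracle(self):
        rng = np.random.default_rng(17)
        d = rng.normal(0.4, 1.0, 10)
        p_exact = exact_signflip_p(d)
        n_perms = 50_000
        res = paired_permutation_ttest(d, np.zeros(10), n_perms=n_perms, seed=5)
        mc_sd = np.sqrt(p_exact * (1 - p_exact) / n_perms)
        assert abs(res.p - p_exact) <= 3 * mc_sd + 2 / n_perms

    def test_p_invariant_to_swapping_samples(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 20)
        r1 = paired_permutation_ttest(x, y, n_perms=20_000, seed=3)
        r2 = paired_permutation_ttest(y, x, n_perms=20_000, seed=3)
        assert r1.p == r2.p
        assert r1.t == pytest.approx(-r2.t)

    def test_type_one_error_calibration(self):
        # 2000 simulated Gaussian nulls, n=30 pairs, 1000 sign flips each
        rng = np.random.default_rng(99)
        n_sims, n, n_perms, alpha = 2000, 30, 1000, 0.05
        rejections = 0
        for i in range(n_sims):
            d = rng.standard_normal(n)
            res = paired_permutation_ttest(d, np.zeros(n), n_perms=n_perms,
                                           seed=int(rng.integers(2 ** 31)))
            rejections += res.p < alpha
        assert 0.04 <= rejections / n_sims <= 0.06

    def test_power_for_reported_effect_size_regime(self):
        # a 0.6-SD paired shift at n=30 should be detected most of the time
        rng = np.random.default_rng(7)
        n_sims, hits = 200, 0
        for i in range(n_sims):
            d = rng.normal(0.6, 1.0, 30)
            res = paired_permutation_ttest(d, np.zeros(30), n_perms=1000,
                                           seed=i)
            hits += res.p < 0.05
        assert hits / n_sims > 0.8

    def test_max_stat_correction_is_conservative_per_measure(self, rng):
        d = rng.normal(0.5, 1.0, size=(20, 4))
        fam = paired_permutation_ttest_family(d, n_perms=5000, seed=1)
        for j, res in enumerate(fam):
            single = paired_permutation_ttest_family(d[:, [j]], n_perms=5000,
                                                     seed=1)[0]
            assert res.p >= single.p


class TestCohensD:
    def test_closed_form_example(self):
        x = np.array([1.0, 1.0, 3.0, 3.0])
        assert cohens_d_paired(x, np.zeros(4)) == pytest.approx(np.sqrt(3))

    def test_constant_shift_degenerate(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            cohens_d_paired(x + 2.0, x)

    def test_matches_direct_formula(self, rng):
        x = rng.normal(1, 2, 50)
        y = rng.normal(0, 2, 50)
        d = x - y
        expect = d.mean() / d.std(ddof=1)
        assert cohens_d_paired(x, y) == pytest.approx(expect, abs=1e-12)


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_corr(x, x ** 3).rho == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman_corr(x, -x).rho == pytest.approx(-1.0)

    def test_ties_match_midrank_hand_computation(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0])
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0, 6.0])
        ry = np.array([2.0, 1.0, 3.5, 3.5, 6.0, 5.0])
        expect = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y).rho == pytest.approx(expect, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr(np.ones(5), np.arange(5.0))


class TestLME:
    def test_no_effect_gives_zero_estimate(self):
        values = np.tile([3.0, 3.0], 10)
        cond = np.tile([0, 1], 10)
        group = np.repeat(np.arange(10), 2)
        res = lme_random_intercept(values, cond, group)
        assert res.estimate == pytest.approx(0.0, abs=1e-8)

    def test_balanced_paired_design_equals_mean_within_group_difference(self):
        rng = np.random.default_rng(21)
        n_groups = 12
        base = rng.normal(0, 2, n_groups)
        effect = 0.7
        values, cond, group = [], [], []
        for g in range(n_groups):
            noise = rng.normal(0, 0.1, 2)
            values += [base[g] + noise[0], base[g] + effect + noise[1]]
            cond += [0, 1]
            group += [g, g]
        res = lme_random_intercept(np.array(values), np.array(cond),
                                   np.array(group))
        diffs = np.array(values[1::2]) - np.array(values[0::2])
        assert res.estimate == pytest.approx(diffs.mean(), abs=1e-6)

    def test_zero_between_group_variance_matches_ols(self):
        rng = np.random.default_rng(5)
        n_groups = 10
        values, cond, group = [], [], []
        for g in range(n_groups):
            for c in (0, 1):
                for _ in range(3):
                    values.append(1.0 + 0.5 * c + rng.normal(0, 1))
                    cond.append(c)
                    group.append(g)
        values, cond, group = map(np.array, (values, cond, group))
        res = lme_random_intercept(values, cond, group)
        import statsmodels.api as sm
        ols = sm.OLS(values, sm.add_constant(cond.astype(float))).fit()
        assert res.estimate == pytest.approx(ols.params[1], abs=1e-4)
        assert res.se == pytest.approx(ols.bse[1], rel=0.05)


class TestAdaptiveFDR:
    def test_all_ones_reject_nothing(self):
        assert not adaptive_fdr(np.ones(20)).any()

    def test_hand_computed_example(self):
        mask = adaptive_fdr(np.array([0.001, 0.2, 0.9]), q=0.05)
        np.testing.assert_array_equal(mask, [True, False, False])

    def test_stepup_monotonicity(self, rng):
        p = rng.uniform(size=50)
        mask = adaptive_fdr(p, q=0.2)
        if mask.any() and (~mask).any():
            assert p[mask].max() <= p[~mask].min()

    def test_empty_input(self):
        assert adaptive_fdr(np.array([])).size == 0

    def test_fdr_controlled_under_global_null(self):
        rng = np.random.default_rng(123)
        n_sims, m = 2000, 100
        false_disc = 0
        for _ in range(n_sims):
            mask = adaptive_fdr(rng.uniform(size=m), q=0.05)
            false_disc += mask.any()     # all discoveries are false here
        # under the global null, FDR = P(any rejection) <= q (+ MC slack)
        assert false_disc / n_sims <= 0.06


class TestFreedmanDiaconis:
    def test_hand_computed_example(self):
        assert fd_bin_count(np.arange(1.0, 9.0)) == 2

    def test_two_points_single_bin(self):
        assert fd_bin_count(np.array([0.0, 1.0])) == 1

    def test_scale_invariant_bin_count(self, rng):
        data = rng.normal(size=200)
        assert fd_bin_count(data) == fd_bin_count(data * 123.4)

    def test_zero_iqr_falls_back_to_one_bin(self):
        data = np.r_[np.zeros(50), 1.0]
        with pytest.warns(UserWarning, match="IQR"):
            assert fd_bin_count(data) == 1
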