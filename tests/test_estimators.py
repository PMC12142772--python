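"""Univariable MR estimators: exact examples, invariances, calibration."""

import numpy as np
import pytest

from mrmediate import (beta_to_or, cochran_q, ivw, leave_one_out, mr_egger,
                       wald_ratio, weighted_median)
from mrmediate.simulate import simulate_summary_instruments

from conftest import make_hset


class TestWaldRatio:
    def test_ratio_arithmetic(self):
        r = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert r.theta_hat == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)
        assert r.ci_low < r.theta_hat < r.ci_high

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02).theta_hat == 0.0

    def test_zero_gamma_is_error(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIvw:
    def test_closed_form_weighted_regression(self):
        h = make_hset(np.ones(3), [0.4, 0.5, 0.6], sigma_y=1.0)
        assert ivw(h).theta_hat == pytest.approx(0.5)

    def test_single_snp_equals_wald(self):
        h = make_hset(np.array([0.1]), np.array([0.05]),
                      sigma_x=0.01, sigma_y=0.02)
        r, w = ivw(h), wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert r.theta_hat == pytest.approx(w.theta_hat, rel=1e-14)
        assert r.se == pytest.approx(w.se, rel=1e-14)
        assert r.pval == pytest.approx(w.pval, rel=1e-12)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(21)
        est = [ivw(simulate_summary_instruments(J=50, theta=0.2, seed=rng)).theta_hat
               for _ in range(500)]
        mc_se = np.std(est) / np.sqrt(500)
        assert abs(np.mean(est) - 0.2) < 3 * mc_se

    def test_random_effects_never_deflate(self):
        # homogeneous data: SE equals the fixed-effect SE (floor at 1)
        h = make_hset(np.ones(4), np.full(4, 0.3), sigma_y=0.1)
        r = ivw(h)
        assert r.se == pytest.approx(np.sqrt(1 / np.sum(np.ones(4) / 0.1**2)))


class TestEgger:
    def test_exact_linear_fit(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_hset(g, 0.03 + 0.2 * g)
        r = mr_egger(h)
        assert r.theta_hat == pytest.approx(0.2, abs=1e-10)
        assert r.egger_intercept == pytest.approx(0.03, abs=1e-10)
        assert r.q == pytest.approx(0.0, abs=1e-12)

    def test_needs_three_snps(self):
        with pytest.raises(ValueError, match=">= 3"):
            mr_egger(make_hset(np.ones(2), np.zeros(2)))

    def test_balanced_pleiotropy_intercept_calibrated(self):
        rng = np.random.default_rng(5)
        rej = sum(
            mr_egger(simulate_summary_instruments(
                J=40, theta=0.1, pleiotropy=("balanced", 0.02), seed=rng)
            ).egger_intercept_pval < 0.05
            for _ in range(500))
        # binomial 99.9% band around 0.05 for 500 draws
        assert 9 <= rej <= 42

    def test_directional_pleiotropy_intercept_recovered(self):
        # pleiotropy added to every instrument in its stated orientation, so
        # gamma must be bounded away from 0 (the orientation flip would turn
        # a directional offset into a sign-mixed one on near-null SNPs)
        rng = np.random.default_rng(6)
        inter = [mr_egger(simulate_summary_instruments(
            J=40, theta=0.1, gamma_loc=0.15, gamma_scale=0.03,
            pleiotropy=("directional", 0.05, 0.02), seed=rng)
        ).egger_intercept for _ in range(300)]
        mc_se = np.std(inter) / np.sqrt(300)
        assert abs(np.mean(inter) - 0.05) < 3 * mc_se


class TestWeightedMedian:
    def test_symmetric_median(self):
        h = make_hset(np.ones(3), [0.4, 0.5, 0.6], sigma_y=1.0)
        assert weighted_median(h, n_boot=100, seed=0).theta_hat == pytest.approx(0.5)

    def test_outlier_with_minority_weight_ignored(self):
        h = make_hset(np.ones(4), [0.5, 0.5, 0.5, 5.0], sigma_y=1.0)
        assert weighted_median(h, n_boot=100, seed=0).theta_hat == pytest.approx(0.5)

    def test_permutation_and_duplication_invariance(self):
        rng = np.random.default_rng(2)
        h = simulate_summary_instruments(J=11, theta=0.3, seed=7)
        theta = weighted_median(h, n_boot=50, seed=0).theta_hat
        perm = rng.permutation(11)
        assert weighted_median(h.subset(perm), n_boot=50, seed=0
                               ).theta_hat == pytest.approx(theta)
        # duplicating the set moves the midpoint interpolant by at most one
        # inter-ratio gap (interpolation is not a pure function of the CDF)
        dup = h.subset(np.r_[np.arange(11), np.arange(11)])
        gap = np.diff(np.sort(h.Gamma / h.gamma[:, 0])).max()
        theta_dup = weighted_median(dup, n_boot=50, seed=0).theta_hat
        assert abs(theta_dup - theta) <= gap

    def test_bootstrap_se_matches_monte_carlo(self):
        rng = np.random.default_rng(12)
        thetas, boot_ses = [], []
        for _ in range(500):
            h = simulate_summary_instruments(J=30, theta=0.2, seed=rng)
            r = weighted_median(h, n_boot=500, seed=int(rng.integers(2**31)))
            thetas.append(r.theta_hat)
            boot_ses.append(r.se)
        mc_sd = np.std(thetas, ddof=1)
        assert np.mean(boot_ses) == pytest.approx(mc_sd, rel=0.15)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        h = make_hset(np.ones(3), np.full(3, 0.5), sigma_y=1.0)
        q, df, p = cochran_q(h, 0.5)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert (df, p) == (2, pytest.approx(1.0))

    def test_hand_computed_two_snp_value(self):
        # weights gamma^2/sigma_y^2 = 25 each; Q = 25*0.01*2 = 0.5 at theta=0.5
        h = make_hset(np.ones(2), [0.4, 0.6], sigma_y=0.2)
        q, df, _ = cochran_q(h, 0.5)
        assert q == pytest.approx(0.5)
        assert df == 1

    def test_homogeneous_expectation(self):
        rng = np.random.default_rng(3)
        qs = []
        for _ in range(300):
            h = simulate_summary_instruments(J=20, theta=0.2, seed=rng)
            qs.append(cochran_q(h, ivw(h).theta_hat)[0] / 19)
        # Q/df -> 1 in expectation for homogeneous data
        assert np.mean(qs) == pytest.approx(1.0, abs=0.05)


class TestLeaveOneOut:
    def test_identical_snps_all_equal_full(self):
        h = make_hset(np.full(4, 0.1), np.full(4, 0.1))
        full = ivw(h)
        for r in leave_one_out(h):
            assert r.result.theta_hat == pytest.approx(full.theta_hat)
            assert not r.influential

    def test_two_snps_reduce_to_wald(self):
        h = make_hset(np.array([0.1, 0.2]), np.array([0.05, 0.02]),
                      sigma_x=0.01, sigma_y=0.03)
        loo = leave_one_out(h)
        assert loo[0].result.theta_hat == pytest.approx(0.02 / 0.2)
        assert loo[1].result.theta_hat == pytest.approx(0.05 / 0.1)

    def test_gross_outlier_has_largest_shift(self):
        h = simulate_summary_instruments(J=10, theta=0.2, seed=9)
        h.Gamma[4] += 12 * h.sigma_y[4]
        full = ivw(h).theta_hat
        shifts = [abs(r.result.theta_hat - full) for r in leave_one_out(h)]
        assert int(np.argmax(shifts)) == 4


class TestBetaToOr:
    def test_null_effect(self):
        assert beta_to_or(0.0, 0.1)[0] == 1.0

    def test_printed_or_ci_roundtrip(self):
        odds, lo, hi = beta_to_or(0.1484, 0.0628)
        assert odds == pytest.approx(1.16, abs=0.005)
        assert lo == pytest.approx(1.03, abs=0.005)
        assert hi == pytest.approx(1.31, abs=0.005)

    def test_protective_effect_ordered(self):
        odds, lo, hi = beta_to_or(-0.3, 0.05)
        assert lo < odds < hi < 1.0


@pytest.mark.parametrize("c", [0.5, 2.0, -1.5])
def test_outcome_scaling_equivariance(c):
    """Scaling all Gamma and sigma_y by c scales every estimate by c."""
    h = simulate_summary_instruments(J=20, theta=0.25, seed=17)
    hc = make_hset(h.gamma[:, 0], c * h.Gamma,
                   sigma_x=h.sigma_x[:, 0], sigma_y=abs(c) * h.sigma_y)
    assert ivw(hc).theta_hat == pytest.approx(c * ivw(h).theta_hat)
    assert mr_egger(hc).theta_hat == pytest.approx(c * mr_egger(h).theta_hat)
    assert weighted_median(hc, 200, 3).theta_hat == pytest.approx(
        c * weighted_median(h, 200, 3).theta_hat)
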