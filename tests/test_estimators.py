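"""Unit and property tests for the MR estimator suite."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mratlas import (
    Z_95,
    ivw,
    ivw_arrays,
    mr_egger,
    mr_egger_arrays,
    mvmr_ivw_arrays,
    wald_ratio,
    weighted_median,
    weighted_median_arrays,
    weighted_median_point,
)

from conftest import inst
from oracles import weighted_median_scan, wls_through_origin, wls_with_intercept


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(inst("rs1", 0.5, 0.1, se_y=0.05))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_null_effect_gives_p_one(self):
        est = wald_ratio(inst("rs1", 0.5, 0.0, se_y=0.05))
        assert est.beta == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(inst("rs1", 0.0, 0.1))

    def test_matches_single_instrument_ivw(self):
        i = inst("rs1", 1.0, 0.3, se_y=0.1)
        w = wald_ratio(i)
        e, het = ivw([i], effects_model="fixed")
        assert e.beta == pytest.approx(w.beta)
        assert e.se == pytest.approx(w.se)
        assert het.q == 0.0 and het.i2 == 0.0


class TestIvw:
    def test_colinear_instruments_fixed_model(self):
        insts = [inst("rs1", 1.0, 0.3, se_y=0.1), inst("rs2", 2.0, 0.6, se_y=0.1)]
        est, het = ivw(insts)
        assert est.method == "ivw_fixed"  # n = 2 -> fixed under auto
        assert est.beta == pytest.approx(0.3)
        assert het.q == pytest.approx(0.0, abs=1e-12)

    def test_hand_checked_three_snp_example(self, three_instruments):
        est, het = ivw(three_instruments)
        assert est.method == "ivw_random"
        assert est.beta == pytest.approx(0.3)
        assert het.q == pytest.approx(14.0)
        assert het.i2 == pytest.approx(12.0 / 14.0)
        assert het.phi == pytest.approx(7.0)
        assert est.se == pytest.approx((1 / np.sqrt(300)) * np.sqrt(7.0))

    def test_auto_selects_random_iff_three_snps(self):
        two = [inst("rs1", 1.0, 0.1), inst("rs2", 1.0, 0.4)]
        est2, _ = ivw(two)
        assert est2.method == "ivw_fixed"
        est3, _ = ivw(two + [inst("rs3", 1.0, 0.2)])
        assert est3.method == "ivw_random"

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(50):
            n = rng.integers(3, 12)
            bx = rng.normal(0.1, 0.05, n)
            bx[bx == 0] = 0.01
            by = rng.normal(0, 0.1, n)
            sy = rng.uniform(0.01, 0.2, n)
            ef, _ = ivw_arrays(bx, by, sy, effects_model="fixed")
            er, _ = ivw_arrays(bx, by, sy, effects_model="random")
            assert er.se >= ef.se - 1e-15

    def test_random_equals_fixed_when_q_below_df(self):
        insts = [
            inst("rs1", 1.0, 0.300, se_y=0.1),
            inst("rs2", 1.0, 0.301, se_y=0.1),
            inst("rs3", 1.0, 0.302, se_y=0.1),
        ]
        est, het = ivw(insts)
        assert het.q < het.df
        fixed, _ = ivw(insts, effects_model="fixed")
        assert est.se == pytest.approx(fixed.se)

    def test_matches_regression_through_origin_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            bx = rng.uniform(0.05, 0.5, n)
            by = rng.normal(0, 0.1, n)
            sy = rng.uniform(0.01, 0.2, n)
            est, _ = ivw_arrays(bx, by, sy, effects_model="fixed")
            slope, se = wls_through_origin(bx, by, 1.0 / sy**2)
            assert est.beta == pytest.approx(slope, abs=1e-12)
            assert est.se == pytest.approx(se, abs=1e-12)

    def test_ci_and_pvalue_conventions(self, three_instruments):
        est, _ = ivw(three_instruments)
        assert est.ci_low == pytest.approx(est.beta - Z_95 * est.se)
        assert est.ci_high == pytest.approx(est.beta + Z_95 * est.se)
        from scipy.stats import norm

        assert est.pvalue == pytest.approx(2 * norm.sf(abs(est.beta / est.se)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ivw_arrays(np.array([]), np.array([]), np.array([]))


class TestWeightedMedian:
    def test_equal_weights_odd(self):
        beta = weighted_median_point(np.array([0.1, 0.2, 0.3]), np.ones(3))
        assert beta == pytest.approx(0.2)

    def test_equal_weights_even_interpolates(self):
        beta = weighted_median_point(np.array([0.1, 0.2, 0.3, 0.4]), np.ones(4))
        assert beta == pytest.approx(0.25)

    def test_unequal_weights_hand_example(self):
        beta = weighted_median_point(np.array([0.1, 0.2, 0.9]), np.array([0.4, 0.4, 0.2]))
        assert beta == pytest.approx(0.175)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            weighted_median([inst("rs1", 1.0, 0.1), inst("rs2", 1.0, 0.2)])

    def test_deterministic_under_seed(self, three_instruments):
        a = weighted_median(three_instruments, n_boot=200, seed=7)
        b = weighted_median(three_instruments, n_boot=200, seed=7)
        assert a.beta == b.beta and a.se == b.se

    def test_permutation_invariant_point_estimate(self, rng):
        theta = rng.normal(0, 1, 9)
        w = rng.uniform(0.1, 1, 9)
        base = weighted_median_point(theta, w)
        for _ in range(5):
            perm = rng.permutation(9)
            assert weighted_median_point(theta[perm], w[perm]) == pytest.approx(base)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_exhaustive_scan_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 12))
        theta = r.normal(0, 1, n)
        w = r.uniform(0.05, 2.0, n)
        assert weighted_median_point(theta, w) == pytest.approx(
            weighted_median_scan(theta, w), abs=1e-12
        )

    def test_bootstrap_se_positive_and_stable(self):
        bx = np.array([0.2, 0.3, 0.25, 0.4, 0.35])
        sx = np.full(5, 0.01)
        by = np.array([0.04, 0.06, 0.05, 0.08, 0.07])
        sy = np.full(5, 0.02)
        est = weighted_median_arrays(bx, sx, by, sy, n_boot=2000, seed=1)
        assert est.se > 0
        est2 = weighted_median_arrays(bx, sx, by, sy, n_boot=2000, seed=2)
        assert est.se == pytest.approx(est2.se, rel=0.15)  # bootstrap noise only


class TestMrEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.1 + 0.4 * bx
        slope, intercept = mr_egger_arrays(bx, by, np.full(4, 0.05))
        assert slope.beta == pytest.approx(0.4)
        assert intercept.beta == pytest.approx(0.1)

    def test_no_pleiotropy_reduces_to_ivw(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.3 * bx
        slope, intercept = mr_egger_arrays(bx, by, np.full(3, 0.05))
        est, _ = ivw_arrays(bx, by, np.full(3, 0.05), effects_model="fixed")
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)
        assert slope.beta == pytest.approx(est.beta)

    def test_equal_weight_three_point_ols(self):
        slope, intercept = mr_egger_arrays(
            np.array([1.0, 2.0, 3.0]), np.array([0.5, 0.7, 1.2]), np.full(3, 0.1)
        )
        assert slope.beta == pytest.approx(0.35)
        assert intercept.beta == pytest.approx(0.1)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 15))
            bx = rng.uniform(0.05, 0.5, n)
            by = rng.normal(0.1 + 0.2 * bx, 0.05)
            sy = rng.uniform(0.02, 0.2, n)
            slope, intercept = mr_egger_arrays(bx, by, sy)
            oi, osl, sei, sesl = wls_with_intercept(bx, by, 1.0 / sy**2)
            assert slope.beta == pytest.approx(osl, abs=1e-12)
            assert intercept.beta == pytest.approx(oi, abs=1e-12)
            assert slope.se == pytest.approx(sesl, abs=1e-12)
            assert intercept.se == pytest.approx(sei, abs=1e-12)

    def test_matches_statsmodels_wls(self, rng):
        n = 8
        bx = rng.uniform(0.05, 0.5, n)
        by = rng.normal(0.05 + 0.3 * bx, 0.04)
        sy = rng.uniform(0.02, 0.1, n)
        slope, intercept = mr_egger_arrays(bx, by, sy)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            mr_egger_arrays(np.array([0.1, 0.2]), np.array([0.1, 0.2]), np.array([0.1, 0.1]))
        with pytest.raises(ValueError):
            mr_egger_arrays(np.full(4, 0.2), np.ones(4), np.full(4, 0.1))


class TestMvmrIvw:
    def test_zero_second_exposure_reduces_to_univariable(self, rng):
        n = 6
        bx1 = rng.uniform(0.1, 0.5, n)
        by = rng.normal(0.2 * bx1, 0.03)
        sy = rng.uniform(0.02, 0.1, n)
        est1, est2 = mvmr_ivw_arrays(bx1, np.zeros(n), by, sy)
        uni, _ = ivw_arrays(bx1, by, sy, effects_model="fixed")
        assert est1.beta == pytest.approx(uni.beta, abs=1e-12)
        assert est2.se == np.inf and est2.pvalue == 1.0

    def test_exact_two_exposure_recovery(self):
        bx1 = np.array([0.1, 0.3, 0.2, 0.5])
        bx2 = np.array([0.4, 0.1, 0.3, 0.2])
        by = 0.2 * bx1 + 0.5 * bx2
        est1, est2 = mvmr_ivw_arrays(bx1, bx2, by, np.full(4, 0.05))
        assert est1.beta == pytest.approx(0.2, abs=1e-12)
        assert est2.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        from oracles import wls_two_covariates_no_intercept

        for _ in range(25):
            n = int(rng.integers(4, 12))
            bx1 = rng.uniform(0.05, 0.5, n)
            bx2 = rng.uniform(0.05, 0.5, n)
            by = rng.normal(0.2 * bx1 + 0.5 * bx2, 0.05)
            sy = rng.uniform(0.02, 0.2, n)
            est1, est2 = mvmr_ivw_arrays(bx1, bx2, by, sy)
            b1, b2, se1, se2 = wls_two_covariates_no_intercept(bx1, bx2, by, 1.0 / sy**2)
            assert est1.beta == pytest.approx(b1, abs=1e-10)
            assert est2.beta == pytest.approx(b2, abs=1e-10)
            assert est1.se == pytest.approx(se1, abs=1e-10)
            assert est2.se == pytest.approx(se2, abs=1e-10)

    def test_colinear_exposures_rejected(self):
        bx1 = np.array([0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            mvmr_ivw_arrays(bx1, 2 * bx1, np.ones(3), np.full(3, 0.1))


@given(st.floats(0.1, 10.0))
@settings(max_examples=30, deadline=None)
def test_unit_rescaling_equivariance(c):
    """Multiplying beta_x (and se_x) by c divides beta and se by c exactly."""
    bx = np.array([0.1, 0.25, 0.4, 0.3])
    by = np.array([0.03, 0.05, 0.09, 0.05])
    sy = np.array([0.02, 0.03, 0.02, 0.04])
    base_ivw, _ = ivw_arrays(bx, by, sy)
    scaled_ivw, _ = ivw_arrays(c * bx, by, sy)
    assert scaled_ivw.beta * c == pytest.approx(base_ivw.beta, rel=1e-12)
    assert scaled_ivw.se * c == pytest.approx(base_ivw.se, rel=1e-12)
    base_sl, _ = mr_egger_arrays(bx, by, sy)
    scaled_sl, _ = mr_egger_arrays(c * bx, by, sy)
    assert scaled_sl.beta * c == pytest.approx(base_sl.beta, rel=1e-9)
    assert scaled_sl.se * c == pytest.approx(base_sl.se, rel=1e-9)
    base_wm = weighted_median_point(by / bx, bx**2 / sy**2)
    scaled_wm = weighted_median_point(by / (c * bx), (c * bx) ** 2 / sy**2)
    assert scaled_wm * c == pytest.approx(base_wm, rel=1e-12)
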