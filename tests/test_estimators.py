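"""Estimator arithmetic against hand calculations and independent oracles."""

import numpy as np
import pytest
from scipy import stats

from mrkit.estimators import (
    DegenerateDesignError,
    InsufficientInstrumentsError,
    MethodConfig,
    UndefinedRatioError,
    Z_975,
    ivw,
    mr_egger,
    run_all_methods,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from mrkit.harmonize import HarmonizedPair, HarmonizedSet

from conftest import random_hset


def hset_from(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    if sx is None:
        sx = np.full_like(bx, 1e-6)
    return HarmonizedSet.from_arrays(bx, sx, by, sy)


def pair(bx=0.2, sx=0.01, by=0.1, sy=0.05):
    return HarmonizedPair("rs1", bx, sx, by, sy, "A", "aligned")


class TestWaldRatio:
    def test_hand_arithmetic(self):
        est = wald_ratio(pair(bx=0.2, by=0.1, sy=0.05))
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.25)

    def test_zero_outcome_effect_gives_null(self):
        est = wald_ratio(pair(by=0.0))
        assert est.theta == 0.0 and est.pval == 1.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(pair(bx=0.0))

    def test_matches_delta_method_oracle(self, rng):
        for _ in range(50):
            bx, by = rng.normal(size=2)
            if bx == 0:
                continue
            sx, sy = rng.uniform(0.001, 0.1, 2)
            est = wald_ratio(pair(bx=bx, sx=sx, by=by, sy=sy), second_order=True)
            var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
            assert est.theta == pytest.approx(by / bx, rel=1e-12)
            assert est.se == pytest.approx(np.sqrt(var), rel=1e-12)


class TestIvw:
    def test_two_pair_hand_calculation(self):
        est = ivw(hset_from([1, 1], [0.5, 0.7], [1, 1]), mode="fixed")
        assert est.theta == pytest.approx(0.6)
        assert est.se == pytest.approx(1 / np.sqrt(2))

    def test_matches_wls_through_origin_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(50):
            h = random_hset(rng, int(rng.integers(3, 30)))
            fit = sm.WLS(h.beta_outcome, h.beta_exposure, weights=h.se_outcome**-2).fit()
            assert ivw(h, "fixed").theta == pytest.approx(fit.params[0], abs=1e-10)

    def test_printed_wald_inference_example(self):
        # beta/SE -> two-sided normal p, the arithmetic used for reported CIs
        z = 15.9127 / 5.2520
        p = 2 * stats.norm.sf(z)
        assert round(p, 4) == 0.0024

    def test_single_pair_degrades_to_wald_ratio(self):
        h = hset_from([0.2], [0.1], [0.05])
        est = ivw(h, "fixed")
        assert est.theta == pytest.approx(0.5) and est.n_snps == 1

    def test_all_zero_exposure_effects_rejected(self):
        with pytest.raises(DegenerateDesignError):
            ivw(hset_from([0, 0], [0.1, 0.2], [1, 1]))

    def test_random_effects_never_narrower_than_fixed(self, rng):
        for _ in range(20):
            h = random_hset(rng, 10)
            assert ivw(h, "multiplicative_re").se >= ivw(h, "fixed").se - 1e-15

    def test_equal_weights_reduce_to_mean_of_ratios(self):
        by = np.array([0.4, 0.5, 0.9])
        est = ivw(hset_from([1, 1, 1], by, [1, 1, 1]), mode="fixed")
        assert est.theta == pytest.approx(by.mean())


class TestMrEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        slope, intercept = mr_egger(hset_from(bx, 0.7 * bx, np.full(4, 0.01)))
        assert slope.theta == pytest.approx(0.7, abs=1e-10)
        assert intercept.theta == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_lands_in_intercept(self):
        bx = np.array([0.1, 0.25, 0.3, 0.45, 0.6])
        c = 0.03
        slope, intercept = mr_egger(hset_from(bx, 0.5 * bx + c, np.full(5, 0.02)))
        assert intercept.theta == pytest.approx(c, abs=1e-10)
        assert slope.theta == pytest.approx(0.5, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            h = random_hset(rng, int(rng.integers(4, 25)))
            slope, intercept = mr_egger(h)
            # independent 2x2 solve on the sign-oriented data
            sgn = np.where(h.beta_exposure < 0, -1.0, 1.0)
            x, y = h.beta_exposure * sgn, h.beta_outcome * sgn
            w = h.se_outcome**-2.0
            A = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
            b = np.array([(w * y).sum(), (w * x * y).sum()])
            a_hat, t_hat = np.linalg.solve(A, b)
            assert slope.theta == pytest.approx(t_hat, abs=1e-10)
            assert intercept.theta == pytest.approx(a_hat, abs=1e-10)

    def test_orientation_does_not_mutate_input(self, rng):
        h = random_hset(rng, 10)
        before = h.beta_exposure.copy()
        mr_egger(h)
        np.testing.assert_array_equal(h.beta_exposure, before)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(hset_from([0.1, 0.2], [0.1, 0.2], [0.1, 0.1]))


class TestWeightedMedian:
    def test_equal_weight_median(self):
        est = weighted_median(
            hset_from([1, 1, 1], [0.4, 0.5, 0.9], [1, 1, 1]), n_boot=0
        )
        assert est.theta == pytest.approx(0.5)

    def test_matches_interpolation_oracle(self, rng):
        def oracle(th, w):
            order = np.argsort(th)
            th, w = th[order], w[order] / w.sum()
            s = np.cumsum(w) - w / 2
            if 0.5 <= s[0]:
                return th[0]
            if 0.5 >= s[-1]:
                return th[-1]
            k = np.searchsorted(s, 0.5) - 1
            frac = (0.5 - s[k]) / (s[k + 1] - s[k])
            return th[k] + frac * (th[k + 1] - th[k])

        for _ in range(100):
            j = int(rng.integers(3, 40))
            th = rng.normal(size=j)
            w = rng.uniform(0.1, 5, j)
            assert weighted_median_point(th, w) == pytest.approx(oracle(th, w), rel=1e-12)

    def test_bootstrap_se_is_seed_deterministic(self, rng):
        h = random_hset(rng, 10)
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a.se == b.se and a.pval == b.pval

    def test_bootstrap_requires_seed(self, rng):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(random_hset(rng, 5), n_boot=100, seed=None)


class TestRunAllMethods:
    def test_two_snp_set_marks_uncomputable_methods(self):
        ests = run_all_methods(hset_from([0.1, 0.2], [0.05, 0.1], [0.02, 0.02]))
        by_method = {e.method: e for e in ests}
        assert by_method["ivw_re"].computed
        assert not by_method["weighted_median"].computed
        assert not by_method["egger_slope"].computed
        assert by_method["egger_slope"].status.startswith("not_computed")

    def test_repeat_call_bitwise_identical(self, rng):
        h = random_hset(rng, 12)
        cfg = MethodConfig(n_boot=300, seed=9)
        a = run_all_methods(h, cfg)
        b = run_all_methods(h, cfg)
        assert [(e.method, e.theta, e.se, e.pval) for e in a] == [
            (e.method, e.theta, e.se, e.pval) for e in b
        ]

    def test_null_data_estimates_near_zero(self):
        from mrkit.synth import SyntheticTruth, harmonized_from_truth

        h = harmonized_from_truth(SyntheticTruth(theta=0.0, J=50, seed=77))
        for est in run_all_methods(h, MethodConfig(n_boot=300, seed=1)):
            if est.computed:
                assert abs(est.theta) < 3 * est.se


class TestSharedInvariants:
    def test_scale_equivariance(self, rng):
        h = random_hset(rng, 15)
        c = 2.5
        scaled = HarmonizedSet.from_arrays(
            h.beta_exposure * c, h.se_exposure, h.beta_outcome, h.se_outcome
        )
        assert ivw(scaled, "fixed").theta == pytest.approx(
            ivw(h, "fixed").theta / c, rel=1e-10
        )
        assert mr_egger(scaled)[0].theta == pytest.approx(
            mr_egger(h)[0].theta / c, rel=1e-10
        )
        assert weighted_median(scaled, n_boot=0).theta == pytest.approx(
            weighted_median(h, n_boot=0).theta / c, rel=1e-10
        )

    def test_all_methods_agree_on_exact_line(self, rng):
        bx = rng.uniform(0.05, 0.5, 12)
        h = hset_from(bx, 0.42 * bx, rng.uniform(0.01, 0.05, 12))
        assert ivw(h, "fixed").theta == pytest.approx(0.42, abs=1e-10)
        assert mr_egger(h)[0].theta == pytest.approx(0.42, abs=1e-10)
        assert weighted_median(h, n_boot=0).theta == pytest.approx(0.42, abs=1e-10)

    def test_ci_identity_holds_exactly(self, rng):
        h = random_hset(rng, 10)
        for est in run_all_methods(h, MethodConfig(n_boot=100, seed=3)):
            if not est.computed:
                continue
            if est.method.startswith("egger"):
                q = stats.t.ppf(0.975, est.n_snps - 2)
            else:
                q = Z_975
            assert est.ci_low == pytest.approx(est.theta - q * est.se, rel=1e-12)
            assert est.ci_high == pytest.approx(est.theta + q * est.se, rel=1e-12)
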