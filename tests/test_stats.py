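"""Statistics layer against hand-computed and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from mnpool.stats import (fit_linear, classify_r2, fit_mixed, compare_mixed,
                          icc_oneway, effect_contrast, ks_compare,
                          DegeneratePredictorError, UndefinedEffectError)
from mnpool.synth import SyntheticCohortSpec, hierarchical_cohort


def _cohort_frame(spec):
    parts, _ = hierarchical_cohort(spec)
    rows = [{"duration": d, "rate": r, "subject": p.participant_id}
            for p in parts
            for r, d in zip(p.firing_rate_hz, p.inhibition_duration_ms)]
    return pd.DataFrame(rows)


class TestFitLinear:
    def test_perfect_line(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-6
        assert fit.slope == pytest.approx(2.0)

    def test_hand_computed_three_points(self):
        fit = fit_linear([1, 2, 3], [2, 2, 4])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(2.0 / 3.0)
        assert fit.r_squared == pytest.approx(0.75)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(3, 30)
            x = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            y = rng.normal(size=n)
            fit = fit_linear(x, y)
            # brute-force normal equations
            A = np.vstack([np.ones(n), x]).T
            b0, b1 = np.linalg.solve(A.T @ A, A.T @ y)
            assert fit.slope == pytest.approx(b1, rel=1e-10, abs=1e-10)
            assert fit.intercept == pytest.approx(b0, rel=1e-10, abs=1e-10)
            resid = y - (b0 + b1 * x)
            assert fit.mse == pytest.approx(np.mean(resid ** 2), rel=1e-10)

    def test_mse_shares_numerator_with_r2(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = 3 * x + rng.normal(size=20)
        fit = fit_linear(x, y)
        ss_res = fit.mse * fit.n
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)

    def test_shuffled_r2_near_null_expectation(self):
        rng = np.random.default_rng(3)
        n = 10
        x = rng.normal(size=n)
        y = 2 * x + 1
        r2s = []
        for _ in range(2000):
            r2s.append(fit_linear(rng.permutation(x), y).r_squared)
        assert np.mean(r2s) == pytest.approx(1.0 / (n - 1), abs=0.03)

    def test_constant_predictor_raises(self):
        with pytest.raises(DegeneratePredictorError):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClassifyR2:
    @pytest.mark.parametrize("r2,label", [
        (0.92, "strong"), (0.67, "strong"), (0.33, "moderate"),
        (0.19, "weak"), (0.18, "negligible"), (0.0, "negligible")])
    def test_bands(self, r2, label):
        assert classify_r2(r2) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_r2(1.2)


class TestMixedModels:
    def test_shared_line_gives_negligible_icc(self):
        spec = SyntheticCohortSpec(n_subjects=10, min_units=20, max_units=20,
                                   intercept_sd_ms=0.0, residual_sd_ms=10.0,
                                   seed=11)
        fit = fit_mixed(_cohort_frame(spec), "random-intercept")
        assert fit.icc_subject <= 0.05

    def test_parameter_recovery_random_intercept(self):
        hits_slope = 0
        hits_icc = 0
        n_rep = 20
        for rep in range(n_rep):
            # intercept SD chosen for ICC = 72^2/(72^2+36^2) = 0.8
            spec = SyntheticCohortSpec(n_subjects=10, min_units=7,
                                       max_units=7, beta1_ms_per_hz=-15.0,
                                       intercept_sd_ms=72.0,
                                       residual_sd_ms=36.0, seed=100 + rep)
            fit = fit_mixed(_cohort_frame(spec), "random-intercept")
            lo, hi = fit.beta1_ci
            hits_slope += lo <= -15.0 <= hi
            hits_icc += abs(fit.icc_subject - 0.8) <= 0.1
        assert hits_slope >= 0.8 * n_rep
        assert hits_icc >= 0.8 * n_rep

    def test_zero_slope_variance_flags_singular_fits(self):
        singular = 0
        for rep in range(20):
            spec = SyntheticCohortSpec(n_subjects=8, min_units=8, max_units=8,
                                       intercept_sd_ms=30.0,
                                       slope_sd_ms_per_hz=0.0,
                                       residual_sd_ms=15.0, seed=200 + rep)
            fit = fit_mixed(_cohort_frame(spec), "random-intercept-slope")
            singular += fit.singular
        assert singular >= 10

    def test_model_selection_prefers_true_structure(self):
        pick2 = 0
        pick1 = 0
        for rep in range(10):
            strong = SyntheticCohortSpec(n_subjects=10, min_units=10,
                                         max_units=10, slope_sd_ms_per_hz=8.0,
                                         intercept_sd_ms=10.0,
                                         residual_sd_ms=8.0, seed=300 + rep)
            df = _cohort_frame(strong)
            m1 = fit_mixed(df, "random-intercept")
            m2 = fit_mixed(df, "random-intercept-slope")
            pick2 += compare_mixed(m1, m2).selected == "random-intercept-slope"

            plain = SyntheticCohortSpec(n_subjects=10, min_units=10,
                                        max_units=10, slope_sd_ms_per_hz=0.0,
                                        intercept_sd_ms=30.0,
                                        residual_sd_ms=15.0, seed=400 + rep)
            df = _cohort_frame(plain)
            m1 = fit_mixed(df, "random-intercept")
            m2 = fit_mixed(df, "random-intercept-slope")
            pick1 += compare_mixed(m1, m2).selected == "random-intercept"
        assert pick2 >= 6
        assert pick1 >= 6


class TestIccOneway:
    def test_two_by_two_standard_is_one(self):
        assert icc_oneway([[0.0, 0.0], [10.0, 10.0]],
                          variant="standard") == pytest.approx(1.0)

    def test_identical_means_noise_only_nonpositive(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, 1, 30) for _ in range(6)]
        assert icc_oneway(groups) <= 0.1

    def test_printed_vs_standard_denominators(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, 10) for m in (0.0, 1.0, 2.0)]
        printed = icc_oneway(groups, variant="printed")
        standard = icc_oneway(groups, variant="standard")
        # (k+1) in the denominator shrinks the coefficient
        assert printed < standard

    def test_balanced_groups_match_generating_icc(self):
        # between-SD 1, within-SD 1 -> true ICC 0.5
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(30):
            groups = [rng.normal(rng.normal(0, 1), 1, 50) for _ in range(12)]
            vals.append(icc_oneway(groups, variant="standard"))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            icc_oneway([[1.0, 2.0]])


class TestEffectContrast:
    def test_identical_samples_zero_effect(self):
        e = effect_contrast([1, 2, 3], [1, 2, 3], n_boot=200, seed=0)
        assert e.hedges_g == 0.0
        assert e.mean_diff == 0.0

    def test_hand_computed_g(self):
        e = effect_contrast([1, 2, 3], [3, 4, 5], n_boot=200, seed=0)
        assert e.mean_diff == pytest.approx(-2.0)
        assert e.hedges_g == pytest.approx(-2.0)

    def test_effect_bands(self):
        e = effect_contrast([1, 2, 3], [3, 4, 5], n_boot=100, seed=0)
        assert e.band == "large"
        assert effect_contrast([0.0, 0.6, 1.2, 1.8], [0.5, 1.1, 1.7, 2.3],
                               n_boot=100, seed=0).band == "medium"

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(UndefinedEffectError):
            effect_contrast([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], n_boot=10)

    def test_bootstrap_ci_coverage(self):
        rng = np.random.default_rng(9)
        cover = 0
        n_rep = 200
        for rep in range(n_rep):
            a = rng.normal(1.0, 1.0, 25)
            b = rng.normal(0.0, 1.0, 25)
            e = effect_contrast(a, b, n_boot=400, seed=rep)
            lo, hi = e.mean_diff_ci
            cover += lo <= 1.0 <= hi
        assert cover >= 0.93 * n_rep


class TestKsCompare:
    def test_identical(self):
        d, p = ks_compare(np.arange(10.0), np.arange(10.0))
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_separated_distributions(self):
        rng = np.random.default_rng(10)
        d, p = ks_compare(rng.normal(0, 1, 200), rng.normal(3, 1, 200))
        assert p < 1e-6

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(200):
            a = rng.normal(12.0, 2.0, 100)  # same firing-rate distribution
            b = rng.normal(12.0, 2.0, 100)
            ps.append(ks_compare(a, b)[1])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01
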