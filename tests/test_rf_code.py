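"""Receptive-field codes: power, Fisher information, threshold errors,
width optimization, ML decoding, and ramp responses."""

import math

import numpy as np
import pytest

from popassign import rf_code as rc


@pytest.fixture(scope="module")
def small_pop():
    return rc.build_population(100, 1, 0.1, snr_target=5.0, seed=7)


class TestBuildPopulation:
    def test_peak_matches_printed_normalization(self, small_pop):
        # K=1, w=0.1: bracket = sqrt(pi)*0.1 - 0.01 = 0.16725 (erf(10)=1)
        assert small_pop.P == pytest.approx(math.sqrt(25.0 / (100 * 0.16725)), rel=1e-4)

    def test_power_hits_snr_target(self, small_pop):
        V, _ = rc.population_power(small_pop)
        assert V == pytest.approx(25.0, rel=1e-10)

    def test_empirical_power_matches_analytic(self, small_pop):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (100_000, 1))
        v_emp = np.mean(np.sum(rc.mean_response(small_pop, x) ** 2, axis=1))
        assert v_emp == pytest.approx(25.0, rel=0.02)

    def test_zero_snr_degenerates(self):
        pop = rc.build_population(10, 1, 0.1, snr_target=0.0, seed=0)
        assert pop.P == 0.0

    def test_snr_definition(self):
        p1 = rc.build_population(50, 1, 0.1, snr_target=8.0, sigma_N=1.0, seed=0)
        p2 = rc.build_population(50, 1, 0.1, snr_target=8.0, sigma_N=2.0, seed=0)
        for p in (p1, p2):
            V, _ = rc.population_power(p)
            assert math.sqrt(V) / p.sigma_N == pytest.approx(8.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            rc.build_population(10, 1, -0.1, 5.0)
        with pytest.raises(ValueError):
            rc.build_population(10, 1, 0.1, 5.0, kind="ramp")  # no ramp dims
        with pytest.warns(UserWarning, match="small-width"):
            rc.build_population(10, 1, 0.6, 5.0, seed=0)


class TestResponse:
    def test_unit_at_center_responds_at_peak(self):
        pop = rc.build_population(20, 2, 0.1, 5.0, seed=3)
        x = pop.centers[[4]]
        r = rc.mean_response(pop, x)[0]
        assert r[4] == pytest.approx(pop.P)

    def test_multi_stimulus_superposition(self):
        from dataclasses import replace

        pop = rc.build_population(30, 1, 0.1, 5.0, seed=4)
        x = np.array([[0.4], [0.4]])
        noiseless = rc.response(replace(pop, sigma_N=0.0), x)
        single = rc.mean_response(pop, x[:1])[0]
        assert noiseless == pytest.approx(2 * single)

    def test_noise_added_once_with_correct_variance(self):
        pop = rc.build_population(50, 1, 0.1, 5.0, sigma_N=0.5, seed=5)
        x = np.array([[0.3], [0.8]])
        draws = np.stack([rc.response(pop, x, seed=s) for s in range(4000)])
        var = draws.var(axis=0).mean()
        assert var == pytest.approx(0.25, rel=0.05)

    def test_dimension_mismatch_rejected(self):
        pop = rc.build_population(10, 2, 0.1, 5.0, seed=0)
        with pytest.raises(ValueError):
            rc.response(pop, np.zeros((1, 3)))


class TestPower:
    def test_exact_formula_value(self):
        # K=1, w=0.1, P=1, 100 units: 100 * (sqrt(pi)*0.1*erf(10) - 0.01)
        pop = rc.build_population(100, 1, 0.1, 5.0, seed=1)
        from dataclasses import replace

        unit = replace(pop, P=1.0)
        exact, approx = rc.population_power(unit)
        assert exact == pytest.approx(100 * 0.16725, rel=1e-4)
        assert approx == pytest.approx(exact, rel=0.01)  # w < 0.3 regime

    def test_scaling_in_units_and_peak(self):
        from dataclasses import replace

        pop = rc.build_population(100, 1, 0.1, 5.0, seed=1)
        v1, _ = rc.population_power(pop)
        v2, _ = rc.population_power(replace(pop, P=2 * pop.P))
        assert v2 == pytest.approx(4 * v1)

    def test_vanishes_for_narrow_fields(self):
        from dataclasses import replace

        pop = rc.build_population(100, 1, 0.1, 5.0, seed=1)
        vals = [rc.population_power(replace(pop, P=1.0, w=w))[0] for w in (0.1, 1e-2, 1e-4)]
        assert vals[0] > vals[1] > vals[2]  # V ~ sqrt(pi) n w for small w
        assert vals[2] < 2e-3 * vals[0]  # 1e-4 / 0.1 width ratio, up to the -w^2 term

    def test_power_std_regression(self, small_pop):
        # deterministic given seeds; value frozen from a 1e5-stimulus run
        pop = rc.build_population(100, 1, 0.1, 5.0, seed=7)
        assert rc.power_std(pop, n_mc=100_000, seed=3) == pytest.approx(4.0400025, rel=1e-6)

    def test_power_std_positive_and_shrinks_for_wide_fields(self):
        narrow = rc.build_population(200, 1, 0.05, 5.0, seed=9)
        wide = rc.build_population(200, 1, 0.45, 5.0, seed=9)
        s_narrow = rc.power_std(narrow, seed=1)
        s_wide = rc.power_std(wide, seed=1)
        assert s_narrow > 0 and s_wide > 0
        # relative fluctuation drops as fields flatten out
        assert s_wide / rc.population_power(wide)[0] < s_narrow / rc.population_power(narrow)[0]


class TestFisherInformation:
    def test_approximation_equals_snr_form(self):
        pop = rc.build_population(300, 1, 0.1, 10.0, seed=2)
        _, approx = rc.fisher_information(pop)
        assert approx == pytest.approx(100.0 / (2 * 0.01))  # SNR^2 / 2 w^2

    def test_quarter_width_sixteenfold_information(self):
        f1 = rc.fisher_information(rc.build_population(300, 1, 0.2, 10.0, seed=2))[1]
        f2 = rc.fisher_information(rc.build_population(300, 1, 0.05, 10.0, seed=2))[1]
        assert f2 == pytest.approx(16 * f1)

    @pytest.mark.parametrize("w,K", [(0.05, 1), (0.1, 1), (0.2, 1), (0.1, 2), (0.2, 2)])
    def test_exact_matches_score_function_monte_carlo(self, w, K):
        pop = rc.build_population(300, K, w, 10.0, seed=2)
        exact, _ = rc.fisher_information(pop)
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 1, (80_000, K))
        rbar = rc.mean_response(pop, x)
        noise = rng.normal(0, pop.sigma_N, rbar.shape)
        d0 = -(x[:, [0]] - pop.centers[None, :, 0]) / w**2 * rbar
        score = np.sum(noise * d0, axis=1) / pop.sigma_N**2
        assert np.mean(score**2) == pytest.approx(exact, rel=0.03)

    def test_noiseless_code_rejected(self):
        pop = rc.build_population(10, 1, 0.1, 5.0, sigma_N=0.0, seed=0)
        with pytest.raises(ValueError):
            rc.fisher_information(pop)


class TestThresholdErrors:
    def test_sphere_volumes(self):
        assert rc.sphere_volume(0.2, 1) == pytest.approx(0.4)  # 4 w at w = 0.1
        assert rc.sphere_volume(0.2, 2) == pytest.approx(math.pi * 0.04)

    def test_switch_probability_at_zero_power(self):
        pop = rc.build_population(100, 1, 0.1, 5.0, seed=7)
        # enormous power variability forces V_lambda to 0: p_switch = 1/2
        p = rc.threshold_error_prob(pop, lam=2.0, sigma_V=1e9)
        assert p == pytest.approx(min(1.0, 0.5 / rc.sphere_volume(0.2, 1)))

    def test_decreases_with_power(self):
        lo = rc.build_population(300, 1, 0.05, 4.0, seed=8)
        hi = rc.build_population(300, 1, 0.05, 12.0, seed=8)
        assert rc.threshold_error_prob(hi, seed=1) < rc.threshold_error_prob(lo, seed=1)

    def test_sparse_coverage_is_threshold_dominated(self):
        # 8-D code with tiny fields covers almost none of the space: the
        # sampled power is ~0 even though the analytic average is large
        pop = rc.build_population(2000, 8, 0.02, 10.0, seed=0)
        assert rc.threshold_error_prob(pop, n_mc=800, seed=0) == 1.0


class TestTotalMSE:
    def test_reduces_to_cramer_rao_without_threshold_errors(self):
        pop = rc.build_population(300, 1, 0.1, 10.0, seed=2)
        mse = rc.total_mse(pop, sigma_V=0.0)
        fi, _ = rc.fisher_information(pop)
        # p_thr ~ erfc(5)/0.4 is ~1e-12; both forms collapse to 1/FI scale
        assert mse.weighted == pytest.approx((1 - mse.p_thr) / fi + mse.p_thr / 6)
        assert mse.local_mse == pytest.approx(1 / fi)

    def test_threshold_error_magnitude_is_one_sixth(self):
        # E[(U - U')^2] for independent uniforms on [0, 1]
        rng = np.random.default_rng(0)
        u, v = rng.random(2_000_000), rng.random(2_000_000)
        assert np.mean((u - v) ** 2) == pytest.approx(rc.THRESHOLD_ERROR_MSE, rel=0.005)

    def test_u_shaped_tradeoff_over_width(self):
        grid = np.logspace(math.log10(0.02), math.log10(0.45), 25)
        locals_, thrs, totals = [], [], []
        for w in grid:
            pop = rc.build_population(300, 1, w, 5.0, seed=6)
            m = rc.total_mse(pop, seed=6)
            locals_.append(m.local_mse)
            thrs.append(m.p_thr)
            totals.append(m.weighted)
        # local term grows with w, threshold term grows as w shrinks,
        # total has an interior minimum
        assert all(a <= b + 1e-15 for a, b in zip(locals_, locals_[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(thrs, thrs[1:]))
        i = int(np.argmin(totals))
        assert 0 < i < len(grid) - 1


class TestOptimalWidth:
    def test_frozen_reference_value(self):
        # 200-point log grid + golden refinement, deterministic given seed
        assert rc.optimal_width(100, 1, 5.0, seed=0) == pytest.approx(0.09560, abs=2e-3)

    def test_is_the_argmin_on_a_grid(self):
        w_star = rc.optimal_width(100, 1, 5.0, seed=0)
        pop = rc.build_population(100, 1, w_star, 5.0, seed=0)
        best = rc.total_mse(pop, seed=0).weighted
        for w in np.logspace(math.log10(0.02), math.log10(0.45), 12):
            pop_w = rc.build_population(100, 1, w, 5.0, seed=0)
            assert best <= rc.total_mse(pop_w, seed=0).weighted * (1 + 1e-6)

    def test_more_units_allow_narrower_fields(self):
        widths = [rc.optimal_width(n, 1, 5.0, n_grid=80, seed=0) for n in (50, 200, 800)]
        assert widths[0] >= widths[1] >= widths[2]

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            rc.optimal_width(100, 1, 0.0)


class TestDecoding:
    def test_noiseless_decode_recovers_truth(self):
        pop = rc.build_population(200, 1, 0.1, 8.0, seed=3)
        truth = np.array([0.37])
        res = rc.ml_decode(pop, rc.mean_response(pop, truth[None, :])[0], true_value=truth)
        assert abs(res.estimate[0] - 0.37) < 1e-6
        assert res.error_sq < 1e-12

    def test_decode_is_a_fixed_point(self):
        pop = rc.build_population(200, 1, 0.1, 8.0, seed=3)
        rng = np.random.default_rng(1)
        noisy = rc.mean_response(pop, np.array([[0.6]]))[0] + rng.normal(0, 1.0, 200)
        first = rc.ml_decode(pop, noisy)
        again = rc.ml_decode(pop, rc.mean_response(pop, first.estimate[None, :])[0])
        assert np.allclose(again.estimate, first.estimate, atol=1e-5)

    def test_batch_matches_single(self):
        pop = rc.build_population(200, 1, 0.1, 8.0, seed=3)
        rng = np.random.default_rng(2)
        truth = rng.uniform(0, 1, (5, 1))
        resp = rc.mean_response(pop, truth) + rng.normal(0, 1.0, (5, 200))
        batch = rc.decode_many(pop, resp)
        for i in range(5):
            single = rc.ml_decode(pop, resp[i])
            assert abs(batch[i, 0] - single.estimate[0]) < 5e-3

    def test_two_dimensional_decode(self):
        pop = rc.build_population(300, 2, 0.12, 10.0, seed=4)
        truth = np.array([[0.3, 0.7]])
        est = rc.decode_many(pop, rc.mean_response(pop, truth), n_grid=128)
        assert np.allclose(est, truth, atol=5e-3)

    def test_dense_grid_guard_for_high_dimensions(self):
        pop = rc.build_population(50, 4, 0.2, 5.0, seed=0)
        with pytest.raises(ValueError, match="n_grid"):
            rc.decode_many(pop, np.zeros((1, 50)))


class TestErrorClassification:
    def test_all_zero_errors(self):
        out = rc.classify_errors(np.zeros(10), cutoff=0.2)
        assert out["threshold_rate"] == 0.0
        assert out["local_mse"] == 0.0

    def test_large_error_is_threshold(self):
        out = rc.classify_errors(np.array([0.25]), cutoff=0.2)  # error 0.5 > 0.2
        assert out["threshold_rate"] == 1.0

    def test_default_cutoff_derived_from_population(self):
        pop = rc.build_population(300, 1, 0.1, 10.0, seed=2)
        out = rc.classify_errors(np.zeros(5), pop=pop)
        fi, _ = rc.fisher_information(pop)
        assert out["cutoff"] == pytest.approx(np.clip(6 / math.sqrt(fi), 0.1, 0.3))

    def test_error_histogram_is_bimodal(self):
        # local errors cluster at the 1/sqrt(FI) scale; threshold errors
        # land roughly uniformly across the space, so their tail follows
        # the triangular law P(|U - U'| > c) ~ (1 - c)^2 rather than
        # piling up near the cutoff
        pop = rc.build_population(300, 1, 0.05, 5.0, seed=12)
        rng = np.random.default_rng(42)
        truth = rng.uniform(0, 1, (30_000, 1))
        resp = rc.mean_response(pop, truth) + rng.normal(0, 1.0, (30_000, 300))
        est = rc.decode_many(pop, resp)
        err = np.abs(est - truth)[:, 0]
        fi, _ = rc.fisher_information(pop)
        local_scale = 1 / math.sqrt(fi)
        assert np.mean(err < 5 * local_scale) > 0.98  # most errors are local
        valley = np.mean((err > 5 * local_scale) & (err < 0.1))
        thr = np.mean(err > 0.1)
        assert thr > 0  # threshold errors do occur at this SNR
        assert valley < 0.01  # the two modes are separated
        # tail consistent with uniform landing (within binomial slack)
        ratio = np.mean(err > 0.3) / thr
        assert 0.25 < ratio < 1.0


class TestRampCodes:
    @pytest.fixture()
    def ramp_pop(self):
        return rc.build_population(100, 2, 0.1, 5.0, kind="ramp", ramp_dims=(0,), seed=6)

    def test_midpoint_response_is_zero(self, ramp_pop):
        x = np.array([[0.5, 0.3]])
        assert np.allclose(rc.mean_response(ramp_pop, x), 0.0)

    def test_antisymmetric_about_midpoint(self, ramp_pop):
        lo = rc.mean_response(ramp_pop, np.array([[0.0, 0.3]]))
        hi = rc.mean_response(ramp_pop, np.array([[1.0, 0.3]]))
        assert np.allclose(lo, -hi)

    def test_linear_slope_is_two_p(self):
        pop = rc.build_population(1, 1, 0.1, 5.0, kind="ramp", ramp_dims=(0,), seed=6)
        u = pop.u_R[0, 0]  # +-1 for a single ramp dimension
        for x in (0.1, 0.7, 0.9):
            r = rc.mean_response(pop, np.array([[x]]))[0, 0]
            assert r == pytest.approx(2 * pop.P * (x - 0.5) * u)

    def test_power_normalization_via_monte_carlo(self, ramp_pop):
        v_mc, _ = rc.population_power(ramp_pop, n_mc=100_000, seed=2)
        assert v_mc == pytest.approx(25.0, rel=0.05)

    def test_ramp_response_requires_ramp_kind(self, small_pop):
        with pytest.raises(ValueError):
            rc.ramp_response(small_pop, np.zeros((1, 1)))
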