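"""Statistics tests: yield, multiple-tether correction, discard rule,
double-Gaussian histogram fit, effective-counts SEs, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smforce import (CONTROL_MIXTURE, SimulationConfig, compare_conditions,
                     compute_yield, discard_highest, effective_counts_se,
                     fit_double_gaussian, fit_double_gaussian_histogram,
                     multi_tether_probability, simulate_rupture_forces,
                     summarize_condition)
from smforce.rupture_stats import _double_gauss


class TestYield:
    def test_table_value(self):
        assert compute_yield(1000, 143) == pytest.approx(14.3)

    def test_limits(self):
        assert compute_yield(1000, 0) == 0.0
        assert compute_yield(555, 555) == 100.0

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_yield(0, 0)
        with pytest.raises(ValueError):
            compute_yield(10, 11)


class TestMultiTether:
    def test_small_yield_limit(self):
        lam, p = multi_tether_probability(1e-6)
        assert p == pytest.approx(lam / 2, rel=1e-3)
        assert p < 1e-5

    def test_observed_yield_value(self):
        # 14.3 % yield -> p ~ 0.075
        _, p = multi_tether_probability(0.143)
        assert p == pytest.approx(0.075, abs=0.001)

    def test_highest_yield_reproduces_printed_probability(self):
        # the p = 0.12 correction corresponds to a ~22 % yield experiment
        _, p = multi_tether_probability(0.221)
        assert p == pytest.approx(0.12, abs=0.002)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.001, 0.95), st.floats(0.001, 0.95))
    def test_strictly_increasing_in_yield(self, y1, y2):
        p1 = multi_tether_probability(y1)[1]
        p2 = multi_tether_probability(y2)[1]
        if y1 < y2:
            assert p1 < p2

    def test_invalid_yield_raises(self):
        with pytest.raises(ValueError):
            multi_tether_probability(1.0)
        with pytest.raises(ValueError):
            multi_tether_probability(-0.1)


class TestDiscard:
    def test_discard_counts(self):
        forces = np.arange(1000, dtype=float)
        retained = discard_highest(forces, 0.12)
        assert len(retained) == 880
        assert retained.max() == 879.0

    def test_zero_probability_is_identity(self):
        forces = np.array([3.0, 1.0, 2.0])
        np.testing.assert_array_equal(discard_highest(forces, 0.0), forces)

    def test_floor_rule_small_case(self):
        forces = np.arange(1, 11, dtype=float)
        retained = discard_highest(forces, 0.25)  # floor(2.5) = 2 removed
        np.testing.assert_array_equal(retained, np.arange(1, 9, dtype=float))

    def test_retained_order_is_stable(self, rng):
        forces = rng.normal(100, 30, 200)
        retained = discard_highest(forces, 0.1)
        # retained values appear in their original relative order
        idx = 0
        for v in retained:
            while idx < len(forces) and forces[idx] != v:
                idx += 1
            assert idx < len(forces)
            idx += 1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            discard_highest(np.array([]), 0.1)


class TestDoubleGaussianFit:
    def test_exact_recovery_from_analytic_histogram(self):
        centers = np.arange(5.0, 206.0, 10.0)
        counts = _double_gauss(centers, 50, 66, 20, 50, 132, 30)
        fit = fit_double_gaussian_histogram(centers, counts, 10.0)
        assert fit.mu1 == pytest.approx(66.0, abs=1e-6)
        assert fit.mu2 == pytest.approx(132.0, abs=1e-6)
        assert fit.sigma1 == pytest.approx(20.0, abs=1e-6)
        assert fit.sigma2 == pytest.approx(30.0, abs=1e-6)

    def test_control_draws_recover_within_three_se(self, control_config):
        forces = simulate_rupture_forces(control_config, 2000)
        fit = fit_double_gaussian(forces, 10.0)
        assert abs(fit.mu1 - 66.0) < 3 * fit.SE1
        assert abs(fit.mu2 - 132.0) < 3 * fit.SE2

    def test_matches_grid_search_oracle_on_fixed_sample(self):
        forces = simulate_rupture_forces(SimulationConfig(seed=8), 200)
        # plain (unweighted) least squares so the oracle shares the objective
        fit = fit_double_gaussian(forces, 10.0, weighted=False)
        centers, counts = fit.bin_centers, fit.counts
        from scipy.optimize import curve_fit

        def profiled_ssr(m1, m2):
            def model(c, a1, s1, a2, s2):
                return _double_gauss(c, a1, m1, abs(s1), a2, m2, abs(s2))
            try:
                popt, _ = curve_fit(model, centers, counts,
                                    p0=[counts.max(), 20, counts.max() / 2, 30],
                                    maxfev=10000)
            except RuntimeError:
                return np.inf
            return np.sum((model(centers, *popt) - counts) ** 2)

        grid1 = np.arange(50.0, 85.0, 5.0)
        grid2 = np.arange(105.0, 165.0, 5.0)
        best = min(((profiled_ssr(m1, m2), m1, m2)
                    for m1 in grid1 for m2 in grid2))
        assert abs(fit.mu1 - best[1]) <= 5.0 + 1e-9
        assert abs(fit.mu2 - best[2]) <= 5.0 + 1e-9

    def test_unbiased_over_replicates(self):
        mus1, mus2 = [], []
        for seed in range(50):
            forces = simulate_rupture_forces(SimulationConfig(seed=200 + seed), 2000)
            fit = fit_double_gaussian(forces, 10.0)
            mus1.append(fit.mu1)
            mus2.append(fit.mu2)
        assert abs(np.mean(mus1) - 66.0) < 1.0
        assert abs(np.mean(mus2) - 132.0) < 1.0

    def test_components_ordered_and_histogram_untouched(self, control_config):
        forces = simulate_rupture_forces(control_config, 500)
        snapshot = forces.copy()
        fit = fit_double_gaussian(forces, 10.0)
        assert fit.mu1 <= fit.mu2
        np.testing.assert_array_equal(forces, snapshot)
        # fitting preserves the histogram area
        assert fit.counts.sum() == fit.N
        assert fit.area_fraction1 + fit.area_fraction2 == pytest.approx(1.0)

    def test_too_few_forces_raise(self):
        with pytest.raises(ValueError):
            fit_double_gaussian(np.full(30, 66.0))


class TestEffectiveCounts:
    def test_arithmetic(self):
        fit = fit_double_gaussian_histogram(
            np.arange(5.0, 206.0, 10.0),
            _double_gauss(np.arange(5.0, 206.0, 10.0), 50, 66, 10, 50, 132, 30),
            10.0)
        fit.sigma1, fit.area_fraction1, fit.area_fraction2 = 10.0, 0.25, 0.75
        ne1, se1, ne2, se2 = effective_counts_se(fit, 400)
        assert ne1 == pytest.approx(100.0)
        assert se1 == pytest.approx(1.0)

    def test_zero_area_fraction_raises(self):
        fit = fit_double_gaussian_histogram(
            np.arange(5.0, 206.0, 10.0),
            _double_gauss(np.arange(5.0, 206.0, 10.0), 50, 66, 10, 50, 132, 30),
            10.0)
        fit.area_fraction1 = 0.0
        with pytest.raises(ValueError):
            effective_counts_se(fit, 400)

    def test_se_order_of_magnitude_at_experiment_scale(self, control_config):
        forces = simulate_rupture_forces(control_config, 880)
        fit = fit_double_gaussian(forces, 10.0)
        assert 0.3 < fit.SE1 < 3.0  # ~1 pN at ~880 retained events


class TestSummaries:
    def test_mean_of_two(self, control_config):
        forces = simulate_rupture_forces(control_config, 2000)
        fit = fit_double_gaussian(forces, 10.0)
        s = summarize_condition(np.array([100.0, 150.0]), fit)
        assert s.mean_force == pytest.approx(125.0)

    def test_heavy_tail_pushes_mean_above_upper_peak(self):
        # a high-force tail reproduces mean force > mu2
        rng = np.random.default_rng(0)
        forces = np.concatenate([
            rng.normal(83, 15, 300), rng.normal(164, 20, 500),
            rng.uniform(220, 400, 200)])
        fit = fit_double_gaussian(forces, 10.0)
        s = summarize_condition(forces, fit)
        assert s.mean_force > fit.mu2

    def test_comparison_deltas_and_quadrature(self, control_config):
        forces = simulate_rupture_forces(control_config, 2000)
        fit = fit_double_gaussian(forces, 10.0)
        a = summarize_condition(forces, fit, label="a")
        b = summarize_condition(forces, fit, label="b")
        same = compare_conditions(a, b)
        assert same["delta_mu1_pN"] == 0.0
        assert same["delta_mu2_pN"] == 0.0
        a.se1, b.se1 = 3.0, 4.0
        rep = compare_conditions(a, b)
        assert rep["delta_mu1_se_pN"] == pytest.approx(5.0)
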