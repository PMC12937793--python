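"""Curve fits, agreement metrics, Fréchet distance, OAT sensitivity, repeatability."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from padflow import (
    breakpoint_fit,
    frechet_distance,
    normalize_curve,
    oat_sensitivity,
    pearson_r,
    quadratic_fit,
    repeatability_stats,
    rmse,
    slope_doubling_sigma,
)


def frechet_bruteforce(a, b):
    """Min over all monotone couplings of the max pairwise distance.

    Exhaustive path enumeration over the coupling lattice — exponential, so
    only usable for curves of a handful of points; independent of the DP
    implementation under test.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    dist = np.linalg.norm(a[:, None] - b[None, :], axis=2)
    n, m = dist.shape
    best = [np.inf]

    def walk(i, j, cur):
        cur = max(cur, dist[i, j])
        if cur >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cur
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cur)

    walk(0, 0, 0.0)
    return best[0]


class TestNormalize:
    def test_baseline_maps_to_one(self):
        out = normalize_curve([2.0, 4.0, 8.0])
        assert out[0] == 1.0
        assert list(out) == [1.0, 2.0, 4.0]

    def test_idempotent(self):
        once = normalize_curve([3.0, 6.0, 9.0])
        assert np.allclose(normalize_curve(once), once)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_curve([0.0, 1.0])


class TestQuadraticFit:
    def test_exact_quadratic_recovered(self):
        x = np.array([0.0, 0.25, 0.5, 0.75, 0.9])
        y = 2 + 3 * x + 4 * x**2
        fit = quadratic_fit(x, y)
        assert fit.coefficients == pytest.approx((2.0, 3.0, 4.0), abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_noisy_coefficients_inside_bootstrap_cis(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 1, 40)
        y = 2 + 3 * x + 4 * x**2 + rng.normal(0, 0.01, 40)
        fit = quadratic_fit(x, y, seed=5)
        for name, true in zip(("a0", "a1", "a2"), (2.0, 3.0, 4.0)):
            lo, hi = fit.ci95[name]
            assert lo <= true <= hi

    def test_constant_y_degenerates_gracefully(self):
        fit = quadratic_fit([0.0, 0.5, 1.0, 1.5], [7.0] * 4)
        assert fit.a1 == pytest.approx(0.0, abs=1e-10)
        assert fit.a2 == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == 0.0  # convention for zero total variance

    def test_linear_data_gives_zero_curvature(self):
        x = np.linspace(0, 1, 10)
        fit = quadratic_fit(x, 5 * x + 1)
        assert fit.a2 == pytest.approx(0.0, abs=1e-9)
        assert fit.a1 == pytest.approx(5.0, abs=1e-9)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            quadratic_fit([1.0, 1.0, 2.0], [1.0, 1.0, 2.0])


class TestBreakpoint:
    def test_exact_hinge_recovered_on_grid(self):
        x = np.linspace(0, 1, 21)
        y = np.maximum(0.0, x - 0.5) * 10
        fit = breakpoint_fit(x, y)
        assert fit.breakpoint_sigma == pytest.approx(0.5)
        assert fit.slope_left == pytest.approx(0.0, abs=1e-9)
        assert fit.slope_right == pytest.approx(10.0, abs=1e-9)

    def test_pure_line_ties_break_to_smallest_candidate(self):
        x = np.linspace(0, 1, 9)
        fit = breakpoint_fit(x, 2 * x + 1)
        assert fit.breakpoint_sigma == pytest.approx(x[1])
        assert fit.sse == pytest.approx(0.0, abs=1e-16)

    def test_breakpoint_invariant_to_y_rescaling(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 25)
        y = np.maximum(0.0, x - 0.4) * 7 + rng.normal(0, 0.05, 25)
        assert breakpoint_fit(x, y).breakpoint_sigma == breakpoint_fit(x, 100 * y).breakpoint_sigma

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            breakpoint_fit([0, 1, 2, 3], [0, 1, 2, 3])


class TestSlopeDoubling:
    @pytest.mark.parametrize("a1,a2,expected", [(1.0, 1.0, 0.5), (2.0, 5.0, 0.2)])
    def test_closed_form(self, a1, a2, expected):
        fit = quadratic_fit([0, 0.3, 0.6, 1.0], [0 + a1 * x + a2 * x**2 for x in (0, 0.3, 0.6, 1.0)])
        assert slope_doubling_sigma(fit) == pytest.approx(expected, abs=1e-9)

    def test_zero_curvature_rejected(self):
        fit = quadratic_fit([0, 0.3, 0.6, 1.0], [1 + 2 * x for x in (0, 0.3, 0.6, 1.0)])
        with pytest.raises(ValueError):
            slope_doubling_sigma(fit)


class TestAgreementMetrics:
    def test_perfect_and_inverse_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(0)
        assert abs(pearson_r(rng.normal(size=1000), rng.normal(size=1000))) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_rmse_basics(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))


class TestFrechet:
    def test_identical_curves(self):
        c = [[0, 0], [1, 1], [2, 0]]
        assert frechet_distance(c, c) == 0.0

    def test_parallel_offset_lines(self):
        a = [[0, 0], [1, 0], [2, 0]]
        b = [[0, 0.7], [1, 0.7], [2, 0.7]]
        assert frechet_distance(a, b) == pytest.approx(0.7)

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_and_symmetry_on_small_random_curves(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1, 1, size=(rng.integers(1, 7), 2))
        b = rng.uniform(-1, 1, size=(rng.integers(1, 7), 2))
        d = frechet_distance(a, b)
        assert d == pytest.approx(frechet_bruteforce(a, b), rel=1e-12, abs=1e-12)
        assert d == pytest.approx(frechet_distance(b, a))

    @given(st.integers(0, 10_000))
    def test_dominates_hausdorff(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1, 1, size=(5, 2))
        b = rng.uniform(-1, 1, size=(4, 2))
        dist = np.linalg.norm(a[:, None] - b[None, :], axis=2)
        hausdorff = max(dist.min(axis=1).max(), dist.min(axis=0).max())
        assert frechet_distance(a, b) >= hausdorff - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            frechet_distance([], [[0, 0]])


class TestOatSensitivity:
    @staticmethod
    def _model(mu, E, frequency):
        sig = np.linspace(0, 0.9, 10)
        return mu * (1 + sig**2)  # ignores E and frequency

    def test_ignored_parameter_gives_zero_response(self):
        table = oat_sensitivity(self._model, {"mu": 3.5e-3, "E": 0.4e6, "frequency": 50.0})
        for _, row in table[table.parameter != "mu"].iterrows():
            assert row["max_abs_change"] == pytest.approx(0.0, abs=1e-15)

    def test_linear_parameter_response_is_exact(self):
        table = oat_sensitivity(self._model, {"mu": 3.5e-3, "E": 0.4e6, "frequency": 50.0})
        plus = table[(table.parameter == "mu") & (table.direction == "+")].iloc[0]
        assert np.allclose(plus["relative_change"], 0.20)

    def test_small_perturbations_antisymmetric(self):
        def smooth(mu, E, frequency):
            return np.array([mu**2 + 0.1 * E, mu * frequency])

        table = oat_sensitivity(smooth, {"mu": 1.0, "E": 1.0, "frequency": 1.0}, perturbation=0.01)
        for name in ("mu", "E", "frequency"):
            plus = table[(table.parameter == name) & (table.direction == "+")].iloc[0]
            minus = table[(table.parameter == name) & (table.direction == "-")].iloc[0]
            assert np.allclose(plus["relative_change"], -minus["relative_change"], atol=5e-4)

    def test_model_failures_flagged_not_raised(self):
        def fragile(mu):
            if mu > 1.0:
                raise RuntimeError("boom")
            return np.ones(3)

        table = oat_sensitivity(fragile, {"mu": 1.0})
        assert (table[table.direction == "+"]["error"] != "").all()
        assert (table[table.direction == "-"]["error"] == "").all()


class TestRepeatability:
    def test_identical_series_degenerate(self):
        runs = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [1.0, 2.0, 3.0]})
        rep = repeatability_stats(runs)
        assert (rep.table["cv"] == 0.0).all()
        assert rep.drift_p_value == 1.0

    def test_small_noise_keeps_cv_low(self):
        rng = np.random.default_rng(8)
        levels = np.linspace(1.0, 5.0, 12)
        runs = pd.DataFrame(
            {f"s{i}": levels * (1 + rng.normal(0, 0.01, 12)) for i in range(3)}, index=levels
        )
        rep = repeatability_stats(runs)
        assert (rep.table["cv"] < 0.05).all()

    def test_injected_shift_detected_as_drift(self):
        rng = np.random.default_rng(9)
        levels = np.linspace(1.0, 5.0, 12)
        noise_sd = 0.01
        runs = pd.DataFrame(
            {f"s{i}": levels + rng.normal(0, noise_sd, 12) for i in range(3)}, index=levels
        )
        runs["s2"] = runs["s2"] + 10 * noise_sd
        rep = repeatability_stats(runs)
        assert rep.drift_p_value < 0.01

    def test_mismatched_grids_rejected(self):
        runs = pd.DataFrame({"s1": [1.0, 2.0, np.nan], "s2": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            repeatability_stats(runs)
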