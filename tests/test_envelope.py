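import numpy as np
import pytest

import audioloc as al
from audioloc.envelope import BinnedBounds, LogFit
from audioloc.exceptions import AnalysisError, ValidationError

RNG = np.random.default_rng(17)


class TestBinUpperBounds:
    def test_direct_arithmetic(self):
        # one bin: h = [0.1, 0.3], mean 0.2, sample SD sqrt(0.02) ~ 0.1414
        bb = al.bin_upper_bounds([0.2, 0.3], [0.1, 0.3], k_sd=3.0)
        assert bb.bin_centers.tolist() == [0.0]
        assert bb.upper_bounds[0] == pytest.approx(0.2 + 3 * np.sqrt(0.02), abs=1e-12)

    def test_constant_h_bound_is_constant(self):
        bb = al.bin_upper_bounds([0.1, 0.2, 0.3], [0.5, 0.5, 0.5], k_sd=3.0)
        assert bb.upper_bounds[0] == pytest.approx(0.5)

    def test_k_zero_gives_bin_means(self):
        eps = RNG.uniform(0, 5, 100)
        h = RNG.uniform(0, 1, 100)
        bb = al.bin_upper_bounds(eps, h, k_sd=0.0)
        binned = al.bin_by_degree(eps)
        for c, bound in zip(bb.bin_centers, bb.upper_bounds):
            members = h[np.floor(eps + 0.5) == c]
            assert bound == pytest.approx(members.mean(), abs=1e-12)

    def test_sparse_bins_excluded(self):
        bb = al.bin_upper_bounds([0.1, 0.2, 5.0], [1.0, 2.0, 3.0], k_sd=2.0)
        assert bb.bin_centers.tolist() == [0.0]
        assert bb.excluded_bins == (5.0,)

    def test_all_bins_degenerate(self):
        with pytest.raises(AnalysisError):
            al.bin_upper_bounds([0.0, 5.0], [1.0, 1.0], k_sd=2.0)

    def test_higher_k_gives_higher_bounds(self):
        eps = RNG.uniform(0, 10, 300)
        h = RNG.uniform(0, 1, 300)
        lo = al.bin_upper_bounds(eps, h, k_sd=1.96)
        hi = al.bin_upper_bounds(eps, h, k_sd=3.0)
        assert np.all(hi.upper_bounds >= lo.upper_bounds)


class TestEnvelopeFits:
    def test_linear_recovers_generating_line_exactly(self):
        centers = np.arange(0.0, 26.0)
        bounds = 0.440 - 0.016 * centers
        fit = al.fit_linear_envelope(centers, bounds)
        assert fit.slope == pytest.approx(-0.016, abs=1e-12)
        assert fit.intercept == pytest.approx(0.440, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_log_recovers_generating_curve_exactly(self):
        centers = np.arange(0.0, 26.0)
        max_err = 25.0
        bounds = 0.139 * np.log(max_err + 1 - centers) - 0.064
        fit = al.fit_log_envelope(centers, bounds, max_err)
        assert fit.A == pytest.approx(0.139, abs=1e-12)
        assert fit.B == pytest.approx(-0.064, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_log_defined_at_eps_equals_max(self):
        centers = np.array([0.0, 1.0, 2.0])
        fit = al.fit_log_envelope(centers, [0.3, 0.2, 0.1], max_error=2.0)
        assert np.isfinite(fit.A)

    def test_log_rejects_center_beyond_max(self):
        with pytest.raises(ValidationError):
            al.fit_log_envelope([0.0, 1.0, 3.0], [0.3, 0.2, 0.1], max_error=2.0)

    def test_constant_bounds_flat(self):
        fit = al.fit_linear_envelope([0.0, 1.0, 2.0], [0.2, 0.2, 0.2])
        assert fit.slope == 0.0

    def test_triangular_data_recovery(self):
        """h uniform on [0, c - s*eps]: the k-SD bound of a uniform [0, u]
        is u*(1/2 + k/sqrt(12)), so the fitted slope should match
        -s*(1/2 + k/sqrt(12)) within the Monte-Carlo CI over seeds."""
        c, s, k = 0.45, 0.015, 3.0
        implied = -s * (0.5 + k / np.sqrt(12.0))
        slopes = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            eps = rng.uniform(0, 25, 4000)
            h = rng.uniform(0, c - s * eps)
            env = al.fit_envelope(eps, h, "99.7", k, max_error=25.0)
            slopes.append(env.linear.slope)
            assert env.linear.r_squared >= 0.6 and env.log.r_squared >= 0.6
        slopes = np.asarray(slopes)
        ci = 1.96 * slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - implied) < max(ci, 5e-4)
        assert np.all(slopes < 0)


def brute_force_count(eps, h, e0, h0):
    return int(np.sum((eps >= e0) & (h >= h0)))


class TestQuadrantCurve:
    def test_k_one_case(self):
        eps = RNG.uniform(0, 10, 20)
        h = RNG.uniform(0, 1, 20)
        curve = al.quadrant_curve(eps, h, fraction=0.05)
        assert curve.k == 1
        for e0, h0 in curve.points:
            assert h0 == h[eps >= e0].max()
        assert np.all(np.diff(curve.h0) <= 1e-15)

    def test_integer_grid_exhaustive(self):
        xs, ys = np.meshgrid(np.arange(10), np.arange(10))
        eps, h = xs.ravel().astype(float), ys.ravel().astype(float)
        curve = al.quadrant_curve(eps, h, fraction=0.05)
        assert curve.k == 5
        for e0, h0 in curve.points:
            # integer grid has h ties: closed-quadrant count is the
            # smallest achievable count >= k
            count = brute_force_count(eps, h, e0, h0)
            assert count >= 5
            tighter = brute_force_count(eps, h, e0, np.nextafter(h0, np.inf))
            assert tighter < count

    def test_matches_brute_force_on_random_instances(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(40, 500))
            eps = rng.uniform(0, 30, n)
            h = rng.normal(0.2, 0.08, n)  # continuous: ties have measure zero
            curve = al.quadrant_curve(eps, h, fraction=0.05)
            assert len(curve.points) > 0
            for e0, h0 in curve.points:
                assert brute_force_count(eps, h, e0, h0) == curve.k
            assert np.all(np.diff(curve.h0) <= 1e-15)

    def test_all_h_equal_flat_curve(self):
        eps = np.arange(40.0)
        h = np.full(40, 0.5)
        curve = al.quadrant_curve(eps, h, fraction=0.1)
        assert np.all(curve.h0 == 0.5)
        # terminates when fewer than k points remain to the right
        assert len(curve.eps0) == 40 - curve.k + 1

    def test_too_small_fraction_rejected(self):
        with pytest.raises(ValidationError):
            al.quadrant_curve([1.0, 2.0], [0.1, 0.2], fraction=0.05)


class TestQuadrantEmptiness:
    def test_all_below_line(self):
        fit = al.RegressionFit(slope=0.0, intercept=1.0, r_squared=1.0, n_points=3)
        assert al.quadrant_emptiness([1, 2, 3], [0.1, 0.2, 0.3], fit) == 0.0

    def test_all_above_line(self):
        fit = al.RegressionFit(slope=0.0, intercept=0.0, r_squared=1.0, n_points=3)
        assert al.quadrant_emptiness([1, 2, 3], [0.1, 0.2, 0.3], fit) == 1.0

    def test_own_envelope_bound_on_triangular_data(self):
        """For triangular data (h uniform below a decreasing ceiling) the
        3-SD per-bin bound lies above the ceiling itself, so essentially no
        mass sits above the fitted envelope."""
        rng = np.random.default_rng(31)
        eps = rng.uniform(0, 25, 5000)
        h = rng.uniform(0, 0.45 - 0.015 * eps)
        env = al.fit_envelope(eps, h, "99.7", 3.0, max_error=25.0)
        prop = al.quadrant_emptiness(eps, h, env.linear)
        assert prop <= 0.003 + 3 * np.sqrt(0.003 / len(eps))

    def test_step_frontier(self):
        curve = al.quadrant_curve(np.arange(20.0), RNG.uniform(0, 1, 20), fraction=0.05)
        prop = al.quadrant_emptiness(np.arange(20.0), np.full(20, 10.0), curve)
        assert prop == 1.0


class TestQuartileSplit:
    def test_perfect_centering(self):
        h = np.array([0.0] * 6 + [1.0, 1.0])
        div = np.array([-2.0, 2.0, 4.0, -2.0, 2.0, 4.0, -1.0, 1.0])
        out = al.quartile_split_divergence(h, div)
        assert out.mean_below == pytest.approx(4.0 / 3.0)
        assert out.mean_above == pytest.approx(0.0)
        assert out.mean_shift_pct == pytest.approx(100.0)

    def test_identical_distributions(self):
        h = np.r_[np.zeros(96), np.ones(32)]
        div = np.tile([-1.0, 1.0], 64)
        out = al.quartile_split_divergence(h, div)
        assert abs(out.mean_shift_pct) < 1e-9 or out.mean_shift_pct == 0.0
        assert abs(out.sd_reduction_pct) < 5.0

    def test_q3_linear_interpolation(self):
        h = np.arange(9.0)
        out = al.quartile_split_divergence(h, RNG.normal(size=9))
        assert out.q3 == pytest.approx(np.percentile(h, 75))

    def test_too_few_trials(self):
        with pytest.raises(ValidationError):
            al.quartile_split_divergence([1, 2, 3], [0, 0, 0])

    def test_high_movement_trials_are_tighter(self, default_metrics):
        gv = [m for m in default_metrics if m.group == "G_V" and m.condition == "V" and not m.is_outlier]
        out = al.quartile_split_divergence(
            [m.head_distance for m in gv], [m.head_divergence for m in gv]
        )
        assert out.mean_shift_pct > 0 and out.sd_reduction_pct > 0
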