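import numpy as np
import pytest
from scipy import stats as sps

import audioloc as al
from audioloc.exceptions import ValidationError
from audioloc.stats import ols_fit, with_power
from conftest import make_metrics

RNG = np.random.default_rng(5)


def levene_oracle(samples):
    """Direct textbook computation of Levene's W with mean centering."""
    z = [np.abs(s - np.mean(s)) for s in samples]
    k = len(z)
    n = sum(len(zi) for zi in z)
    zbar = np.concatenate(z).mean()
    num = (n - k) * sum(len(zi) * (zi.mean() - zbar) ** 2 for zi in z)
    den = (k - 1) * sum(((zi - zi.mean()) ** 2).sum() for zi in z)
    return num / den


class TestLevene:
    def test_identical_samples(self):
        s = [1.0, 2.0, 3.0]
        res = al.levene_test([s, s])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_direct_formula(self):
        samples = [RNG.normal(0, sd, size=n) for sd, n in [(1, 30), (2, 45), (1.5, 20)]]
        res = al.levene_test(samples)
        assert res.statistic == pytest.approx(levene_oracle(samples), rel=1e-10)

    def test_detects_unequal_variance(self):
        a = RNG.normal(0, 1, 500)
        b = RNG.normal(0, 3, 500)
        assert al.levene_test([a, b]).p_value < 0.001

    def test_undersized_sample_rejected(self):
        with pytest.raises(ValidationError):
            al.levene_test([[1.0], [1.0, 2.0]])


class TestWelch:
    def test_identical_samples_t_zero(self):
        s = list(RNG.normal(size=10))
        res = al.welch_t(s, s)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_f_equals_t_squared(self):
        for _ in range(20):
            a = RNG.normal(0, 1, RNG.integers(5, 40))
            b = RNG.normal(0.5, 2, RNG.integers(5, 40))
            f = al.welch_anova([a, b])
            t = al.welch_t(a, b)
            assert f.statistic == pytest.approx(t.statistic**2, abs=1e-9)
            assert f.dof[1] == pytest.approx(t.dof[0], abs=1e-6)
            assert f.p_value == pytest.approx(t.p_value, abs=1e-9)

    def test_welch_detects_mean_shift(self):
        a = RNG.normal(0, 1, 1000)
        b = RNG.normal(0.3, 2, 1000)
        assert al.welch_t(a, b).p_value < 0.001

    def test_classical_anova_three_groups(self):
        groups = [RNG.normal(m, 1, 50) for m in (0, 0, 2)]
        res = al.anova_f(groups)
        assert res.dof == (2.0, 147.0)
        assert res.p_value < 0.001


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert al.spearman(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert al.spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_equals_pearson_on_ranks(self):
        for _ in range(10):
            x = RNG.normal(size=20)
            y = RNG.normal(size=20)
            rho = al.spearman(x, y).statistic
            oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            al.spearman([1, 2, 3], [1, 2])


class TestBonferroni:
    def test_examples(self):
        assert al.bonferroni([0.01], 4) == [0.04]
        assert al.bonferroni([0.5], 4) == [1.0]
        assert al.bonferroni([], 0) == []

    def test_monotone_order_preserving(self):
        ps = sorted(RNG.uniform(size=20))
        adj = al.bonferroni(ps, 25)
        assert adj == sorted(adj)
        assert all(a >= p for a, p in zip(adj, ps))

    def test_family_smaller_than_comparisons_rejected(self):
        with pytest.raises(ValidationError):
            al.bonferroni([0.1, 0.2], 1)


class TestPosthocPower:
    def test_zero_effect_gives_alpha(self):
        res = al.welch_t(RNG.normal(size=50), RNG.normal(size=50))
        assert al.posthoc_power(res, [50, 50], 0.0) == pytest.approx(0.05, abs=1e-9)

    def test_huge_effect_near_one(self):
        a, b = RNG.normal(0, 1, 50), RNG.normal(5, 1, 50)
        res = al.welch_t(a, b)
        assert al.posthoc_power(res, [50, 50], 5.0) > 0.999

    def test_matches_monte_carlo(self):
        d, n = 0.5, 100
        res = al.welch_t(RNG.normal(0, 1, n), RNG.normal(d, 1, n))
        analytic = al.posthoc_power(res, [n, n], d)
        rng = np.random.default_rng(123)
        hits = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(0, 1, n)
            b = rng.normal(d, 1, n)
            if sps.ttest_ind(a, b, equal_var=False).pvalue < 0.05:
                hits += 1
        assert analytic == pytest.approx(hits / reps, abs=0.02)

    def test_unsupported_design(self):
        res = al.spearman([1, 2, 3], [1, 2, 3])
        with pytest.raises(NotImplementedError):
            al.posthoc_power(res, [3], 0.5)

    def test_with_power_fills_field(self):
        res = al.welch_t(RNG.normal(size=20), RNG.normal(size=20))
        assert with_power(res, [20, 20], 0.3).power is not None


class TestEccentricityRegression:
    def _metrics_on_line(self, slope, noise=0.0):
        ms = []
        for az in al.DEFAULT_AZIMUTHS:
            for r in range(3):
                val = slope * az + noise * RNG.normal()
                ms += make_metrics([val], target_az=az)
        return ms

    def test_exact_line(self):
        fit = al.eccentricity_regression(self._metrics_on_line(0.4), "signed_error", "V")
        assert fit.slope == pytest.approx(0.4, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points == 13

    def test_constant_means_degenerate(self):
        fit = al.eccentricity_regression(self._metrics_on_line(0.0), "signed_error", "V")
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_too_few_locations(self):
        ms = make_metrics([1.0, 2.0], target_az=0.0) + make_metrics([1.0], target_az=15.0)
        with pytest.raises(ValidationError, match="locations"):
            al.eccentricity_regression(ms, "signed_error", "V")

    def test_fit_is_on_the_means(self):
        # unbalanced raw trials must not tilt the fit: only per-azimuth means count
        ms = []
        for az, vals in [(0.0, [0.0] * 50), (15.0, [1.5]), (30.0, [3.0])]:
            for v in vals:
                ms += make_metrics([v], target_az=az)
        fit = al.eccentricity_regression(ms, "signed_error", "V")
        assert fit.slope == pytest.approx(0.1, abs=1e-12)


class TestPerParticipantSpearman:
    def test_divergence_equals_error(self):
        ms = []
        for i, d in enumerate(np.linspace(-20, 20, 10)):
            ms += make_metrics([d], participant_id="P01", head_divergence=float(d))
        out = al.per_participant_spearman(ms)
        assert len(out) == 1 and out[0].rho == pytest.approx(1.0)

    def test_independent_divergence(self):
        rng = np.random.default_rng(99)
        ms = []
        errs = rng.normal(0, 3, 200)
        divs = rng.normal(0, 20, 200)
        for e, d in zip(errs, divs):
            ms += make_metrics([e], participant_id="P02", head_divergence=float(d))
        out = al.per_participant_spearman(ms)
        assert abs(out[0].rho) < 0.2 and out[0].p_value > 0.05

    def test_sorted_by_rho(self, small_metrics):
        gv_v = [m for m in small_metrics if m.condition == "V" and not m.is_outlier]
        out = al.per_participant_spearman(gv_v)
        rhos = [r.rho for r in out]
        assert rhos == sorted(rhos)


def test_ols_zero_variance_convention():
    fit = ols_fit([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
    assert fit.slope == 0.0 and fit.r_squared == 0.0 and fit.intercept == 5.0
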