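import numpy as np
import pytest
from scipy import stats

from streamfd.trends_stats import (
    compact_letter_display,
    mann_kendall_modified,
    ols_trend,
    oneway_anova_tukey,
    paired_t,
    rank_correlation,
    sens_slope,
    spline_trend,
)


def brute_force_s(x):
    n = len(x)
    return sum(np.sign(x[j] - x[i]) for i in range(n) for j in range(i + 1, n))


class TestMannKendall:
    def test_strictly_increasing_n5(self):
        r = mann_kendall_modified([1.0, 2.0, 3.0, 4.0, 5.0])
        assert r.statistic == 10 and r.tau == pytest.approx(1.0)
        assert r.p_value < 0.05

    def test_constant_series(self):
        r = mann_kendall_modified([2.0] * 8)
        assert r.statistic == 0 and r.p_value == 1.0

    def test_white_noise_correction_factor_is_one(self):
        # no significant rank autocorrelation -> corrected variance = classical
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            x = rng.normal(size=24)
            r = mann_kendall_modified(x)
            n = 24
            classical = n * (n - 1) * (2 * n + 5) / 18
            if np.isclose(r.variance, classical):
                hits += 1
        assert hits >= 15  # occasional spurious significant lags allowed

    def test_s_matches_brute_force_pair_count(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, size=n).astype(float)  # ties common
            r = mann_kendall_modified(x)
            assert r.statistic == brute_force_s(x)
            assert abs(r.tau) <= 1.0 + 1e-12
            assert r.variance > 0

    def test_autocorrelation_inflates_variance(self):
        # strongly AR(1) series should trigger the correction on average
        rng = np.random.default_rng(2)
        ratios = []
        for _ in range(50):
            z = rng.normal(size=24)
            x = np.empty(24)
            x[0] = z[0]
            for i in range(1, 24):
                x[i] = 0.8 * x[i - 1] + z[i]
            r = mann_kendall_modified(x)
            classical = 24 * 23 * 53 / 18
            ratios.append(r.variance / classical)
        assert np.mean(ratios) > 1.2

    def test_power_bracket_on_autocorrelated_trend(self):
        # linear trend of 1 sd per decade + AR(1) rho=0.3 noise, n=24:
        # rejection rate at alpha=0.05 lands between 0.4 and 0.95
        rng = np.random.default_rng(7)
        n, hits, reps = 24, 0, 500
        for _ in range(reps):
            z = rng.normal(size=n)
            x = np.empty(n)
            x[0] = z[0]
            for i in range(1, n):
                x[i] = 0.3 * x[i - 1] + z[i]
            sd = np.sqrt(1.0 / (1 - 0.3**2))
            y = x + (sd / 10.0) * np.arange(n)
            if mann_kendall_modified(y).p_value < 0.05:
                hits += 1
        assert 0.4 <= hits / reps <= 0.95

    def test_sens_slope_recovers_line(self):
        t = np.arange(10.0)
        assert sens_slope(2.0 * t + 1.0, t) == pytest.approx(2.0)


class TestOlsTrend:
    def test_flat_series(self):
        r = ols_trend(np.full(6, 3.0), np.arange(6.0))
        assert r.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        t = np.arange(8.0)
        r = ols_trend(2 * t + 1, t)
        assert r.slope == pytest.approx(2.0) and r.r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        t = np.arange(12.0)
        y = 0.5 * t + rng.normal(0, 1, 12)
        r = ols_trend(y, t)
        tc = t - t.mean()
        beta = float((tc * y).sum() / (tc**2).sum())
        assert r.slope == pytest.approx(beta, rel=1e-12)

    def test_degenerate_times_rejected(self):
        with pytest.raises(ValueError):
            ols_trend([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestSplineTrend:
    def test_constant_series_fits_mean(self):
        t = np.arange(24.0)
        r = spline_trend(np.full(24, 7.0), t, k=6)
        np.testing.assert_allclose(r.fitted["fit"], 7.0, atol=1e-8)

    def test_noiseless_line_reproduced(self):
        t = np.arange(24.0)
        y = 3.0 * t - 4.0
        r = spline_trend(y, t, k=6)
        np.testing.assert_allclose(r.fitted["fit"], y, atol=1e-6)

    def test_sine_wave_fit_error_small(self):
        t = np.linspace(0, 2 * np.pi, 24)
        y = np.sin(t)
        r = spline_trend(y, t, k=6)
        assert np.max(np.abs(r.fitted["fit"] - y)) < 0.05
        assert r.adj_r2 > 0.99

    def test_n_not_greater_than_k_rejected(self):
        with pytest.raises(ValueError):
            spline_trend(np.arange(6.0), np.arange(6.0), k=6)


class TestRankCorrelation:
    def test_perfect_agreement_and_reversal(self):
        x = np.arange(10.0)
        for method in ("spearman", "kendall"):
            assert rank_correlation(x, x, method)[0] == pytest.approx(1.0)
            assert rank_correlation(x, -x, method)[0] == pytest.approx(-1.0)

    def test_kendall_matches_concordance_counting_with_ties(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 5, size=15).astype(float)
        y = rng.integers(0, 5, size=15).astype(float)
        tau, _ = rank_correlation(x, y, "kendall")
        ref = stats.kendalltau(x, y).statistic
        assert tau == pytest.approx(ref)
        # independent concordant/discordant count (tau-b)
        c = d = tx = ty = 0
        for i in range(15):
            for j in range(i + 1, 15):
                sx, sy = np.sign(x[j] - x[i]), np.sign(y[j] - y[i])
                if sx == 0 and sy == 0:
                    continue
                if sx == 0:
                    tx += 1
                elif sy == 0:
                    ty += 1
                elif sx == sy:
                    c += 1
                else:
                    d += 1
        taub = (c - d) / np.sqrt((c + d + tx) * (c + d + ty))
        assert tau == pytest.approx(taub, abs=1e-12)

    def test_signs_agree_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = x + rng.normal(0, 0.5, 20)
        for f in (lambda v: v, np.exp, lambda v: v**3):
            rho, _ = rank_correlation(f(x), y, "spearman")
            tau, _ = rank_correlation(f(x), y, "kendall")
            assert np.sign(rho) == np.sign(tau)

    def test_zero_variance_flagged(self):
        rho, p = rank_correlation(np.full(5, 1.0), np.arange(5.0))
        assert np.isnan(rho)


class TestPairedT:
    def test_identical_pairs(self):
        t, df, p = paired_t(np.arange(5.0), np.arange(5.0))
        assert t == 0.0 and p == 1.0 and df == 4

    def test_constant_nonzero_difference_flagged_infinite(self):
        t, df, p = paired_t(np.array([2.0, 3.0, 4.0, 5.0]), np.array([1.0, 2.0, 3.0, 4.0]))
        assert np.isinf(t) and p == 0.0

    def test_matches_hand_computation(self):
        x = np.array([3.0, 5.0, 4.0, 6.0, 7.0])
        y = np.array([2.0, 5.0, 1.0, 4.0, 6.0])
        t, df, p = paired_t(x, y)
        d = x - y
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(expected_t, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), 4), rel=1e-12)


class TestAnovaTukey:
    def test_identical_groups_share_a_letter(self):
        g = {k: np.array([1.0, 1.0, 1.0]) for k in "abc"}
        f, p, table, letters = oneway_anova_tukey(g)
        assert f == 0.0 and p == 1.0
        assert len(set(letters.values())) == 1

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        f, p, _, _ = oneway_anova_tukey({"a": a, "b": b})
        t = stats.ttest_ind(a, b).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_matches_hand_anova(self):
        g = {"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6]), "c": np.array([7.0, 8, 9])}
        f, p, table, letters = oneway_anova_tukey(g)
        # between SS = 3*(2-5)^2+3*(5-5)^2+3*(8-5)^2 = 54; within SS = 6
        # F = (54/2)/(6/6) = 27
        assert f == pytest.approx(27.0, rel=1e-12)
        assert len({letters["a"], letters["b"], letters["c"]}) == 3

    def test_compact_letters_insert_absorb(self):
        # a~b and b~c but a!~c -> letters overlap through b only
        ns = {frozenset(("a", "b")), frozenset(("b", "c"))}
        letters = compact_letter_display(["a", "b", "c"], ns)
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])
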