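import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actirhythm import (
    ValidationError,
    autocorrelation,
    cohort_preset,
    compute_spectrum,
    find_local_maxima,
    fisher_g_pvalue,
    pool_ordinates,
    sequential_fisher,
    significant_periods,
    simulate_cohort,
)

from conftest import cosine_series


def mc_fisher_tail(g, n, draws, seed):
    """Monte Carlo oracle: P(max/sum > g) for n iid exponential ordinates."""
    e = np.random.default_rng(seed).exponential(size=(draws, n))
    stat = e.max(axis=1) / e.sum(axis=1)
    return float((stat > g).mean())


class TestFisherGPvalue:
    def test_g_one_is_zero(self):
        for n in (2, 5, 50):
            assert fisher_g_pvalue(1.0, n) == 0.0

    def test_minimal_g_is_one(self):
        # N=2, g=0.5: C(2,1)(0.5)^1 - C(2,2)(0)^1 = 1
        assert fisher_g_pvalue(0.5, 2) == 1.0
        assert fisher_g_pvalue(1.0 / 10, 10) == pytest.approx(1.0, abs=1e-9)

    def test_exact_closed_form_n5(self):
        # 5 * (0.5)^4 = 0.3125, the only surviving series term
        assert fisher_g_pvalue(0.5, 5) == 0.3125

    def test_matches_monte_carlo(self):
        for n, g, seed in [(10, 0.3, 1), (50, 0.2, 2)]:
            draws = 40_000
            mc = mc_fisher_tail(g, n, draws, seed)
            p = fisher_g_pvalue(g, n)
            se = np.sqrt(max(p * (1 - p), 1e-8) / draws)
            assert abs(p - mc) <= 3 * se + 1e-9

    def test_large_n_small_g_regime(self):
        # growing-terms regime: the alternating series cancels catastrophically
        # in doubles; the Poisson-limit fallback must stay close to simulation
        p = fisher_g_pvalue(8e-4, 5037)
        mc = mc_fisher_tail(8e-4, 5037, 2000, 3)
        assert p == pytest.approx(mc, abs=0.05)
        assert p > 0.6

    def test_strictly_decreasing_in_g(self):
        for n in (10, 50, 200):
            gs = np.linspace(1.0 / n + 1e-6, 1.0, 40)
            ps = [fisher_g_pvalue(g, n) for g in gs]
            diffs = np.diff(ps)
            assert np.all(diffs <= 0)
            assert ps[0] > ps[-1]

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            fisher_g_pvalue(0.05, 10)  # below 1/N
        with pytest.raises(ValidationError):
            fisher_g_pvalue(1.5, 10)
        with pytest.raises(ValidationError):
            fisher_g_pvalue(0.5, 1)

    @given(st.integers(3, 500), st.floats(0.01, 0.99))
    @settings(max_examples=60, deadline=None)
    def test_always_a_probability(self, n, frac):
        g = 1.0 / n + frac * (1.0 - 1.0 / n)
        p = fisher_g_pvalue(g, n)
        assert 0.0 <= p <= 1.0


class TestSequentialFisher:
    def test_single_spike(self):
        ordinates = np.array([1000.0] + [1.0] * 99)
        labels = np.arange(100, 0, -1.0)
        steps = sequential_fisher(ordinates, labels, alpha=0.05, correction_p=100)
        assert steps[0].significant
        assert steps[0].period_minutes == 100.0
        assert steps[0].n_remaining == 100
        # step 2 tests the 99 near-uniform leftovers and stops
        assert len(steps) == 2
        assert steps[1].n_remaining == 99
        assert not steps[1].significant

    def test_flat_spectrum_stops_immediately(self):
        ordinates = np.full(50, 2.5)
        steps = sequential_fisher(ordinates, np.arange(50, 0, -1.0))
        assert len(steps) == 1
        assert steps[0].g_statistic == pytest.approx(1 / 50)
        assert steps[0].p_value == pytest.approx(1.0, abs=1e-9)
        assert significant_periods(steps) == []

    def test_nonpositive_ordinate_rejected(self):
        with pytest.raises(ValidationError):
            sequential_fisher(np.array([1.0, 0.0]), np.array([2.0, 1.0]))

    def test_g_at_least_reciprocal_n(self):
        rng = np.random.default_rng(7)
        steps = sequential_fisher(rng.exponential(size=200) + 1e-3,
                                  np.arange(200, 0, -1.0))
        for s in steps:
            assert s.g_statistic >= 1.0 / s.n_remaining

    def test_adding_spike_only_adds_steps(self):
        # sequential consistency: a dominant spike cannot remove earlier hits
        rng = np.random.default_rng(11)
        base = rng.exponential(size=100) + 1e-3
        base[3] = 400.0  # one planted spike
        labels = np.arange(100, 0, -1.0)
        before = significant_periods(
            sequential_fisher(base, labels, alpha=0.05, correction_p=100))
        boosted = base.copy()
        boosted[17] = 4000.0  # add a stronger spike elsewhere
        after = significant_periods(
            sequential_fisher(boosted, labels, alpha=0.05, correction_p=100))
        assert set(before) <= set(after)

    def test_max_steps(self):
        ordinates = np.array([1e6, 1e3, 1.0, 1.0, 1.0])
        steps = sequential_fisher(ordinates, np.arange(5, 0, -1.0),
                                  alpha=0.05, correction_p=1, max_steps=2)
        assert len(steps) == 2
        assert all(s.significant for s in steps)

    def test_toddler_regime_significant_set(self):
        cohort = simulate_cohort(cohort_preset("24m", n_subjects=50, days=7, seed=9))
        X = compute_spectrum(cohort)
        steps = sequential_fisher(pool_ordinates(X), X.periods_minutes,
                                  alpha=0.05)
        flagged = {round(p) for p in significant_periods(steps)}
        assert flagged == {1440, 720, 480}


class TestPoolOrdinates:
    def test_single_subject(self):
        series = cosine_series(days=2, components=[(720.0, 4.0, 0.2)])
        X = compute_spectrum([series])
        np.testing.assert_allclose(pool_ordinates(X), X.magnitudes[0] ** 2)

    def test_two_identical_subjects_double(self):
        a = cosine_series(days=2, components=[(720.0, 4.0, 0.2)], subject_id="a")
        b = cosine_series(days=2, components=[(720.0, 4.0, 0.2)], subject_id="b")
        single = pool_ordinates(compute_spectrum([a]))
        double = pool_ordinates(compute_spectrum([a, b]))
        np.testing.assert_allclose(double, 2 * single, rtol=1e-12)

    def test_matches_naive_summation(self, rng):
        from actirhythm import SpectrumMatrix

        mags = rng.random((6, 9))
        X = SpectrumMatrix(
            subject_ids=tuple("abcdef"),
            periods_minutes=1440.0 / np.arange(1, 10),
            magnitudes=mags,
            record_days=1,
        )
        pooled = pool_ordinates(X)
        for j in range(9):
            total = sum(mags[i, j] ** 2 for i in range(6))
            assert pooled[j] == pytest.approx(total, rel=1e-12)


class TestAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        series = cosine_series(days=2, noise_sd=5.0, seed=1)
        profile = autocorrelation(series, 100)
        assert profile.r[0] == pytest.approx(1.0, abs=1e-12)

    def test_bounded_by_one(self, rng):
        series = cosine_series(days=3, components=[(1440.0, 8.0, 0.0)],
                               noise_sd=10.0, seed=2)
        profile = autocorrelation(series, 2000)
        assert np.max(np.abs(profile.r)) <= 1.0 + 1e-12

    def test_constant_series_rejected(self):
        series = cosine_series(days=1, components=[], baseline=5.0)
        with pytest.raises(ValidationError):
            autocorrelation(series, 10)

    def test_bad_max_lag(self):
        series = cosine_series(days=1)
        with pytest.raises(ValidationError):
            autocorrelation(series, 1440)

    def test_matches_definition_oracle(self, rng):
        # brute-force the defining formula on a short series
        x = rng.random(200) * 10
        xbar = x.mean()
        denom = np.sum((x - xbar) ** 2)
        prof = autocorrelation(x, 20)
        for k in range(21):
            num = sum((x[t] - xbar) * (x[t + k] - xbar) for t in range(200 - k))
            assert prof.r[k] == pytest.approx(num / denom, abs=1e-10)

    def test_cosine_peak_near_period(self):
        # The taper (1 - k/L) of the biased estimator shifts the 1440-epoch
        # peak left by up to ~14 epochs on a 7-day record, so +/-2 epochs is
        # not attainable here; assert the honest 1% bound.
        series = cosine_series(days=7, components=[(1440.0, 10.0, 0.4)])
        profile = autocorrelation(series, 2880)
        peaks = find_local_maxima(profile, 240)
        assert abs(peaks[0] - 1440) <= 15

    def test_white_noise_null_band(self):
        # |r_k| <= 4/sqrt(L) for >=99% of lags, pooled over seeded replicates
        length, lags, reps = 10080, 300, 50
        hits = total = 0
        for seed in range(reps):
            x = np.random.default_rng(seed).normal(size=length)
            r = autocorrelation(x, lags).r[1:]
            hits += int(np.sum(np.abs(r) <= 4 / np.sqrt(length)))
            total += lags
        assert hits / total >= 0.99


class TestFindLocalMaxima:
    def test_single_cosine_multiples(self):
        series = cosine_series(days=7, components=[(480.0, 10.0, 0.0)])
        profile = autocorrelation(series, 2100)
        peaks = sorted(find_local_maxima(profile, 100))
        expected = [480, 960, 1440, 1920]
        assert len(peaks) == len(expected)
        for found, want in zip(peaks, expected):
            assert abs(found - want) <= 2

    def test_monotone_decay_has_no_peaks(self):
        from actirhythm import AutocorrelationProfile

        profile = AutocorrelationProfile(
            lags_epochs=np.arange(100), r=np.exp(-np.arange(100) / 20)
        )
        assert find_local_maxima(profile, 5) == []

    def test_two_cosines_vs_exhaustive_scan(self):
        # the short period carries more energy, so its harmonics survive the
        # long component's slope (a weak secondary rhythm gets absorbed --
        # the same estimation bias that motivates spectral methods)
        series = cosine_series(
            days=7, components=[(1440.0, 4.0, 0.0), (480.0, 10.0, 1.0)]
        )
        profile = autocorrelation(series, 2000)
        window = 120
        peaks = set(find_local_maxima(profile, window))
        r = profile.r
        for k in range(window, r.size):  # exhaustive neighborhood oracle
            lo, hi = max(0, k - window), min(r.size, k + window + 1)
            is_peak = all(r[k] >= r[m] for m in range(lo, hi))
            assert (k in peaks) == is_peak
        assert any(abs(p - 480) <= 5 for p in peaks)
        assert any(abs(p - 1440) <= 5 for p in peaks)

    def test_bad_window(self):
        from actirhythm import AutocorrelationProfile

        profile = AutocorrelationProfile(np.arange(5), np.zeros(5))
        with pytest.raises(ValidationError):
            find_local_maxima(profile, 0)
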