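"""Sleep scoring and nonparametric circadian metrics against closed forms
and independent brute-force oracles."""

import numpy as np
import pytest

from actiga.circadian import (
    MINUTES_PER_DAY,
    activity_summaries,
    intradaily_variability,
    interdaily_stability,
    mean_binned_is_iv,
    oakley_sleep_wake,
    relative_amplitude,
)
from actiga.exceptions import UndefinedMetricError


def oakley_oracle(a, theta=80.0):
    """Direct per-epoch evaluation of the weighted sum."""
    a = np.asarray(a, dtype=float)
    out = np.zeros(a.size, dtype=int)
    w = {-2: 0.04, -1: 0.20, 0: 1.0, 1: 0.20, 2: 0.04}
    for t in range(a.size):
        s = sum(wk * a[t + k] for k, wk in w.items() if 0 <= t + k < a.size)
        out[t] = int(s < theta)
    return out


class TestOakley:
    def test_all_zero_is_sleep(self):
        assert oakley_sleep_wake(np.zeros(100)).all()

    def test_constant_high_is_wake(self):
        assert not oakley_sleep_wake(np.full(100, 1000.0)).any()

    def test_single_spike_matches_convolution_oracle(self):
        a = np.zeros(50)
        a[25] = 100.0
        np.testing.assert_array_equal(oakley_sleep_wake(a), oakley_oracle(a))

    def test_random_activity_matches_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 300, size=500).astype(float)
        np.testing.assert_array_equal(oakley_sleep_wake(a), oakley_oracle(a))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 300, size=2000).astype(float)
        rest = [oakley_sleep_wake(a, th).sum() for th in (20, 80, 200, 1000)]
        assert rest == sorted(rest)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            oakley_sleep_wake(np.zeros(4))


def is_oracle(x, bin_minutes=60):
    """Independent evaluation of the IS formula."""
    z = x.reshape(-1, bin_minutes).mean(axis=1)
    p = MINUTES_PER_DAY // bin_minutes
    hourly = z.reshape(-1, p).mean(axis=0)
    return z.size * np.sum((hourly - z.mean()) ** 2) / (p * np.sum((z - z.mean()) ** 2))


class TestInterdailyStability:
    def test_periodic_week_is_one(self):
        day = np.concatenate([np.zeros(480), np.full(900, 200.0), np.zeros(60)])
        assert interdaily_stability(np.tile(day, 7)) == pytest.approx(1.0)

    def test_constant_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            interdaily_stability(np.full(7 * MINUTES_PER_DAY, 5.0))

    def test_noise_matches_formula_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.random(7 * MINUTES_PER_DAY)
        assert interdaily_stability(x) == pytest.approx(is_oracle(x), rel=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.random(7 * MINUTES_PER_DAY) * 100
        assert interdaily_stability(3.5 * x + 7.0) == pytest.approx(
            interdaily_stability(x), rel=1e-9
        )

    def test_partial_day_rejected(self):
        with pytest.raises(ValueError):
            interdaily_stability(np.ones(1500))


class TestIntradailyVariability:
    def test_alternating_series_is_four(self):
        x = np.tile([1.0, -1.0], 5040)
        assert intradaily_variability(x) == pytest.approx(4.0)

    def test_slow_ramp_near_zero(self):
        assert intradaily_variability(np.linspace(0, 100, 10080)) < 0.01

    def test_white_noise_near_two(self):
        rng = np.random.default_rng(4)
        vals = [intradaily_variability(rng.normal(size=10080)) for _ in range(20)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.random(2000)
        assert intradaily_variability(x + 123.0) == pytest.approx(
            intradaily_variability(x), rel=1e-9
        )

    def test_constant_undefined(self):
        with pytest.raises(UndefinedMetricError):
            intradaily_variability(np.ones(100))


class TestRelativeAmplitude:
    def test_silent_night_gives_one(self):
        day = np.concatenate([np.zeros(8 * 60), np.full(16 * 60, 50.0)])
        _, l5, ra = relative_amplitude(np.tile(day, 7))
        assert l5 == 0 and ra == pytest.approx(1.0)

    def test_constant_undefined_or_zero(self):
        day = np.full(MINUTES_PER_DAY, 10.0)
        m10, l5, ra = relative_amplitude(np.tile(day, 7))
        assert ra == pytest.approx(0.0)

    def test_step_profile_matches_window_enumeration(self):
        # 24-h step profile: activity level = hour index
        hourly = np.arange(24.0)
        day = np.repeat(hourly, 60)
        week = np.tile(day, 7)
        m10, l5, ra = relative_amplitude(week)
        wrapped = np.concatenate([hourly, hourly])
        best10 = max(wrapped[s : s + 10].mean() for s in range(24))
        best5 = min(wrapped[s : s + 5].mean() for s in range(24))
        assert m10 == pytest.approx(best10)
        assert l5 == pytest.approx(best5)
        assert ra == pytest.approx((best10 - best5) / (best10 + best5))

    def test_bounds_for_nonnegative_activity(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.random(7 * MINUTES_PER_DAY) * rng.integers(1, 100)
            _, _, ra = relative_amplitude(x)
            assert 0.0 <= ra <= 1.0


class TestActivitySummaries:
    def test_all_sleep(self):
        x = np.ones(7 * MINUTES_PER_DAY)
        out = activity_summaries(x, np.ones_like(x))
        assert out["minutes_rest"] == 10080
        assert np.isnan(out["mean_activity_wake"])

    def test_counts_sleep_epochs(self):
        x = np.ones(10080)
        mask = np.zeros(10080)
        mask[:6000] = 1
        assert activity_summaries(x, mask)["minutes_rest"] == 6000

    def test_planted_stratum_means_recovered(self):
        mask = np.zeros(10080)
        mask[: 3 * MINUTES_PER_DAY] = 1
        x = np.where(mask == 1, 0.25, 4.5)
        out = activity_summaries(x, mask, start_weekday=0)
        assert out["mean_activity_sleep"] == pytest.approx(0.25, abs=1e-9)
        assert out["mean_activity_wake"] == pytest.approx(4.5, abs=1e-9)

    def test_weekend_stratification(self):
        # start Monday: weekend = days 5,6 of the week
        x = np.concatenate([np.full(5 * MINUTES_PER_DAY, 1.0), np.full(2 * MINUTES_PER_DAY, 9.0)])
        out = activity_summaries(x, np.zeros_like(x), start_weekday=0)
        assert out["mean_activity_weekday"] == pytest.approx(1.0)
        assert out["mean_activity_weekend"] == pytest.approx(9.0)


def test_multibin_is_iv_are_finite_means():
    rng = np.random.default_rng(7)
    x = rng.random(7 * MINUTES_PER_DAY) * 50
    ism, ivm = mean_binned_is_iv(x, widths=[1, 2, 5, 60])
    assert np.isfinite(ism) and np.isfinite(ivm)
    assert 0 <= ism <= 1.1
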