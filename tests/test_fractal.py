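import numpy as np
import pytest

from ultrarhythm.fractal import (
    dfa,
    default_window_sizes,
    moving_average_filter,
    select_scaling_range,
)
from ultrarhythm.periodogram import power_spectrum, spectral_slope
from ultrarhythm.synthetic_data import RhythmComponent, gen_fgn, gen_sum_of_sines


class TestDfa:
    def test_bernoulli_noise_is_uncorrelated(self, rng):
        x = rng.integers(0, 2, size=2**17).astype(float)
        res = dfa(x, order=3, window_sizes=default_window_sizes(2**17))
        assert res.alpha == pytest.approx(0.5, abs=0.05)

    def test_fgn_cross_check_multiple_seeds(self):
        alphas = [
            dfa(gen_fgn(0.85, 2**16, seed), order=3,
                window_sizes=default_window_sizes(2**16)).alpha
            for seed in range(5)
        ]
        assert np.mean(alphas) == pytest.approx(0.85, abs=0.05)

    def test_fluctuation_nondecreasing(self, rng):
        x = gen_fgn(0.85, 2**15, 0)
        res = dfa(x, order=3, window_sizes=default_window_sizes(2**15))
        assert np.all(np.diff(res.fluctuations) > 0)

    def test_constant_series_raises(self):
        with pytest.raises(ValueError, match="constant"):
            dfa(np.ones(10000), order=3, window_sizes=np.array([60, 100, 200]))

    def test_order_robustness_on_trend_free_fgn(self):
        x = gen_fgn(0.85, 2**16, 2)
        sizes = default_window_sizes(2**16)
        alphas = [dfa(x, order=o, window_sizes=sizes).alpha for o in (2, 3, 4)]
        assert max(alphas) - min(alphas) < 0.05

    def test_only_high_order_removes_cubic_trend(self):
        n = 2**16
        t = np.linspace(-1, 1, n)
        x = gen_fgn(0.85, n, 4) + 50.0 * t**3
        sizes = default_window_sizes(n)
        a1 = dfa(x, order=1, window_sizes=sizes).alpha
        a3 = dfa(x, order=3, window_sizes=sizes).alpha
        assert a3 == pytest.approx(0.85, abs=0.05)
        assert a1 > 0.95  # trend masquerades as strong persistence

    def test_data_loss_robustness(self, rng):
        x = gen_fgn(0.85, 2**17, 5)
        keep = rng.random(2**17) > 0.30
        sizes = default_window_sizes(int(keep.sum()))
        a_full = dfa(x, order=3, window_sizes=default_window_sizes(2**17)).alpha
        a_lossy = dfa(x[keep], order=3, window_sizes=sizes).alpha
        assert abs(a_full - a_lossy) < 0.05

    def test_beta_alpha_consistency(self):
        for alpha in (0.5, 0.7, 0.85, 1.0):
            x = gen_fgn(alpha, 2**16, 1)
            a = dfa(x, order=3, window_sizes=default_window_sizes(2**16)).alpha
            beta, _ = spectral_slope(
                power_spectrum(x, 1.0), (16 / 3600.0, 2**13 / 3600.0)
            )
            assert abs(beta - (2 * a - 1)) < 0.15


class TestScalingRange:
    def test_exact_power_law_selects_full_range(self):
        from ultrarhythm.fractal import DFAResult

        sizes = np.unique(np.logspace(np.log10(60), np.log10(30000), 20).astype(int))
        fake = DFAResult(
            window_sizes=sizes, fluctuations=sizes**0.85, order=3, alpha=0.85,
            fit_range=(sizes[0], sizes[-1]), r_squared=1.0,
        )
        fit_range, diag = select_scaling_range(fake)
        assert not diag["fallback"]
        assert fit_range == (sizes[0], sizes[-1])

    def test_crossover_detected(self):
        # synthetic two-slope fluctuation function with a crossover
        sizes = np.unique(np.logspace(np.log10(60), np.log10(30000), 20).astype(int))
        n_star = 2000.0
        flucts = np.where(
            sizes < n_star,
            sizes**0.9,
            n_star**0.9 * (sizes / n_star) ** 0.3,
        )
        res = dfa.__wrapped__ if hasattr(dfa, "__wrapped__") else None
        from ultrarhythm.fractal import DFAResult

        fake = DFAResult(
            window_sizes=sizes, fluctuations=flucts, order=3, alpha=0.0,
            fit_range=(sizes[0], sizes[-1]), r_squared=1.0,
        )
        fit_range, diag = select_scaling_range(fake)
        # selected interval must stop within one log step of the crossover
        idx_hi = np.searchsorted(sizes, fit_range[1])
        idx_star = np.searchsorted(sizes, n_star)
        assert abs(idx_hi - idx_star) <= 1 or diag["deviates_beyond"]

    def test_white_noise_spans_most_of_range(self, rng):
        res = dfa(rng.standard_normal(2**17), order=3,
                  window_sizes=default_window_sizes(2**17))
        fit_range, _ = select_scaling_range(res)
        log_span = np.log10(fit_range[1] / fit_range[0])
        full = np.log10(res.window_sizes[-1] / res.window_sizes[0])
        assert log_span >= 0.8 * full

    def test_needs_ten_window_sizes(self):
        from ultrarhythm.fractal import DFAResult

        fake = DFAResult(np.array([60, 100, 200]), np.array([1.0, 2, 4]),
                         3, 1.0, (60, 200), 1.0)
        with pytest.raises(ValueError, match="10 window sizes"):
            select_scaling_range(fake)


class TestMovingAverageFilter:
    def test_nulls_its_own_period(self):
        x = np.sin(2 * np.pi * np.arange(3 * 169200) * 0.5 / (23.5 * 3600.0))
        resid = moving_average_filter(x, 0.5, 23.5)
        assert np.abs(resid).max() < 0.05 * np.abs(x).max()

    def test_constant_maps_to_exact_zero(self):
        resid = moving_average_filter(np.full(400000, 7.0), 0.5, 23.5)
        assert np.abs(resid).max() == 0.0

    def test_window_longer_than_series_raises(self):
        with pytest.raises(ValueError, match="longer than the series"):
            moving_average_filter(np.ones(100), 0.5, 23.5)

    def test_alpha_unchanged_and_correlated_across_seeds(self):
        n = 2**18
        sizes = default_window_sizes(n)
        originals, filtered = [], []
        for seed in range(5):
            x = gen_fgn(0.85, n, seed) + gen_sum_of_sines(
                [RhythmComponent(24.0, 2.0)], n * 0.5 / 86400.0, 0.5
            )[:n]
            a0 = dfa(x, order=3, window_sizes=sizes).refit((60, 31680)).alpha
            a1 = dfa(moving_average_filter(x, 0.5), order=3,
                     window_sizes=sizes).refit((60, 31680)).alpha
            originals.append(a0)
            filtered.append(a1)
            assert abs(a0 - a1) < 0.05
        r = np.corrcoef(originals, filtered)[0, 1]
        assert r > 0.9
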