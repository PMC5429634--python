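import numpy as np
import pytest
from scipy import signal

from ultrarhythm.periodogram import (
    PeriodogramResult,
    dominant_period,
    enright_periodogram,
    enright_select_peaks,
    peak_significance,
    power_spectrum,
    spectral_slope,
)
from ultrarhythm.synthetic_data import RhythmComponent, gen_fgn, gen_sum_of_sines


class TestPowerSpectrum:
    def test_parseval_holds(self, rng):
        x = rng.standard_normal(4097)  # odd length exercises Nyquist handling
        res = power_spectrum(x, 30.0)
        assert res.scores.sum() == pytest.approx(x.var(), rel=1e-6)
        res = power_spectrum(x[:4096], 30.0)
        assert res.scores.sum() == pytest.approx(x[:4096].var(), rel=1e-6)

    def test_matches_scipy_periodogram(self, rng):
        x = rng.standard_normal(2048)
        res = power_spectrum(x, 1.0)
        freqs, pxx = signal.periodogram(x, fs=1.0, detrend="constant")
        # scipy scales as density: power per ordinate = pxx * df
        np.testing.assert_allclose(res.scores, pxx[1:] / 2048, rtol=1e-8)

    def test_pure_tone_located(self):
        x = gen_sum_of_sines([RhythmComponent(24.0)], 6.5, 30.0)
        res = power_spectrum(x, 30.0)
        k = np.argmax(res.scores)
        f_res = 1.0 / res.periods_h[-1] - 1.0 / res.periods_h[-2]
        assert abs(1 / res.periods_h[k] - 1 / 24.0) <= 1.01 * abs(f_res)
        assert dominant_period(res) == pytest.approx(24.0, abs=0.5)

    def test_triple_shows_three_dominant_peaks(self):
        comps = [RhythmComponent(p) for p in (24.0, 12.0, 8.0)]
        res = power_spectrum(gen_sum_of_sines(comps, 6.5, 30.0), 30.0)
        top = res.periods_h[np.argsort(res.scores)[-6:]]
        for p in (24.0, 12.0, 8.0):
            assert np.any(np.abs(top - p) / p < 0.15)

    def test_constant_series_flagged_degenerate(self):
        res = power_spectrum(np.full(64, 3.0), 1.0)
        assert res.degenerate and np.all(res.scores == 0)


class TestPeakSignificance:
    def test_tone_in_noise_flags_only_tone(self, rng):
        t = np.arange(2048)
        x = 5.0 * np.sin(2 * np.pi * t / 64) + 0.5 * rng.standard_normal(2048)
        res = peak_significance(power_spectrum(x, 1.0), 0.001)
        flagged = res.periods_h[res.significant] * 3600.0  # back to samples
        assert flagged.size >= 1
        assert np.all(np.abs(flagged - 64.0) < 2.0)

    def test_white_noise_rate_near_nominal(self, rng):
        flags = total = 0
        for _ in range(300):
            res = peak_significance(power_spectrum(rng.standard_normal(512), 1.0), 0.01)
            flags += res.significant.sum()
            total += res.significant.size
        assert flags / total == pytest.approx(0.01, rel=0.35)

    def test_zero_variance_has_no_flags(self):
        res = peak_significance(power_spectrum(np.zeros(64), 1.0), 0.001)
        assert not res.significant.any()

    def test_sidak_correction_is_stricter(self, rng):
        x = rng.standard_normal(1024)
        point = peak_significance(power_spectrum(x, 1.0), 0.05)
        fam = peak_significance(power_spectrum(x, 1.0), 0.05, correction="sidak")
        assert fam.significant.sum() <= point.significant.sum()


class TestSpectralSlope:
    def test_white_noise_is_flat(self, rng):
        res = power_spectrum(rng.standard_normal(2**16), 1.0)
        beta, _ = spectral_slope(res, (16 / 3600.0, 2**14 / 3600.0))
        assert beta == pytest.approx(0.0, abs=0.1)

    @pytest.mark.parametrize("alpha", [0.5, 0.85])
    def test_fgn_follows_beta_identity(self, alpha):
        res = power_spectrum(gen_fgn(alpha, 2**17, 3), 1.0)
        beta, r2 = spectral_slope(res, (16 / 3600.0, 2**14 / 3600.0))
        assert beta == pytest.approx(2 * alpha - 1, abs=0.1)

    def test_range_outside_frequencies_raises(self, rng):
        res = power_spectrum(rng.standard_normal(64), 1.0)
        with pytest.raises(ValueError, match="fit range"):
            spectral_slope(res, (1e6, 2e6))


class TestEnright:
    def test_square_wave_reaches_theoretical_maximum(self):
        # exact period-10 square wave: all variance is between columns
        x = np.tile(np.r_[np.ones(5), np.zeros(5)], 48)
        res = enright_periodogram(x, bin_seconds=360.0, period_range=(2, 40))
        i = np.flatnonzero(res.period_bins == 10)[0]
        assert res.scores[i] == pytest.approx(x.size)  # Q_P = N when within-var = 0

    def test_offset_and_scale_invariance(self, rng):
        x = rng.standard_normal(400)
        a = enright_periodogram(x, bin_seconds=360.0).scores
        b = enright_periodogram(5.0 * x + 100.0, bin_seconds=360.0).scores
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_synthetic_24_12_peaks_significant(self, rhythmic_actogram_6min):
        res = enright_periodogram(rhythmic_actogram_6min)
        for target in (120, 240):  # bins = 12 h and 24 h at 6-min bins
            window = np.abs(res.period_bins - target) <= 2
            assert res.significant[window].any()

    def test_constant_actogram_raises(self):
        with pytest.raises(ValueError, match="constant"):
            enright_periodogram(np.ones(100), bin_seconds=360.0)


class TestEnrightSelectPeaks:
    def _result(self, periods, qp):
        periods = np.asarray(periods)
        return PeriodogramResult(
            periods_h=periods / 10.0,
            scores=np.asarray(qp, dtype=float),
            method="enright",
            significant=np.ones(len(periods), dtype=bool),
            period_bins=periods,
            bin_seconds=360.0,
        )

    def test_multiples_of_retained_period_removed(self):
        periods = np.arange(50, 251)
        qp = np.ones(periods.size)
        for p in (60, 120, 240):  # 6 h, 12 h, 24 h at 6-min bins
            qp[periods == p] = 100.0
        out = enright_select_peaks(self._result(periods, qp))
        assert out["period_bins"].tolist() == [60]

    def test_non_multiples_both_survive(self):
        periods = np.arange(50, 150)
        qp = np.ones(periods.size)
        qp[periods == 80] = 90.0
        qp[periods == 120] = 100.0
        out = enright_select_peaks(self._result(periods, qp))
        assert out["period_bins"].tolist() == [80, 120]

    def test_single_peak_survives(self):
        periods = np.arange(10, 50)
        qp = np.ones(periods.size)
        qp[periods == 24] = 50.0
        out = enright_select_peaks(self._result(periods, qp))
        assert out["period_bins"].tolist() == [24]

    def test_ten_percent_threshold_excludes_minor_peaks(self):
        periods = np.arange(10, 100)
        qp = np.ones(periods.size)
        qp[periods == 23] = 100.0
        qp[periods == 47] = 5.0  # below 10% of max
        out = enright_select_peaks(self._result(periods, qp))
        assert out["period_bins"].tolist() == [23]

    def test_output_is_antichain_under_multiples(self, rng):
        x = rng.standard_normal(600)
        res = enright_periodogram(x, bin_seconds=360.0)
        kept = enright_select_peaks(res)["period_bins"].to_numpy()
        for i, p in enumerate(kept):
            for q in kept[:i]:
                m = round(p / q)
                assert not (m >= 2 and abs(p - m * q) <= 0.5)
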