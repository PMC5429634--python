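import numpy as np
import pytest

from ultrarhythm.synthetic_data import RhythmComponent, gen_sum_of_sines
from ultrarhythm.wavelet import (
    count_real_peaks,
    cwt_morlet,
    group_synchrony,
    peak_lag_times,
    synchrony,
)


def binned_sines(periods_h, duration_days=6.5, bin_seconds=360.0):
    """Sum-of-sines sampled at 0.5 s, averaged into actogram-like bins."""
    comps = [RhythmComponent(p) for p in periods_h]
    x = gen_sum_of_sines(comps, duration_days, 0.5)
    per = int(bin_seconds / 0.5)
    n = x.size // per
    return x[: n * per].reshape(n, per).mean(axis=1)


@pytest.fixture(scope="module")
def triple_field():
    return cwt_morlet(binned_sines([24.0, 12.0, 8.0]), bin_seconds=360.0)


class TestCwt:
    def test_scale_to_period_map(self, triple_field):
        # period = scale * bin / (3600 * fc); fc = 1.5 for cmor1-1.5
        np.testing.assert_allclose(
            triple_field.periods_h, triple_field.scales * 360.0 / (3600.0 * 1.5)
        )
        assert triple_field.periods_h[0] == pytest.approx(0.0667, abs=1e-3)
        assert triple_field.periods_h[-1] == pytest.approx(26.67, abs=0.01)

    def test_tone_modulus_localized_at_its_scale(self):
        field = cwt_morlet(binned_sines([12.0]), bin_seconds=360.0)
        profile = np.abs(field.coefficients).mean(axis=1)
        best = field.periods_h[np.argmax(profile)]
        assert abs(best - 12.0) <= field.periods_h[1] - field.periods_h[0] + 0.1

    def test_zero_series_gives_zero_coefficients(self):
        field = cwt_morlet(np.zeros(1200), bin_seconds=360.0)
        np.testing.assert_allclose(np.abs(field.coefficients), 0.0, atol=1e-12)

    def test_linearity(self, rng):
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        scales = np.arange(1, 50)
        fx = cwt_morlet(x, scales=scales, bin_seconds=360.0).coefficients
        fy = cwt_morlet(y, scales=scales, bin_seconds=360.0).coefficients
        fxy = cwt_morlet(2.0 * x + 3.0 * y, scales=scales, bin_seconds=360.0).coefficients
        np.testing.assert_allclose(fxy, 2.0 * fx + 3.0 * fy, atol=1e-8)

    def test_matches_direct_convolution_oracle(self):
        # independent oracle: explicit convolution with the analytic
        # complex-Morlet atom at one scale
        rng = np.random.default_rng(0)
        x = rng.standard_normal(600)
        scale, B, C = 20.0, 1.0, 1.5
        field = cwt_morlet(x, scales=np.array([20]), bin_seconds=1.0)
        t = (np.arange(-300, 300)) / scale
        atom = np.exp(2j * np.pi * C * t) * np.exp(-(t**2) / B) / np.sqrt(np.pi * B)
        ref = np.convolve(x - x.mean(), np.conj(atom[::-1]), mode="same") / np.sqrt(scale)
        got = field.coefficients[0]
        corr = np.abs(np.vdot(got, ref)) / (np.linalg.norm(got) * np.linalg.norm(ref))
        assert corr > 0.99

    def test_series_too_short_for_scales_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            cwt_morlet(np.ones(100), scales=np.arange(1, 401), bin_seconds=360.0)


class TestPeakCountsAndLags:
    def test_twelve_hour_component_gives_thirteen_peaks(self, triple_field):
        assert count_real_peaks(triple_field, 12.0) == 13

    def test_twenty_four_hour_row_gives_seven_peaks(self, triple_field):
        assert count_real_peaks(triple_field, 24.0) == 7

    def test_branching_doubles_peak_count(self):
        field = cwt_morlet(binned_sines([24.0, 12.0]), bin_seconds=360.0)
        n24 = count_real_peaks(field, 24.0)
        assert count_real_peaks(field, 12.0) in (2 * n24 - 1, 2 * n24)

    def test_lag_equals_period_for_tone(self):
        field = cwt_morlet(binned_sines([12.0]), bin_seconds=360.0)
        _, mean, _ = peak_lag_times(field, 12.0)
        assert mean == pytest.approx(12.0, abs=0.2)

    def test_lag_at_8h_row_of_triple(self, triple_field):
        _, mean, _ = peak_lag_times(triple_field, 8.0)
        assert mean == pytest.approx(8.0, abs=0.3)

    def test_period_outside_range_raises(self, triple_field):
        with pytest.raises(ValueError, match="outside"):
            peak_lag_times(triple_field, 40.0)


class TestSynchrony:
    def test_self_synchrony_is_one_everywhere(self, triple_field):
        prof = synchrony(triple_field, triple_field)
        assert np.nanmin(prof.rho) == pytest.approx(1.0, abs=1e-9)

    def test_in_phase_tones_max_correlated_despite_amplitudes(self):
        t = np.arange(1560) * 360.0
        a = cwt_morlet(10.0 * np.sin(2 * np.pi * t / 86400), bin_seconds=360.0)
        b = cwt_morlet(2.0 * np.sin(2 * np.pi * t / 86400), bin_seconds=360.0)
        prof = synchrony(a, b)
        assert prof.rho[a.scale_index(24.0)] == pytest.approx(1.0, abs=0.01)

    def test_antiphase_tones_anticorrelated(self):
        t = np.arange(1560) * 360.0
        a = cwt_morlet(np.sin(2 * np.pi * t / 43200), bin_seconds=360.0)
        b = cwt_morlet(-np.sin(2 * np.pi * t / 43200), bin_seconds=360.0)
        prof = synchrony(a, b)
        assert prof.rho[a.scale_index(12.0)] == pytest.approx(-1.0, abs=0.01)

    def test_symmetry_of_arguments(self, rng):
        a = cwt_morlet(rng.standard_normal(800), bin_seconds=360.0, scales=np.arange(1, 100))
        b = cwt_morlet(rng.standard_normal(800), bin_seconds=360.0, scales=np.arange(1, 100))
        np.testing.assert_allclose(synchrony(a, b).rho, synchrony(b, a).rho)

    def test_mismatched_grids_rejected(self, rng):
        a = cwt_morlet(rng.standard_normal(800), bin_seconds=360.0, scales=np.arange(1, 50))
        b = cwt_morlet(rng.standard_normal(800), bin_seconds=30.0, scales=np.arange(1, 50))
        with pytest.raises(ValueError, match="grids"):
            synchrony(a, b)


class TestGroupSynchrony:
    def test_identical_fields_mean_one(self, triple_field):
        prof = group_synchrony([triple_field] * 3)
        assert np.nanmin(prof.rho) == pytest.approx(1.0, abs=1e-9)

    def test_two_fields_equal_single_pair(self, rng):
        a = cwt_morlet(rng.standard_normal(900), bin_seconds=360.0, scales=np.arange(1, 80))
        b = cwt_morlet(rng.standard_normal(900), bin_seconds=360.0, scales=np.arange(1, 80))
        np.testing.assert_allclose(group_synchrony([a, b]).rho, synchrony(a, b).rho)

    def test_needs_two_fields(self, triple_field):
        with pytest.raises(ValueError, match="at least two"):
            group_synchrony([triple_field])
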