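"""Pulse-detection pipeline: segmentation, spectrum, peak search, decision."""

import numpy as np
import pytest

from lifesign import (
    InvalidInputError,
    InvalidParameterError,
    PPGSegment,
    amplitude_spectrum,
    decide_pulse,
    detect_pulse,
    find_pulse_peak,
    remove_dc,
    samples_per_segment,
    segment_mean,
    segment_statistics,
    segment_stream,
)
from lifesign.kde import KernelDensityModel


def brute_force_dft_amplitudes(x):
    """Direct O(N^2) evaluation of the one-sided DFT magnitude (test oracle)."""
    n = len(x)
    m = np.arange(n // 2 + 1)
    w = np.exp(-2j * np.pi * np.outer(m, np.arange(n)) / n)
    return np.abs(w @ x)


def make_segment(samples, fs=1000.0):
    samples = np.asarray(samples, dtype=float)
    return PPGSegment(samples, fs=fs, tau=samples.size / fs)


class TestSegmentation:
    @pytest.mark.parametrize(
        "n_samples,fs,tau,expected",
        [
            (240_000, 500.0, 4.0, 120),  # 480 s at 500 Hz
            (4000, 1000.0, 4.0, 1),
            (3999, 1000.0, 4.0, 0),  # trailing remainder discarded
            (0, 1000.0, 4.0, 0),  # empty stream is not an error
        ],
    )
    def test_window_counts(self, n_samples, fs, tau, expected):
        segs = segment_stream(np.zeros(n_samples), fs=fs, tau=tau)
        assert len(segs) == expected
        assert all(len(s) == samples_per_segment(tau, fs) for s in segs)

    @pytest.mark.parametrize("fs,tau", [(0.0, 4.0), (-1.0, 4.0), (500.0, 0.0)])
    def test_invalid_parameters_rejected(self, fs, tau):
        with pytest.raises(InvalidParameterError):
            segment_stream(np.zeros(100), fs=fs, tau=tau)

    def test_segments_partition_the_stream(self, rng):
        stream = rng.normal(size=2500)
        segs = segment_stream(stream, fs=100.0, tau=4.0)
        assert len(segs) == 6
        np.testing.assert_array_equal(
            np.concatenate([s.samples for s in segs]), stream[:2400]
        )


class TestMeanRemoval:
    def test_hand_computed_mean_and_centering(self):
        seg = make_segment([1.0, 2.0, 3.0, 4.0], fs=1.0)
        assert segment_mean(seg) == pytest.approx(2.5)
        cs = remove_dc(seg)
        np.testing.assert_allclose(cs.sp, [-1.5, -0.5, 0.5, 1.5])
        assert cs.s_avg == pytest.approx(2.5)

    def test_constant_segment_centers_to_zero(self):
        seg = make_segment(np.full(100, 500.0))
        cs = remove_dc(seg)
        assert np.all(cs.sp == 0.0)
        assert cs.s_avg == 500.0

    def test_output_mean_is_zero(self, rng):
        seg = make_segment(rng.uniform(1e4, 2e5, size=1000))
        assert abs(np.mean(remove_dc(seg).sp)) <= 1e-9 * np.mean(seg.samples)

    def test_non_finite_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            make_segment([1.0, np.nan, 3.0, 4.0], fs=1.0)


class TestSpectrum:
    def test_matches_brute_force_dft(self, rng):
        for n in (8, 17, 64, 101, 256):
            x = rng.normal(size=n)
            spec = amplitude_spectrum(remove_dc(make_segment(x, fs=float(n) / 4)))
            oracle = brute_force_dft_amplitudes(x - x.mean())
            np.testing.assert_allclose(spec.amplitudes, oracle, rtol=1e-6, atol=1e-9)

    def test_parseval_energy_identity(self, rng):
        x = rng.normal(size=512)
        x -= x.mean()
        full = np.fft.fft(x)
        assert np.sum(x**2) == pytest.approx(
            np.sum(np.abs(full) ** 2) / x.size, rel=1e-6
        )
        # and the one-sided amplitudes agree with the two-sided transform
        spec = amplitude_spectrum(remove_dc(make_segment(x, fs=128.0)))
        np.testing.assert_allclose(spec.amplitudes, np.abs(full[: 257]), rtol=1e-9)

    def test_on_bin_cosine_closed_form(self):
        fs, n, f0 = 1000.0, 4000, 1.25
        t = np.arange(n) / fs
        spec = amplitude_spectrum(remove_dc(make_segment(np.cos(2 * np.pi * f0 * t), fs)))
        peak = find_pulse_peak(spec)
        assert peak.f_hr == pytest.approx(1.25)
        assert peak.s_max == pytest.approx(n / 2, rel=1e-9)
        # all other in-band bins are essentially empty
        band = (spec.freqs >= 0.5) & (spec.freqs <= 4.0) & (spec.freqs != f0)
        assert spec.amplitudes[band].max() < 1e-8 * peak.s_max

    def test_frequency_grid(self):
        spec = amplitude_spectrum(remove_dc(make_segment(np.arange(4000.0), 1000.0)))
        assert spec.freqs[0] == 0.0
        assert spec.freqs[1] - spec.freqs[0] == pytest.approx(0.25)
        assert np.all(np.diff(spec.freqs) > 0)
        assert np.all(spec.amplitudes >= 0)

    def test_too_short_segment_rejected(self):
        with pytest.raises(InvalidInputError):
            amplitude_spectrum(remove_dc(make_segment([1.0, 2.0, 3.0], fs=1.0)))


class TestPeakSearch:
    def test_larger_amplitude_wins(self):
        fs, n = 1000.0, 4000
        t = np.arange(n) / fs
        x = 2 * np.cos(2 * np.pi * 1.0 * t) + np.cos(2 * np.pi * 3.0 * t)
        peak = find_pulse_peak(amplitude_spectrum(remove_dc(make_segment(x, fs))))
        assert peak.f_hr == pytest.approx(1.0)

    def test_zero_spectrum_tie_breaks_to_lowest_in_band_bin(self):
        spec = amplitude_spectrum(remove_dc(make_segment(np.zeros(4000), 1000.0)))
        peak = find_pulse_peak(spec)
        assert peak.s_max == 0.0
        assert peak.f_hr == 0.5  # lowest bin with f >= f_min at 0.25 Hz spacing

    def test_band_edges_inclusive(self):
        fs, n = 1000.0, 4000
        t = np.arange(n) / fs
        for f0 in (0.5, 4.0):
            x = np.cos(2 * np.pi * f0 * t)
            peak = find_pulse_peak(amplitude_spectrum(remove_dc(make_segment(x, fs))))
            assert peak.f_hr == pytest.approx(f0)

    def test_empty_band_rejected(self):
        spec = amplitude_spectrum(remove_dc(make_segment(np.zeros(16), fs=4.0)))
        with pytest.raises(InvalidParameterError):
            find_pulse_peak(spec, f_min=0.26, f_max=0.3)  # between bins

    def test_dc_immunity(self, rng):
        fs, n = 1000.0, 4000
        x = rng.normal(size=n) + np.cos(2 * np.pi * 1.25 * np.arange(n) / fs)
        base = detect_pulse(make_segment(x, fs), threshold=0.0)
        for c in (-1e6, 123.456, 2e5):
            shifted = detect_pulse(make_segment(x + c, fs), threshold=0.0)
            assert shifted.f_hr == base.f_hr
            assert shifted.s_max == pytest.approx(base.s_max, rel=1e-9)

    def test_amplitude_equivariance(self, rng):
        fs, n = 500.0, 2000
        x = rng.normal(size=n)
        base = detect_pulse(make_segment(x, fs), threshold=0.0)
        for a in (0.001, 3.0, 1e4):
            scaled = detect_pulse(make_segment(a * x, fs), threshold=0.0)
            assert scaled.f_hr == base.f_hr
            assert scaled.s_max == pytest.approx(a * base.s_max, rel=1e-9)

    def test_noiseless_sinusoid_recovery_at_every_in_band_bin(self):
        fs, n = 1000.0, 4000
        t = np.arange(n) / fs
        for f0 in np.arange(0.5, 4.0 + 1e-9, 0.25):  # every bin in the band
            peak = find_pulse_peak(
                amplitude_spectrum(remove_dc(make_segment(np.sin(2 * np.pi * f0 * t), fs)))
            )
            assert peak.f_hr == pytest.approx(f0)


class TestDecision:
    @pytest.mark.parametrize(
        "s_max,threshold,expected",
        [
            (10000.0, 10000.0, True),  # ties accept H1
            (0.0, 10000.0, False),
            (61427.0, 61426.0, True),
            (61425.0, 61426.0, False),
        ],
    )
    def test_threshold_comparison(self, s_max, threshold, expected):
        from lifesign import SpectralPeak

        d = decide_pulse(SpectralPeak(f_hr=1.0, s_max=s_max), threshold)
        assert d.detected is expected
        assert d.detected == (d.s_max >= d.threshold_used)

    def test_negative_threshold_rejected(self):
        from lifesign import SpectralPeak

        with pytest.raises(InvalidParameterError):
            decide_pulse(SpectralPeak(f_hr=1.0, s_max=5.0), -1.0)

    def test_constant_segment_never_detected(self):
        seg = make_segment(np.full(4000, 12345.0))
        d = detect_pulse(seg, threshold=10000.0)
        assert not d.detected
        assert d.s_max == 0.0

    def test_noise_false_alarm_rate_at_kde_quantile_threshold(self, rng):
        # Threshold placed at the noise statistic's 0.999 KDE quantile keeps
        # the false-alarm fraction at the per-mille level.
        fs, tau, n_seg = 250.0, 4.0, 10_000
        stats = segment_statistics(rng.normal(0, 50.0, size=n_seg * 1000), fs, tau)
        model = KernelDensityModel.fit(stats["s_max"].to_numpy())
        th = model.quantile(0.999)
        assert (stats["s_max"].to_numpy() >= th).mean() <= 0.002


class TestBatchStatistics:
    def test_matches_per_segment_pipeline(self, rng):
        fs, tau = 200.0, 4.0
        stream = rng.normal(1000.0, 20.0, size=4123)
        stats = segment_statistics(stream, fs, tau)
        segs = segment_stream(stream, fs, tau)
        assert len(stats) == len(segs)
        for i, seg in enumerate(segs):
            d = detect_pulse(seg, threshold=0.0)
            assert stats.loc[i, "s_avg"] == pytest.approx(segment_mean(seg))
            assert stats.loc[i, "f_hr"] == pytest.approx(d.f_hr)
            assert stats.loc[i, "s_max"] == pytest.approx(d.s_max)

    def test_empty_stream_gives_empty_frame(self):
        stats = segment_statistics([], 1000.0, 4.0)
        assert stats.empty
        assert list(stats.columns) == ["segment", "start_s", "s_avg", "f_hr", "s_max"]
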