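"""Pre-processing chain: resampling, filtering, rejection, epoching, FFT."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import qeeglda as q
from qeeglda.montage import FREQ_GRID
from qeeglda.spectra import compute_subject_spectra


def _sine_signal(f0, fs, duration, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    data = amp * np.sin(2 * np.pi * f0 * t)[:, None] * np.ones((1, 22))
    return q.MultiChannelSignal(data, fs)


class TestResample:
    def test_noop_at_256(self):
        sig = _sine_signal(10, 256.0, 4)
        out = q.resample_to_256(sig)
        assert out is sig

    def test_sample_count_from_128(self):
        sig = q.MultiChannelSignal(np.zeros((1280, 22)), 128.0)
        assert q.resample_to_256(sig).n_samples == 2560

    def test_spectral_preservation_from_500(self):
        sig = _sine_signal(10, 500.0, 10)
        out = q.resample_to_256(sig)
        assert out.fs == 256.0

        def peak_amp(x, fs):
            spec = np.abs(np.fft.rfft(x)) / x.size * 2
            freqs = np.fft.rfftfreq(x.size, 1 / fs)
            return spec[np.argmin(np.abs(freqs - 10.0))]

        a_in = peak_amp(sig.data[:, 0], 500.0)
        a_out = peak_amp(out.data[:, 0], 256.0)
        assert abs(a_out - a_in) / a_in < 0.01

    def test_unsupported_rate_raises(self):
        with pytest.raises(ValueError):
            q.resample_to_256(q.MultiChannelSignal(np.zeros((100, 22)), 200.0))


class TestBandpass:
    def test_dc_removed(self):
        sig = q.MultiChannelSignal(5.0 * np.ones((256 * 30, 22)), 256.0)
        out = q.bandpass_filter(sig).data[256 * 6:-256 * 6]
        assert np.abs(out).mean() < 0.05

    def test_passband_10hz_unit_gain(self):
        out = q.bandpass_filter(_sine_signal(10, 256.0, 30)).data[256 * 6:-256 * 6, 0]
        amp = np.sqrt(2) * out.std()
        assert abs(amp - 1.0) < 0.01

    def test_stopband_60hz_attenuated(self):
        out = q.bandpass_filter(_sine_signal(60, 256.0, 30)).data[256 * 6:-256 * 6, 0]
        amp = np.sqrt(2) * out.std()
        assert amp < 0.1  # >= 20 dB

    def test_short_signal_raises(self):
        with pytest.raises(ValueError):
            q.bandpass_filter(q.MultiChannelSignal(np.zeros((100, 22)), 256.0))


class TestRejectArtifactEpochs:
    def test_clean_signal_passes_untouched(self, hc_profile):
        truth = q.sample_subject(hc_profile, 300)
        sig = q.synthesize_timeseries(truth, 40.0, 256.0, seed=401)
        clean, quality = q.reject_artifact_epochs(sig)
        assert quality.rejected.sum() == 0
        assert clean.n_samples == 40 * 256

    def test_spike_epoch_rejected_exactly(self, hc_profile):
        truth = q.sample_subject(hc_profile, 300)
        sig = q.synthesize_timeseries(truth, 40.0, 256.0, seed=401)
        sig.data[int(7.5 * 256), 3] += 500.0  # spike inside second 7
        clean, quality = q.reject_artifact_epochs(sig, amplitude_uv=100.0)
        amp_hits = np.nonzero(quality.max_amplitude > 100.0)[0]
        np.testing.assert_array_equal(amp_hits, [7])
        assert quality.rejected[7]
        assert clean.n_samples == 39 * 256

    def test_spatially_deviant_epoch_rejected_by_sstd(self, hc_profile):
        truth = q.sample_subject(hc_profile, 301)
        sig = q.synthesize_timeseries(truth, 40.0, 256.0, seed=402)
        sec = slice(12 * 256, 13 * 256)
        sig.data[sec, :11] *= 4.0  # half the montage blows up -> spatial outlier
        _, quality = q.reject_artifact_epochs(sig, amplitude_uv=1e9, power_z_max=1e9)
        # independent z-score pass over the epoch set
        z = (quality.sstd - quality.sstd.mean()) / quality.sstd.std()
        assert z[12] > 3
        assert quality.rejected[12]
        np.testing.assert_allclose(quality.sstd_z, z)

    def test_zscores_standardized(self, hc_profile):
        truth = q.sample_subject(hc_profile, 302)
        sig = q.synthesize_timeseries(truth, 60.0, 256.0, seed=403)
        _, quality = q.reject_artifact_epochs(sig)
        for z in (quality.power_z, quality.sstd_z):
            assert abs(z.mean()) < 1e-10
            assert abs(z.std() - 1.0) < 1e-10

    def test_all_rejected_raises(self):
        sig = q.MultiChannelSignal(500.0 * np.ones((256 * 5, 22)), 256.0)
        with pytest.raises(ValueError):
            q.reject_artifact_epochs(sig, amplitude_uv=100.0)


class TestSegmentEpochs:
    @pytest.mark.parametrize("duration,expected", [(335, 334), (2, 1), (10, 9)])
    def test_epoch_count(self, duration, expected):
        sig = q.MultiChannelSignal(np.zeros((duration * 256, 22)), 256.0)
        assert q.segment_epochs(sig).n_epochs == expected

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            q.segment_epochs(q.MultiChannelSignal(np.zeros((256, 22)), 256.0))

    @given(duration=st.integers(2, 60))
    def test_count_formula(self, duration):
        sig = q.MultiChannelSignal(np.zeros((duration * 256, 22)), 256.0)
        eps = q.segment_epochs(sig, 2.0, 1.0)
        assert eps.n_epochs == (duration - 2) // 1 + 1

    def test_epochs_tile_signal_left_to_right(self):
        data = np.arange(10 * 256, dtype=float)[:, None] * np.ones((1, 22))
        eps = q.segment_epochs(q.MultiChannelSignal(data, 256.0))
        assert eps.data[0, 0, 0] == 0.0
        assert eps.data[1, 0, 0] == 256.0  # 1-s hop


class TestEpochSpectrum:
    def test_hundred_bins_on_grid(self):
        power = q.epoch_spectrum(np.random.default_rng(0).normal(size=(512, 22)))
        assert power.shape == (22, 100)
        assert np.all(power >= 0)

    def test_on_grid_sinusoid_peaks_at_its_bin(self):
        t = np.arange(512) / 256.0
        x = np.sin(2 * np.pi * 10 * t)[:, None] * np.ones((1, 22))
        power = q.epoch_spectrum(x)
        assert FREQ_GRID[np.argmax(power[0])] == 10.0

    def test_parseval_total_power_equals_variance(self):
        x = np.random.default_rng(1).normal(size=(512, 22))
        full, freqs = q.epoch_spectrum(x, full_band=True)
        total = full[:, 1:].sum(axis=1)  # all non-DC bins
        np.testing.assert_allclose(total, x.var(axis=0), rtol=1e-10)

    def test_wrong_epoch_length_raises(self):
        with pytest.raises(ValueError):
            q.epoch_spectrum(np.zeros((500, 22)))


class TestAverageSpectrum:
    def test_mean_of_identical_epochs_is_identity(self):
        one = np.random.default_rng(0).uniform(0.1, 5.0, size=(1, 22, 100))
        avg = q.average_spectrum(np.repeat(one, 7, axis=0))
        np.testing.assert_allclose(avg.power, one[0])

    def test_truncation_to_334(self):
        powers = np.random.default_rng(0).uniform(0.1, 1.0, size=(400, 22, 100))
        avg = q.average_spectrum(powers, truncate_to=334)
        assert avg.n_epochs == 334
        np.testing.assert_allclose(avg.power, powers[:334].mean(axis=0))

    def test_truncation_beyond_available_raises(self):
        with pytest.raises(ValueError):
            q.average_spectrum(np.ones((10, 22, 100)), truncate_to=11)

    def test_standard_error_shrinks_with_epoch_count(self):
        """Averaging N epochs shrinks the bin-wise error ~ 1/sqrt(N)."""
        rng = np.random.default_rng(5)
        errs = {n: [] for n in (50, 200)}
        for _ in range(60):
            powers = rng.gamma(2.0, 0.5, size=(200, 1, 100))
            for n in errs:
                errs[n].append(np.abs(powers[:n].mean(axis=0) - 1.0).mean())
        ratio = np.mean(errs[50]) / np.mean(errs[200])
        assert 1.6 < ratio < 2.6  # ideal: sqrt(200/50) = 2


class TestFullChain:
    def test_deterministic_and_truncated(self, hc_profile):
        truth = q.sample_subject(hc_profile, 310)
        sig = q.synthesize_timeseries(truth, 370.0, 256.0, seed=500)
        a, _ = compute_subject_spectra(sig, truncate_to=334)
        b, _ = compute_subject_spectra(sig, truncate_to=334)
        np.testing.assert_array_equal(a.power, b.power)
        assert a.n_epochs == 334
        assert np.all(a.power >= 0)
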