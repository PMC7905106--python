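import dataclasses

import numpy as np
import pytest

from manowave.wavelet import (FrequencyGrid, ScaleGrid, Spectrum1D,
                              SynchrosqueezedCWT, WaveletSpectrum,
                              apply_harmonic_clip, cwt, global_power,
                              morlet_ft, synchrosqueeze)

CPM = 1.0 / 60.0


def tone(freq_cpm, duration=3600.0, fs=10.0, amp=1.0, offset=0.0):
    t = np.arange(0, duration, 1 / fs)
    return amp * np.sin(2 * np.pi * freq_cpm * CPM * t) + offset


def central(v, frac=0.8):
    n = v.shape[0]
    k = int(n * (1 - frac) / 2)
    return v[k:n - k]


class TestGrids:
    def test_geometric_spacing_and_edges(self, grid33):
        r = np.diff(np.log(grid33.centers))
        assert np.allclose(r, r[0])
        assert len(grid33.edges) == 34
        # centers are geometric means of their edges
        assert np.allclose(grid33.centers,
                           np.sqrt(grid33.edges[:-1] * grid33.edges[1:]))

    def test_band_default_covers_analysis_range(self, grid33):
        assert np.isclose(grid33.centers_cpm[0], 1 / 16)
        assert np.isclose(grid33.centers_cpm[-1], 16.0)

    def test_bin_membership_half_open(self, grid33):
        k = 10
        assert grid33.bin_index(grid33.edges[k]) == k
        assert grid33.bin_index(grid33.edges[k + 1] - 1e-12) == k
        assert grid33.bin_index(grid33.edges[0] / 2) == -1
        assert grid33.bin_index(grid33.edges[-1] * 1.01) == -1

    def test_scales_cover_grid(self, grid33, scales33):
        f = scales33.frequencies
        assert f.min() <= grid33.edges[0] * 1.001
        assert f.max() >= grid33.edges[-1] * 0.999


class TestCWT:
    def test_zero_signal_zero_coefficients(self, scales33, fs):
        w = cwt(np.zeros(1000), fs, scales33)
        assert np.allclose(w, 0.0)

    def test_linearity(self, scales33, fs):
        rng = np.random.default_rng(0)
        x = rng.normal(size=600)
        w1 = cwt(x, fs, scales33)
        w3 = cwt(3.0 * x, fs, scales33)
        assert np.allclose(w3, 3.0 * w1, atol=1e-10)

    def test_fft_path_matches_time_domain_convolution(self, fs):
        # brute-force oracle: convolve with the inverse-FFT'd wavelet on a
        # circularly padded short signal
        rng = np.random.default_rng(2)
        n = 256
        x = rng.normal(size=n)
        grid = FrequencyGrid.from_band(2.0, 12.0, 5)
        scales = ScaleGrid.for_grid(grid, voices_per_octave=4)
        w = cwt(x, fs, scales)

        npad = 512  # the transform pads 256 -> 512
        xp = np.zeros(npad)
        xp[:n] = x - x.mean()
        omega = 2 * np.pi * np.fft.fftfreq(npad, 1 / fs)
        taus = np.arange(npad)
        for i, s in enumerate(scales.scales):
            # time-domain wavelet via inverse FFT of the analytic Morlet
            psi = np.fft.ifft(np.sqrt(s) * morlet_ft(s * omega,
                                                     scales.omega0))
            # direct circular-convolution oracle
            conv = np.array([np.sum(xp * psi[(t - taus) % npad])
                             for t in range(n)])
            rel = (np.abs(conv - w[:, i]).max()
                   / max(np.abs(w[:, i]).max(), 1e-30))
            assert rel < 1e-8

    def test_peak_scale_tracks_tone(self, fs):
        grid = FrequencyGrid.from_band(n=33)
        scales = ScaleGrid.for_grid(grid)
        x = tone(3.0)
        w = cwt(x, fs, scales)
        power = np.abs(central(w)) ** 2
        peak = np.argmax(power.mean(axis=0))
        f_peak = scales.frequencies[peak]
        assert abs(np.log(f_peak / (3.0 * CPM))) < np.log(2 ** (1 / 8))

    def test_inadmissible_scales_rejected(self):
        grid = FrequencyGrid.from_band(n=5)
        scales = ScaleGrid.for_grid(grid)
        with pytest.raises(ValueError, match="Nyquist"):
            cwt(np.ones(100), 1e-9, scales)


class TestHarmonicClipHook:
    def test_identity_default(self):
        w = np.arange(12.0).reshape(4, 3) + 0j
        assert np.array_equal(apply_harmonic_clip(w), w)

    def test_wrong_shape_plugin_rejected(self):
        w = np.ones((4, 3), complex)
        with pytest.raises(ValueError, match="shape"):
            apply_harmonic_clip(w, lambda a: a[:2])

    def test_scaling_plugin_scales_power_quadratically(self, fs):
        grid = FrequencyGrid.from_band(n=17)
        x = tone(3.0, duration=600.0)
        tf_id = SynchrosqueezedCWT(n_freq=17)
        tf_half = SynchrosqueezedCWT(n_freq=17, clip_hook=lambda w: 0.5 * w)
        from manowave.preprocess import PressureRecording
        rec = PressureRecording(np.vstack([x, x]), fs=fs)
        p_id = np.exp(tf_id.spectrum1d(rec).y)
        p_half = np.exp(tf_half.spectrum1d(rec).y)
        assert np.allclose(p_half, 0.25 * p_id, rtol=1e-6)


class TestSynchrosqueeze:
    def test_zero_coefficients_zero_spectrum(self, grid33, scales33, fs):
        w = np.zeros((500, len(scales33.scales)), complex)
        v = synchrosqueeze(w, scales33, fs, grid33)
        assert np.allclose(v.v, 0.0)

    @pytest.mark.parametrize("cpm", [1 / 8, 1 / 2, 1, 3, 6, 12])
    def test_tone_peak_bin(self, cpm, grid33, scales33, fs):
        x = tone(cpm)
        w = cwt(x, fs, scales33)
        v = synchrosqueeze(w, scales33, fs, grid33)
        sp = global_power(
            dataclasses.replace(v, v=central(v.v)))
        assert np.argmax(sp.y) == grid33.bin_index(cpm * CPM)

    def test_chirp_tracks_instantaneous_frequency(self, grid33, scales33,
                                                  fs):
        # slow linear chirp 2 -> 6 cpm over 1 h
        t = np.arange(0, 3600, 1 / fs)
        f0, f1 = 2.0 * CPM, 6.0 * CPM
        phase = 2 * np.pi * (f0 * t + (f1 - f0) * t ** 2 / (2 * 3600.0))
        x = np.sin(phase)
        w = cwt(x, fs, scales33)
        v = synchrosqueeze(w, scales33, fs, grid33)
        n = len(t)
        k0, k1 = int(0.1 * n), int(0.9 * n)
        window = 3000
        hits = 0
        checks = 0
        for start in range(k0, k1 - window, window):
            seg = np.abs(v.v[start:start + window]) ** 2
            peak = np.argmax(seg.mean(axis=0))
            f_true = f0 + (f1 - f0) * t[start + window // 2] / 3600.0
            checks += 1
            hits += int(abs(peak - grid33.bin_index(f_true)) <= 1)
        assert checks >= 5 and hits == checks


class TestGlobalPower:
    def make_spectrum(self, v, grid, mask=None):
        return WaveletSpectrum(v, grid, 10.0, mask)

    def test_constant_amplitude(self, grid9):
        v = np.full((100, 9), 2.0 + 0j)
        sp = global_power(self.make_spectrum(v, grid9))
        assert np.allclose(np.exp(sp.y), 4.0)

    def test_two_channel_flattening_averages(self, grid9):
        va = np.full((50, 9), 2.0 + 0j)   # power 4
        vb = np.full((50, 9), 4.0 + 0j)   # power 16
        sp = global_power([self.make_spectrum(va, grid9),
                           self.make_spectrum(vb, grid9)])
        assert np.allclose(np.exp(sp.y), 10.0)

    def test_mask_excludes_samples(self, grid9):
        v = np.ones((100, 9), complex)
        v[:50] = 0.0
        mask = np.zeros(100, bool)
        mask[:50] = True
        sp = global_power(self.make_spectrum(v, grid9, mask))
        assert np.allclose(np.exp(sp.y), 1.0)

    def test_all_masked_rejected(self, grid9):
        v = np.ones((10, 9), complex)
        mask = np.ones(10, bool)
        with pytest.raises(ValueError, match="masked"):
            global_power(self.make_spectrum(v, grid9, mask))

    def test_quadratic_homogeneity(self, fs, grid33, scales33):
        x = tone(3.0, duration=600.0)
        w1 = cwt(x, fs, scales33)
        w2 = cwt(2.0 * x, fs, scales33)
        p1 = np.exp(global_power(synchrosqueeze(w1, scales33, fs,
                                                grid33)).y)
        p2 = np.exp(global_power(synchrosqueeze(w2, scales33, fs,
                                                grid33)).y)
        assert np.allclose(p2, 4.0 * p1, rtol=1e-8)

    def test_offset_invariance(self, fs, grid33, scales33):
        x = tone(3.0, duration=600.0)
        pa = np.abs(cwt(x, fs, scales33))
        pb = np.abs(cwt(x + 15.0, fs, scales33))
        rel = np.abs(pa - pb).max() / np.abs(pa).max()
        assert rel < 1e-6


class TestEstimator:
    def test_get_set_params_roundtrip(self):
        tf = SynchrosqueezedCWT(n_freq=17)
        params = tf.get_params()
        assert params["n_freq"] == 17
        tf.set_params(omega0=5.0)
        assert tf.omega0 == 5.0
        with pytest.raises(ValueError):
            tf.set_params(bogus=1)

    def test_spectrum1d_carries_labels(self, fs):
        from manowave.preprocess import PressureRecording, RecordingMeta
        x = tone(3.0, duration=300.0)
        rec = PressureRecording(np.vstack([x, x]), fs=fs,
                                meta=RecordingMeta(subject="s1",
                                                   group="patient"))
        sp = SynchrosqueezedCWT(n_freq=9).spectrum1d(rec)
        assert isinstance(sp, Spectrum1D)
        assert sp.meta["group"] == "patient"
        assert sp.meta["nchan"] == 2
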