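import numpy as np
import pytest

from manowave.cross import (CrossSpectrum, PhaseGrid, cross_wavelet,
                            pace_of, phase_histogram, phase_to_velocity,
                            velocity_to_phase)
from manowave.preprocess import PressureRecording
from manowave.simulate import WaveSpec, simulate_recording
from manowave.wavelet import (FrequencyGrid, ScaleGrid, WaveletSpectrum,
                              cwt, synchrosqueeze)

CPM = 1.0 / 60.0


def squeeze_tone(freq_cpm, delay=0.0, fs=10.0, duration=3600.0, n_freq=17):
    grid = FrequencyGrid.from_band(n=n_freq)
    scales = ScaleGrid.for_grid(grid)
    t = np.arange(0, duration, 1 / fs)
    x = np.sin(2 * np.pi * freq_cpm * CPM * (t - delay))
    return synchrosqueeze(cwt(x, fs, scales), scales, fs, grid), grid


class TestPhaseGrid:
    def test_uniform_periodic_bins(self):
        pg = PhaseGrid(18)
        assert np.isclose(pg.width, 2 * np.pi / 18)
        assert np.allclose(np.diff(pg.centers), pg.width)
        assert np.isclose(pg.edges[0], -np.pi)
        assert np.isclose(pg.edges[-1], np.pi)

    def test_pi_wraps_into_last_bin(self):
        pg = PhaseGrid(18)
        assert pg.bin_index(np.pi) == 17
        assert pg.bin_index(-np.pi + 1e-9) == 0
        assert pg.bin_index(0.0) == 9  # first bin right of the midline


class TestCrossWavelet:
    def test_self_product_is_power_with_zero_phase(self):
        v, _ = squeeze_tone(3.0, duration=600.0)
        vab = cross_wavelet(v, v)
        assert np.allclose(vab.imag, 0.0, atol=1e-12)
        assert np.allclose(vab.real, np.abs(v.v) ** 2)

    def test_swap_conjugates(self):
        va, grid = squeeze_tone(3.0, duration=600.0)
        vb, _ = squeeze_tone(3.0, delay=2.0, duration=600.0)
        assert np.allclose(cross_wavelet(vb, va),
                           np.conj(cross_wavelet(va, vb)))

    def test_grid_mismatch_rejected(self):
        va, _ = squeeze_tone(3.0, duration=600.0, n_freq=17)
        vb, _ = squeeze_tone(3.0, duration=600.0, n_freq=9)
        with pytest.raises(ValueError):
            cross_wavelet(va, vb)

    def test_delayed_tone_phase(self):
        # b delayed by Delta seconds: angle(v_ab) ~ 2*pi*f*Delta at the tone
        delta = 2.0
        f = 3.0 * CPM
        va, grid = squeeze_tone(3.0)
        vb, _ = squeeze_tone(3.0, delay=delta)
        vab = cross_wavelet(va, vb)
        k = grid.bin_index(f)
        n = vab.shape[0]
        sl = slice(n // 10, 9 * n // 10)
        phases = np.angle(vab[sl, k])
        expected = 2 * np.pi * f * delta
        err = np.abs(np.angle(np.exp(1j * (phases - expected))))
        assert np.median(err) < 0.05


class TestPhaseHistogram:
    def test_identical_signals_mass_at_zero(self):
        v, grid = squeeze_tone(3.0, duration=600.0)
        vab = cross_wavelet(v, v)
        pg = PhaseGrid(18)
        sp = phase_histogram(vab, pg, grid)
        zero_bin = pg.bin_index(0.0)
        k = grid.bin_index(3.0 * CPM)
        assert np.argmax(sp.y[k]) == zero_bin
        # all other bins are at the floor
        others = np.delete(sp.power[k], zero_bin)
        assert np.all(others == 0.0)

    def test_conjugation_mirror_symmetry(self):
        va, grid = squeeze_tone(3.0)
        vb, _ = squeeze_tone(3.0, delay=2.0)
        pg = PhaseGrid(18)
        h_ab = phase_histogram(cross_wavelet(va, vb), pg, grid)
        h_ba = phase_histogram(cross_wavelet(vb, va), pg, grid)
        # phi -> -phi maps bin m to M-1-m on the symmetric grid, bin-exact
        assert np.array_equal(h_ab.counts, h_ba.counts[:, ::-1])
        assert np.allclose(h_ab.power, h_ba.power[:, ::-1])

    def test_partition_of_total_mass(self):
        va, grid = squeeze_tone(3.0, duration=600.0)
        vb, _ = squeeze_tone(3.0, delay=1.0, duration=600.0)
        vab = cross_wavelet(va, vb)
        pg = PhaseGrid(12)
        sp = phase_histogram(vab, pg, grid)
        total_binned = np.sum(sp.counts * sp.power, axis=1)
        assert np.allclose(total_binned, np.abs(vab).sum(axis=0))

    def test_delayed_tone_argmax_bin(self):
        delta = 2.0
        f = 3.0 * CPM
        va, grid = squeeze_tone(3.0)
        vb, _ = squeeze_tone(3.0, delay=delta)
        vab = cross_wavelet(va, vb)
        pg = PhaseGrid(18)
        sp = phase_histogram(vab, pg, grid)
        k = grid.bin_index(f)
        expected_bin = pg.bin_index(2 * np.pi * f * delta)
        assert abs(int(np.argmax(sp.power[k])) - int(expected_bin)) <= 1

    def test_masked_samples_excluded(self):
        v, grid = squeeze_tone(3.0, duration=600.0)
        vab = cross_wavelet(v, v)
        pg = PhaseGrid(6)
        mask = np.zeros(vab.shape[0], bool)
        mask[: vab.shape[0] // 2] = True
        full = phase_histogram(vab, pg, grid)
        half = phase_histogram(vab, pg, grid, mask=mask)
        assert half.counts.sum() < full.counts.sum()


class TestVelocityMapping:
    def test_algebraic_inversion(self):
        # phi constructed from a known velocity maps back to it
        u0, d, f = 2.0, 1.0, 0.05
        phi = d * 2 * np.pi * f / u0
        assert np.isclose(phase_to_velocity(phi, f, d), u0)

    def test_synchronous_pace_zero(self):
        assert pace_of(0.0, 0.05, 1.0) == 0.0
        assert np.isinf(phase_to_velocity(0.0, 0.05, 1.0))

    def test_direct_arithmetic(self):
        # d=1 cm, f=3 cpm=0.05 Hz, phi=pi -> u = 2*pi*0.05/pi = 0.1 cm/s
        assert np.isclose(phase_to_velocity(np.pi, 0.05, 1.0), 0.1)

    def test_out_of_range_phase_rejected(self):
        with pytest.raises(ValueError, match="normalize"):
            phase_to_velocity(3 * np.pi, 0.05, 1.0)

    def test_sign_gives_direction(self):
        u_pos = phase_to_velocity(0.5, 0.05, 1.0)
        u_neg = phase_to_velocity(-0.5, 0.05, 1.0)
        assert u_pos > 0 > u_neg
        assert np.isclose(u_pos, -u_neg)


class TestPropagatingWave:
    def test_velocity_recovered_within_one_phase_bin(self):
        # antegrade wave at u0 across a 10-channel, 1 cm spaced array
        u0 = 0.5  # cm/s
        rec = simulate_recording(
            waves=[WaveSpec(freq_cpm=3.0, amplitude=15.0,
                            velocity_cm_s=u0, burst_interval_s=None)],
            n_channels=10, fs=10.0, duration_s=3600.0, noise_sd=0.05,
            seed=11)
        cs = CrossSpectrum(n_freq=17, n_phase=18)
        sp = cs.spectrum2d(rec)
        f = 3.0 * CPM
        k = sp.fgrid.bin_index(f)
        m = int(np.argmax(sp.power[k]))
        phi_hat = sp.pgrid.centers[m]
        phi_true = velocity_to_phase(u0, f, rec.spacing)
        assert phi_true > 0  # antegrade on the positive side
        assert abs(phi_hat - phi_true) <= sp.pgrid.width

    def test_retrograde_wave_on_negative_side(self):
        rec = simulate_recording(
            waves=[WaveSpec(freq_cpm=3.0, amplitude=15.0,
                            velocity_cm_s=-0.5, burst_interval_s=None)],
            n_channels=10, fs=10.0, duration_s=1800.0, noise_sd=0.05,
            seed=12)
        sp = CrossSpectrum(n_freq=17, n_phase=18).spectrum2d(rec)
        k = sp.fgrid.bin_index(3.0 * CPM)
        m = int(np.argmax(sp.power[k]))
        assert sp.pgrid.centers[m] < 0
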