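import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from vocalchimera.auditory import (AuditorySpectrogram, AuditorySpectrum,
                                   envelope_extract, erb_space,
                                   gammatone_filterbank)
from vocalchimera.features import (RateScalePlane, UnvoicedError,
                                   acoustic_profile, dominant_rate_scale,
                                   estimate_f0, hnr, modulation_spectrum,
                                   spectral_centroid)
from vocalchimera.synth import ToneSpec, synth_instrument, synth_vowel
from vocalchimera.waveform import Waveform

RATE = 44100.0


def harmonic_noise_mixture(hnr_db, f0=220.0, dur=0.25, seed=0, n_harm=15):
    """Independent oracle mixture: harmonic complex plus band-limited
    noise at an exactly known power ratio."""
    t = np.arange(int(dur * RATE)) / RATE
    harm = sum(np.sin(2 * np.pi * k * f0 * t) / k for k in range(1, n_harm + 1))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(t.size)
    sos = butter(4, 5000.0 / (RATE / 2), output="sos")
    noise = sosfiltfilt(sos, noise)
    p_h, p_n = np.mean(harm**2), np.mean(noise**2)
    noise *= np.sqrt(p_h / (p_n * 10 ** (hnr_db / 10)))
    return Waveform(harm + noise, RATE)


class TestEstimateF0:
    def test_synthetic_vowel_at_220(self):
        w = synth_vowel(ToneSpec(kind="vowel", timbre_id="a_s1", f0_hz=220.0,
                                 duration_ms=250.0, target_hnr_db=25.0))
        assert estimate_f0(w) == pytest.approx(220.0, abs=1.0)

    def test_pure_sine_330(self):
        t = np.arange(int(0.25 * RATE)) / RATE
        assert estimate_f0(Waveform(np.sin(2 * np.pi * 330 * t), RATE)) == \
               pytest.approx(330.0, abs=1.0)

    def test_white_noise_is_unvoiced(self):
        rng = np.random.default_rng(5)
        with pytest.raises(UnvoicedError):
            estimate_f0(Waveform(rng.standard_normal(11025), RATE))


class TestHnr:
    def test_noiseless_harmonic_tone_is_high(self):
        w = harmonic_noise_mixture(120.0)   # essentially noise-free
        assert hnr(w) >= 40.0

    @pytest.mark.parametrize("target", [0.0, 10.0, 20.0, 30.0, 40.0])
    def test_recovers_constructed_power_ratio(self, target):
        assert hnr(harmonic_noise_mixture(target)) == pytest.approx(target, abs=2.0)

    def test_white_noise_is_nonpositive(self):
        rng = np.random.default_rng(7)
        assert hnr(Waveform(rng.standard_normal(22050), RATE)) <= 0.0

    def test_capped_at_sixty(self):
        t = np.arange(int(0.25 * RATE)) / RATE
        assert hnr(Waveform(np.sin(2 * np.pi * 220 * t), RATE)) <= 60.0


class TestSpectralCentroid:
    def test_single_channel_returns_its_cf(self):
        cfs = np.array([100.0, 500.0, 2000.0])
        spec = AuditorySpectrum(level=np.array([0.0, 3.0, 0.0]), cf_hz=cfs)
        assert spectral_centroid(spec) == 500.0

    def test_two_equal_channels_give_midpoint(self):
        spec = AuditorySpectrum(level=np.array([1.0, 0.0, 1.0]),
                                cf_hz=np.array([400.0, 800.0, 1200.0]))
        assert spectral_centroid(spec) == 800.0

    def test_gain_invariance(self):
        level = np.array([1.0, 2.0, 0.5])
        cfs = np.array([200.0, 700.0, 1500.0])
        c1 = spectral_centroid(AuditorySpectrum(level=level, cf_hz=cfs))
        c2 = spectral_centroid(AuditorySpectrum(level=7.7 * level, cf_hz=cfs))
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_zero_spectrum_raises(self):
        with pytest.raises(ValueError):
            spectral_centroid(AuditorySpectrum(level=np.zeros(3),
                                               cf_hz=np.array([1.0, 2.0, 3.0])))

    def test_monotone_in_brightness(self):
        cents = []
        for tilt in (-6.0, -3.0, 0.0, 3.0):
            w = synth_instrument(ToneSpec(kind="instrument", timbre_id="oboe",
                                          f0_hz=220.0, duration_ms=250.0,
                                          brightness=tilt, target_hnr_db=30.0))
            from vocalchimera.auditory import auditory_spectrum

            spec = auditory_spectrum(envelope_extract(gammatone_filterbank(w)))
            cents.append(spectral_centroid(spec))
        assert np.all(np.diff(cents) > 0)


def ripple_spectrogram(density_cpo, rate_hz, dur_s=1.0, frame_rate=200.0):
    cfs = erb_space(80.0, 8000.0, 64)
    oct_c = np.log2(cfs)
    t = np.arange(int(dur_s * frame_rate)) / frame_rate
    env = 1.0 + 0.9 * np.sin(2 * np.pi * (rate_hz * t[None, :]
                                          - density_cpo * oct_c[:, None]))
    return AuditorySpectrogram(env=env, cf_hz=cfs, frame_rate_hz=frame_rate)


class TestModulationSpectrum:
    def test_static_spectrum_concentrates_at_zero_rate(self):
        cfs = erb_space(80.0, 8000.0, 64)
        env = np.outer(np.exp(-(np.log2(cfs) - np.log2(800.0)) ** 2), np.ones(100))
        plane = modulation_spectrum(AuditorySpectrogram(env=env, cf_hz=cfs,
                                                        frame_rate_hz=200.0))
        marginal = plane.energy.sum(axis=0)
        assert marginal[plane.rate_axis < 1.0].sum() / marginal.sum() > 0.99

    def test_moving_ripple_peaks_at_its_parameters(self):
        plane = modulation_spectrum(ripple_spectrogram(2.0, 8.0))
        sub = plane.energy[plane.scale_axis > 0.1][:, plane.rate_axis > 1.0]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        assert plane.rate_axis[plane.rate_axis > 1.0][j] == pytest.approx(8.0, abs=0.5)
        assert plane.scale_axis[plane.scale_axis > 0.1][i] == pytest.approx(2.0, abs=0.25)

    def test_energy_nonnegative_and_shapes(self):
        plane = modulation_spectrum(ripple_spectrogram(1.0, 4.0, dur_s=0.25))
        assert np.all(plane.energy >= 0)
        assert plane.energy.shape == (plane.scale_axis.size, plane.rate_axis.size)

    def test_degenerate_dimensions_raise(self):
        sg = AuditorySpectrogram(env=np.ones((1, 10)), cf_hz=np.array([100.0]),
                                 frame_rate_hz=200.0)
        with pytest.raises(ValueError):
            modulation_spectrum(sg)


class TestDominantRateScale:
    def one_cell_plane(self, r0, s0):
        rates = np.arange(0.0, 32.0, 0.5)
        scales = np.arange(0.0, 8.0, 0.25)
        energy = np.zeros((scales.size, rates.size))
        energy[np.argmin(np.abs(scales - s0)), np.argmin(np.abs(rates - r0))] = 1.0
        return RateScalePlane(energy=energy, rate_axis=rates, scale_axis=scales)

    def test_single_cell_returned_exactly(self):
        plane = self.one_cell_plane(8.0, 2.0)
        assert dominant_rate_scale(plane) == (8.0, 2.0)

    def test_two_equal_cells_give_midpoint(self):
        plane = self.one_cell_plane(4.0, 1.0)
        plane.energy[np.argmin(np.abs(plane.scale_axis - 3.0)),
                     np.argmin(np.abs(plane.rate_axis - 12.0))] = 1.0
        assert dominant_rate_scale(plane) == (8.0, 2.0)

    def test_zero_plane_raises(self):
        plane = self.one_cell_plane(8.0, 2.0)
        plane.energy[:] = 0.0
        with pytest.raises(ValueError):
            dominant_rate_scale(plane)

    def test_dominant_scale_monotone_in_ripple_density(self):
        scales = [dominant_rate_scale(modulation_spectrum(
            ripple_spectrogram(d, 8.0)))[1] for d in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(scales) > 0)

    @pytest.mark.parametrize("am_hz", [4.0, 8.0, 16.0])
    def test_dominant_rate_tracks_am_frequency(self, am_hz):
        t = np.arange(int(1.0 * RATE)) / RATE
        x = (1.0 + np.sin(2 * np.pi * am_hz * t)) * np.sin(2 * np.pi * 1000 * t)
        sg = envelope_extract(gammatone_filterbank(Waveform(x, RATE)))
        dom_rate, _ = dominant_rate_scale(modulation_spectrum(sg))
        assert dom_rate == pytest.approx(am_hz, abs=1.0)


class TestAcousticProfile:
    def test_clean_vowel_profile(self):
        w = synth_vowel(ToneSpec(kind="vowel", timbre_id="a_s1", f0_hz=220.0,
                                 duration_ms=250.0, target_hnr_db=60.0))
        p = acoustic_profile(w)
        assert p.f0_hz == pytest.approx(220.0, abs=1.0)
        assert p.hnr_db >= 40.0
        assert p.centroid_hz > 0 and p.dom_scale_cpo > 0 and p.dom_rate_hz >= 0

    def test_identical_waveforms_identical_profiles(self):
        w = synth_vowel(ToneSpec(kind="vowel", timbre_id="i_s2", f0_hz=330.0,
                                 duration_ms=128.0, target_hnr_db=20.0, seed=9))
        assert acoustic_profile(w) == acoustic_profile(w)
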