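"""Gammatone auditory filterbank front end.

Decomposes a waveform into ERB-spaced frequency bands approximating
cochlear frequency selectivity, extracts band envelopes (half-wave
rectification followed by a 70-Hz low-pass, the order used for the
spectral-centroid definition), and collapses them into auditory
spectrograms and time-averaged auditory spectra.

Defaults: 64 channels between 80 and 8000 Hz on the Glasberg-Moore
ERB-rate scale; 4th-order gammatone filters applied forward-backward
(zero phase) so that summing rescaled bands — the chimera resynthesis
path — preserves waveform alignment across channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .waveform import Waveform

DEFAULT_N_CHANNELS = 64
DEFAULT_CF_LO_HZ = 80.0
DEFAULT_CF_HI_HZ = 8000.0
DEFAULT_ENV_LP_HZ = 70.0
DEFAULT_FRAME_RATE_HZ = 200.0


def erb_hz(f_hz):
    """Equivalent rectangular bandwidth at frequency f (Glasberg-Moore)."""
    return 24.7 * (4.37 * np.asarray(f_hz) / 1000.0 + 1.0)


def hz_to_erb_rate(f_hz):
    """Frequency -> ERB-rate (ERB-number) scale."""
    return 21.4 * np.log10(4.37 * np.asarray(f_hz) / 1000.0 + 1.0)


def erb_rate_to_hz(e):
    return (10.0 ** (np.asarray(e) / 21.4) - 1.0) * 1000.0 / 4.37


def erb_space(cf_lo_hz: float, cf_hi_hz: float, n_channels: int) -> np.ndarray:
    """Center frequencies uniformly spaced on the ERB-rate scale."""
    lo, hi = hz_to_erb_rate(cf_lo_hz), hz_to_erb_rate(cf_hi_hz)
    return erb_rate_to_hz(np.linspace(lo, hi, n_channels))


@dataclass(frozen=True)
class FilterbankConfig:
    n_channels: int = DEFAULT_N_CHANNELS
    cf_lo_hz: float = DEFAULT_CF_LO_HZ
    cf_hi_hz: float = DEFAULT_CF_HI_HZ


@dataclass
class BandDecomposition:
    """Output of the gammatone filterbank: one band signal per channel."""

    band_signals: np.ndarray     # (n_channels, n_samples)
    cf_hz: np.ndarray            # ascending center frequencies
    rate_hz: float

    def __post_init__(self) -> None:
        if self.band_signals.shape[0] != self.cf_hz.size:
            raise ValueError("one band signal required per center frequency")
        if np.any(np.diff(self.cf_hz) <= 0):
            raise ValueError("cf_hz must be strictly increasing")


@dataclass
class AuditorySpectrogram:
    """Nonnegative channel x frame envelope matrix."""

    env: np.ndarray              # (n_channels, n_frames), >= 0
    cf_hz: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if self.env.shape[0] != self.cf_hz.size:
            raise ValueError("env rows must match cf_hz")
        if np.any(self.env < 0):
            raise ValueError("envelope values must be nonnegative")


@dataclass
class AuditorySpectrum:
    """Time-averaged envelope level per channel."""

    level: np.ndarray
    cf_hz: np.ndarray

    def __post_init__(self) -> None:
        if self.level.size != self.cf_hz.size:
            raise ValueError("level must match cf_hz")
        if np.any(self.level < 0):
            raise ValueError("levels must be nonnegative")


def gammatone_filterbank(
    w: Waveform,
    n_channels: int = DEFAULT_N_CHANNELS,
    cf_lo_hz: float = DEFAULT_CF_LO_HZ,
    cf_hi_hz: float = DEFAULT_CF_HI_HZ,
) -> BandDecomposition:
    """Split a waveform into ERB-spaced 4th-order gammatone bands.

    Each channel applies the analytic 4th-order gammatone magnitude
    response ``(1 + (2 pi (f - cf) tau)^2)^-2`` (tau set from 1.019 ERB
    bandwidths) in the frequency domain, i.e. zero-phase.  All bands
    stay time-aligned with the input, so direct summation of rescaled
    bands — the chimera resynthesis path — reconstructs a spectrally
    reshaped but temporally coherent signal.
    """
    nyq = w.rate_hz / 2.0
    if not (0.0 < cf_lo_hz < cf_hi_hz < nyq):
        raise ValueError("need 0 < cf_lo < cf_hi < Nyquist")
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    cfs = erb_space(cf_lo_hz, cf_hi_hz, n_channels)
    n = w.n_samples
    spec = np.fft.rfft(w.samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / w.rate_hz)
    tau = 1.0 / (2.0 * np.pi * 1.019 * erb_hz(cfs))          # (n_channels,)
    det = 2.0 * np.pi * (freqs[None, :] - cfs[:, None]) * tau[:, None]
    mag = (1.0 + det**2) ** -2
    bands = np.fft.irfft(mag * spec[None, :], n=n, axis=1)
    return BandDecomposition(band_signals=bands, cf_hz=cfs, rate_hz=w.rate_hz)


def envelope_extract(
    bands: BandDecomposition,
    lp_hz: float = DEFAULT_ENV_LP_HZ,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
) -> AuditorySpectrogram:
    """Half-wave rectify each band, low-pass at ``lp_hz`` (zero-phase
    Butterworth), then decimate to ``frame_rate_hz`` frames."""
    if lp_hz >= bands.rate_hz / 2.0:
        raise ValueError("lp_hz must be below Nyquist")
    rect = np.maximum(bands.band_signals, 0.0)
    sos = butter(4, lp_hz / (bands.rate_hz / 2.0), output="sos")
    env = sosfiltfilt(sos, rect, axis=1)
    env = np.maximum(env, 0.0)      # filter ringing can dip slightly below 0
    step = max(int(round(bands.rate_hz / frame_rate_hz)), 1)
    env = env[:, ::step]
    return AuditorySpectrogram(env=env, cf_hz=bands.cf_hz.copy(),
                               frame_rate_hz=bands.rate_hz / step)


def auditory_spectrum(sg: AuditorySpectrogram) -> AuditorySpectrum:
    """Per-channel time mean of the envelope (the side-panel spectrum)."""
    if sg.env.shape[1] < 1:
        raise ValueError("spectrogram must contain at least one frame")
    return AuditorySpectrum(level=sg.env.mean(axis=1), cf_hz=sg.cf_hz.copy())


def waveform_auditory_spectrum(w: Waveform, fb: FilterbankConfig | None = None) -> AuditorySpectrum:
    """Convenience: waveform -> filterbank -> envelope -> spectrum."""
    fb = fb or FilterbankConfig()
    bands = gammatone_filterbank(w, fb.n_channels, fb.cf_lo_hz, fb.cf_hi_hz)
    return auditory_spectrum(envelope_extract(bands))


def save_spectrogram_tsv(path, sg: AuditorySpectrogram) -> None:
    """Serialize a spectrogram as TSV with cf/frame-rate header lines."""
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz\t{sg.frame_rate_hz}\n")
        fh.write("# cf_hz\t" + "\t".join(f"{cf:.6f}" for cf in sg.cf_hz) + "\n")
        np.savetxt(fh, sg.env.T, delimiter="\t")


def load_spectrogram_tsv(path) -> AuditorySpectrogram:
    with open(path) as fh:
        frame_rate = float(fh.readline().split("\t")[1])
        cfs = np.array([float(v) for v in fh.readline().split("\t")[1:]])
        env = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    return AuditorySpectrogram(env=env, cf_hz=cfs, frame_rate_hz=frame_rate)
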