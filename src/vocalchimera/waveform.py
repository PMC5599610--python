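"""Mono waveform container and level/windowing primitives.

Every stimulus operation in the package consumes and produces
:class:`Waveform` objects: a 1-D float array of dimensionless amplitude
plus a sample rate.  Levels are always controlled through RMS
(root-mean-square) amplitude, the only intensity normalization applied
to the stimulus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class Waveform:
    """Mono audio signal.

    Parameters
    ----------
    samples : ndarray
        1-D float array of finite amplitudes.
    rate_hz : float
        Sampling rate in samples/second, > 0.
    """

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz


def rms_normalize(w: Waveform, target_rms: float = 0.05) -> Waveform:
    """Rescale so the output RMS equals ``target_rms``.

    All stimuli in a bank are equalized this way; shape is unchanged up
    to a positive scalar.  Raises on an identically-zero input, which
    has no defined gain.
    """
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    current = w.rms()
    if current == 0.0:
        raise ValueError("cannot RMS-normalize an all-zero signal")
    return Waveform(w.samples * (target_rms / current), w.rate_hz)


def _raised_cosine(n: int, rising: bool) -> np.ndarray:
    # Half a Hann period sampled so the extreme samples sit on 1 and ~0.
    t = np.arange(1, n + 1) / n
    fall = 0.5 * (1.0 + np.cos(np.pi * t))
    return fall[::-1] if rising else fall


def apply_offset_ramp(w: Waveform, end_ms: float, ramp_ms: float = 5.0) -> Waveform:
    """Fade the signal out at ``end_ms`` with a raised-cosine window.

    Samples after ``end_ms`` are zeroed; the ``ramp_ms`` immediately
    before it are multiplied by a raised cosine falling from 1 to 0;
    earlier samples are untouched.
    """
    if end_ms <= 0 or ramp_ms <= 0:
        raise ValueError("end_ms and ramp_ms must be positive")
    if end_ms > 1000.0 * w.duration_s + 0.5 / w.rate_hz * 1000.0:
        raise ValueError("end_ms exceeds the signal duration")
    if ramp_ms > end_ms:
        raise ValueError("ramp longer than the signal portion to keep")
    end = min(int(round(end_ms * 1e-3 * w.rate_hz)), w.n_samples)
    n_ramp = int(round(ramp_ms * 1e-3 * w.rate_hz))
    out = w.samples.copy()
    out[end:] = 0.0
    out[end - n_ramp : end] *= _raised_cosine(n_ramp, rising=False)
    return Waveform(out, w.rate_hz)


def apply_onset_ramp(w: Waveform, ramp_ms: float = 5.0) -> Waveform:
    """Raised-cosine fade-in over the first ``ramp_ms`` (anti-click)."""
    n_ramp = int(round(ramp_ms * 1e-3 * w.rate_hz))
    if n_ramp > w.n_samples:
        raise ValueError("ramp longer than signal")
    out = w.samples.copy()
    out[:n_ramp] *= _raised_cosine(n_ramp, rising=True)
    return Waveform(out, w.rate_hz)


def write_wav(path, w: Waveform, dtype: str = "float32") -> None:
    """Write a mono RIFF WAV file (float32 or int16 PCM)."""
    if dtype == "float32":
        wavfile.write(path, int(w.rate_hz), w.samples.astype(np.float32))
    elif dtype == "int16":
        peak = np.max(np.abs(w.samples))
        scale = 32767.0 / peak if peak > 1.0 else 32767.0
        wavfile.write(path, int(w.rate_hz), np.round(w.samples * scale).astype(np.int16))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")


def read_wav(path) -> Waveform:
    """Read a mono WAV file, converting integer PCM to float in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    return Waveform(np.asarray(data, dtype=np.float64), float(rate))
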