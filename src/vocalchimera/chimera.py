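"""Auditory chimeras: temporal structure of one donor, auditory
spectrum of the other.

Both donors are decomposed with the same gammatone filterbank; each
band of the *temporal* donor is rescaled so its RMS equals the
*spectral* donor's RMS in the corresponding band, and the rescaled
bands are summed.  The result keeps the temporal donor's
frequency-dependent envelopes (attacks, vibrato, pitch instabilities)
under the spectral donor's band-level profile (e.g. vowel formants).

Bands whose spectral-donor level falls below a floor (default 60 dB
under the maximum band) are left silent rather than amplified out of
numerical noise.  Self-pairs run through the same path so all factorial
cells share any resynthesis artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .auditory import BandDecomposition, FilterbankConfig, gammatone_filterbank
from .synth import build_stimulus_bank, default_expt2_donor_config
from .waveform import Waveform, apply_offset_ramp, apply_onset_ramp, rms_normalize

DEFAULT_LEVEL_FLOOR_DB = 60.0


def band_levels(bands: BandDecomposition) -> np.ndarray:
    """Per-channel RMS over the full stimulus duration."""
    if bands.band_signals.shape[0] == 0:
        raise ValueError("empty band decomposition")
    return np.sqrt(np.mean(bands.band_signals**2, axis=1))


def make_chimera(
    temporal_donor: Waveform,
    spectral_donor: Waveform,
    fb: FilterbankConfig | None = None,
    level_floor_db: float = DEFAULT_LEVEL_FLOOR_DB,
    target_rms: float | None = None,
    offset_ramp_ms: float = 5.0,
) -> Waveform:
    """Swap band levels of ``temporal_donor`` to those of
    ``spectral_donor`` and resynthesize by direct summation.

    The output is RMS-normalized (to ``target_rms`` or, by default, the
    spectral donor's RMS) and offset-ramped like the natural stimuli.
    """
    if temporal_donor.n_samples != spectral_donor.n_samples:
        raise ValueError("donors must have equal duration")
    if temporal_donor.rate_hz != spectral_donor.rate_hz:
        raise ValueError("donors must share a sample rate")
    fb = fb or FilterbankConfig()
    bands_t = gammatone_filterbank(temporal_donor, fb.n_channels, fb.cf_lo_hz, fb.cf_hi_hz)
    bands_s = gammatone_filterbank(spectral_donor, fb.n_channels, fb.cf_lo_hz, fb.cf_hi_hz)
    mixed = chimera_bands(bands_t, bands_s, level_floor_db)
    out = Waveform(mixed.band_signals.sum(axis=0), temporal_donor.rate_hz)
    out = apply_onset_ramp(out, offset_ramp_ms)
    out = apply_offset_ramp(out, 1000.0 * out.duration_s, offset_ramp_ms)
    return rms_normalize(out, target_rms if target_rms is not None else spectral_donor.rms())


def chimera_bands(
    bands_t: BandDecomposition,
    bands_s: BandDecomposition,
    level_floor_db: float = DEFAULT_LEVEL_FLOOR_DB,
) -> BandDecomposition:
    """Pre-summation chimera bands: temporal-donor bands rescaled to the
    spectral donor's band RMS (floored bands silenced)."""
    levels_t = band_levels(bands_t)
    levels_s = band_levels(bands_s)
    floor = np.max(levels_s) * 10.0 ** (-level_floor_db / 20.0)
    out = np.zeros_like(bands_t.band_signals)
    active = (levels_s >= floor) & (levels_t > 0)
    out[active] = bands_t.band_signals[active] * (
        levels_s[active] / levels_t[active]
    )[:, None]
    return BandDecomposition(band_signals=out, cf_hz=bands_t.cf_hz.copy(),
                             rate_hz=bands_t.rate_hz)


@dataclass(frozen=True)
class ChimeraStimulus:
    """One cell of the 2x2 temporal-by-spectrum factorial set."""

    stimulus_id: str
    temporal_donor_id: str
    spectral_donor_id: str
    note: str
    temporal_category: str   # "voice" | "instrument"
    spectral_category: str
    waveform: Waveform

    @property
    def condition(self) -> str:
        """Factorial cell label T<temporal>-S<spectral>."""
        return f"T{self.temporal_category.capitalize()}-S{self.spectral_category.capitalize()}"


@dataclass
class ChimeraSet:
    stimuli: list[ChimeraStimulus]
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.stimuli)

    def per_pitch(self, note: str) -> list[ChimeraStimulus]:
        return [s for s in self.stimuli if s.note == note]

    def per_condition(self, condition: str) -> list[ChimeraStimulus]:
        return [s for s in self.stimuli if s.condition == condition]


def generate_chimera_set(
    donor_bank=None,
    fb: FilterbankConfig | None = None,
    seed: int = 0,
    level_floor_db: float = DEFAULT_LEVEL_FLOOR_DB,
) -> ChimeraSet:
    """Enumerate all ordered (temporal, spectral) donor pairs, including
    self-pairs, at every pitch: 4 donors -> 16 stimuli per pitch, 12
    pitches -> 192 stimuli, labelled by the 2x2 factorial cell.
    """
    if donor_bank is None:
        donor_bank = build_stimulus_bank(default_expt2_donor_config(seed))
    fb = fb or FilterbankConfig()
    notes = sorted({it.note for it in donor_bank.items},
                   key=[it.note for it in donor_bank.items].index)
    stimuli: list[ChimeraStimulus] = []
    for note in notes:
        donors = [it for it in donor_bank.items if it.note == note]
        if len(donors) != 4:
            raise ValueError(f"expected exactly 4 donors at pitch {note}, got {len(donors)}")
        decomps = {
            it.stimulus_id: gammatone_filterbank(
                it.waveform, fb.n_channels, fb.cf_lo_hz, fb.cf_hi_hz)
            for it in donors
        }
        rms = donors[0].waveform.rms()
        for temp in donors:
            for spec in donors:
                mixed = chimera_bands(decomps[temp.stimulus_id],
                                      decomps[spec.stimulus_id], level_floor_db)
                w = Waveform(mixed.band_signals.sum(axis=0), temp.waveform.rate_hz)
                w = apply_onset_ramp(w, 5.0)
                w = apply_offset_ramp(w, 1000.0 * w.duration_s, 5.0)
                w = rms_normalize(w, rms)
                stimuli.append(ChimeraStimulus(
                    stimulus_id=f"chim-T{temp.timbre_id}-S{spec.timbre_id}-{note}",
                    temporal_donor_id=temp.stimulus_id,
                    spectral_donor_id=spec.stimulus_id,
                    note=note,
                    temporal_category=temp.category,
                    spectral_category=spec.category,
                    waveform=w,
                ))
    return ChimeraSet(stimuli=stimuli, config={"level_floor_db": level_floor_db,
                                               "seed": seed})


def broadband_envelope(w: Waveform, lp_hz: float = 70.0) -> np.ndarray:
    """Half-wave rectified, low-passed broadband amplitude envelope."""
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, lp_hz / (w.rate_hz / 2.0), output="sos")
    return np.maximum(sosfiltfilt(sos, np.maximum(w.samples, 0.0)), 0.0)
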