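"""Synthetic sung-vowel and instrument-tone bank.

The experiments this package models used short recorded stimuli: sung
vowels (/a/ /e/ /i/ /o/, four singers) and single notes from sixteen
orchestral/plucked/keyboard instruments, all in the octave A3-G#4,
RMS-equalized and faded out with a 5-ms raised-cosine window.  Those
recordings are commercial and not redistributable, so this module
synthesizes a controllable stand-in bank: additive harmonic tones with

* vowel formant shaping (three-resonance cascade, per-singer formant
  scaling) for the voice category,
* timbre-specific harmonic profiles, attack/decay envelopes and (for
  bowed strings) low-rate vibrato for the instrument category,
* band-limited aspiration/bow noise whose gain is solved exactly from
  the harmonic/noise power ratio so the realized harmonic-to-noise
  ratio (HNR) tracks a target in dB,
* a brightness control (spectral tilt in dB/octave) that moves the
  spectral centroid monotonically.

Synthesis is deterministic given the spec (including its seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .waveform import Waveform, apply_offset_ramp, apply_onset_ramp, rms_normalize

A3_HZ = 220.0
#: the twelve equal-tempered semitones from A3 to G#4
NOTE_NAMES = ["A3", "A#3", "B3", "C4", "C#4", "D4", "D#4", "E4", "F4", "F#4", "G4", "G#4"]

VOWELS = ("a", "e", "i", "o")

# formant frequencies (Hz) and bandwidths for a male-average vocal tract
_FORMANTS = {
    "a": ((730.0, 1090.0, 2440.0), (90.0, 110.0, 140.0)),
    "e": ((530.0, 1840.0, 2480.0), (90.0, 100.0, 140.0)),
    "i": ((270.0, 2290.0, 3010.0), (60.0, 100.0, 140.0)),
    "o": ((570.0, 840.0, 2410.0), (90.0, 100.0, 140.0)),
}

# per-singer vocal-tract length factor (two male, two female)
_SINGER_FORMANT_SCALE = {1: 1.0, 2: 0.95, 3: 1.12, 4: 1.18}

# instrument timbre registry: harmonic rolloff (dB/oct), even-harmonic
# gain, attack (ms), exponential decay tau (ms, None = sustained),
# vibrato (rate Hz, fractional depth) for bowed strings
_INSTRUMENTS: dict[str, dict] = {
    "oboe":        dict(rolloff=3.0,  even=1.0, attack=20.0,  decay=None, vibrato=None),
    "clarinet":    dict(rolloff=5.0,  even=0.3, attack=25.0,  decay=None, vibrato=None),
    "bassoon":     dict(rolloff=6.0,  even=1.0, attack=30.0,  decay=None, vibrato=None),
    "saxophone":   dict(rolloff=4.0,  even=0.9, attack=20.0,  decay=None, vibrato=None),
    "trumpet":     dict(rolloff=2.5,  even=1.0, attack=15.0,  decay=None, vibrato=None),
    "trombone":    dict(rolloff=4.5,  even=1.0, attack=20.0,  decay=None, vibrato=None),
    "horn":        dict(rolloff=7.0,  even=1.0, attack=25.0,  decay=None, vibrato=None),
    "guitar":      dict(rolloff=6.0,  even=0.8, attack=5.0,   decay=180.0, vibrato=None),
    "mandolin":    dict(rolloff=5.0,  even=0.9, attack=4.0,   decay=120.0, vibrato=None),
    "ukulele":     dict(rolloff=8.0,  even=0.8, attack=5.0,   decay=150.0, vibrato=None),
    "harpsichord": dict(rolloff=4.0,  even=1.0, attack=3.0,   decay=200.0, vibrato=None),
    "piano":       dict(rolloff=6.5,  even=0.9, attack=5.0,   decay=250.0, vibrato=None),
    "marimba":     dict(rolloff=12.0, even=0.4, attack=3.0,   decay=100.0, vibrato=None),
    # vibrato depth kept small so the periodicity-based HNR estimate
    # still tracks the injected noise ratio within its 2-dB contract
    "violin":      dict(rolloff=3.5,  even=1.0, attack=60.0,  decay=None, vibrato=(5.5, 0.004)),
    "viola":       dict(rolloff=4.5,  even=1.0, attack=65.0,  decay=None, vibrato=(5.2, 0.004)),
    "cello":       dict(rolloff=5.5,  even=1.0, attack=70.0,  decay=None, vibrato=(5.0, 0.004)),
}

INSTRUMENT_NAMES = tuple(_INSTRUMENTS)

#: upper edge of the band within which harmonic/noise powers are balanced
NOISE_BAND_HZ = 5000.0


def note_to_f0(note: str, a3_hz: float = A3_HZ) -> float:
    """Equal-tempered fundamental for a note name in the A3-G#4 octave."""
    if note not in NOTE_NAMES:
        raise ValueError(f"unknown note {note!r}; expected one of {NOTE_NAMES}")
    return a3_hz * 2.0 ** (NOTE_NAMES.index(note) / 12.0)


@dataclass(frozen=True)
class ToneSpec:
    """Full recipe for one synthetic tone."""

    kind: str                      # "vowel" | "instrument"
    timbre_id: str                 # vowel symbol (+ optional "_s<n>" singer tag) or instrument name
    f0_hz: float
    duration_ms: float = 128.0
    target_hnr_db: float = 24.0
    brightness: float = 0.0        # spectral-tilt offset, dB/octave (positive = brighter)
    seed: int = 0
    rate_hz: float = 44100.0

    def __post_init__(self) -> None:
        if self.kind not in ("vowel", "instrument"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.f0_hz <= 0 or self.duration_ms <= 0 or self.rate_hz <= 0:
            raise ValueError("f0_hz, duration_ms and rate_hz must be positive")


def _parse_vowel_id(timbre_id: str) -> tuple[str, int]:
    vowel, _, singer = timbre_id.partition("_s")
    if vowel not in VOWELS:
        raise ValueError(f"unknown vowel {timbre_id!r}; expected one of {VOWELS}")
    return vowel, int(singer) if singer else 1


def _formant_gain(freqs: np.ndarray, formants, bandwidths) -> np.ndarray:
    """Cascade of second-order resonance magnitude responses, unity at DC."""
    gain = np.ones_like(freqs)
    for fc, bw in zip(formants, bandwidths):
        gain *= fc**2 / np.sqrt((fc**2 - freqs**2) ** 2 + (bw * freqs) ** 2)
    return gain


def _tilt_gain(freqs: np.ndarray, f_ref: float, tilt_db_per_oct: float) -> np.ndarray:
    return 10.0 ** (tilt_db_per_oct * np.log2(freqs / f_ref) / 20.0)


def _band_noise(n: int, rate_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise low-passed to the harmonic band (0-5 kHz)."""
    noise = rng.standard_normal(n)
    sos = butter(4, NOISE_BAND_HZ / (rate_hz / 2.0), output="sos")
    return sosfiltfilt(sos, noise)


def _mix_to_hnr(harmonic: np.ndarray, noise: np.ndarray, target_hnr_db: float) -> np.ndarray:
    """Scale noise so harmonic/noise power sits exactly at the target ratio."""
    p_h = np.mean(harmonic**2)
    p_n = np.mean(noise**2)
    if p_n == 0:
        return harmonic
    gain = np.sqrt(p_h / (p_n * 10.0 ** (target_hnr_db / 10.0)))
    return harmonic + gain * noise


def _harmonic_tone(
    spec: ToneSpec,
    amps: np.ndarray,
    vibrato: tuple[float, float] | None,
) -> np.ndarray:
    n = int(round(spec.duration_ms * 1e-3 * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz
    if vibrato is not None:
        rate, depth = vibrato
        # FM phase: integral of f0 * (1 + depth*sin(2 pi rate t))
        phase0 = 2.0 * np.pi * spec.f0_hz * (
            t - depth * (np.cos(2.0 * np.pi * rate * t) - 1.0) / (2.0 * np.pi * rate)
        )
    else:
        phase0 = 2.0 * np.pi * spec.f0_hz * t
    k = np.arange(1, amps.size + 1)
    return (amps[:, None] * np.sin(k[:, None] * phase0[None, :])).sum(axis=0)


def _harmonic_amps(spec: ToneSpec, base_tilt_db_per_oct: float, even_gain: float = 1.0,
                   formant_pair=None) -> np.ndarray:
    nyq = spec.rate_hz / 2.0
    k_max = int(min(NOISE_BAND_HZ, 0.95 * nyq) // spec.f0_hz)
    if k_max < 1:
        raise ValueError("f0 too high: no harmonic fits below the band limit")
    freqs = spec.f0_hz * np.arange(1, k_max + 1)
    amps = _tilt_gain(freqs, spec.f0_hz, -base_tilt_db_per_oct + spec.brightness)
    if even_gain != 1.0:
        amps[1::2] *= even_gain
    if formant_pair is not None:
        amps *= _formant_gain(freqs, *formant_pair)
    return amps


def synth_vowel(spec: ToneSpec) -> Waveform:
    """Synthesize a sung-vowel stand-in: formant-shaped harmonic series
    plus aspiration noise at the target HNR."""
    if spec.kind != "vowel":
        raise ValueError("spec.kind must be 'vowel'")
    if spec.f0_hz >= spec.rate_hz / 4.0:
        raise ValueError("f0 too high for vowel synthesis")
    vowel, singer = _parse_vowel_id(spec.timbre_id)
    scale = _SINGER_FORMANT_SCALE.get(singer)
    if scale is None:
        raise ValueError(f"unknown singer index {singer}")
    formants, bandwidths = _FORMANTS[vowel]
    formants = tuple(f * scale for f in formants)
    amps = _harmonic_amps(spec, base_tilt_db_per_oct=6.0,
                          formant_pair=(formants, bandwidths))
    harmonic = _harmonic_tone(spec, amps, vibrato=None)
    # fast vocal onset
    env = np.ones_like(harmonic)
    n_att = int(round(0.010 * spec.rate_hz))
    env[:n_att] = np.linspace(0.0, 1.0, n_att)
    harmonic *= env
    rng = np.random.default_rng(spec.seed)
    noise = _band_noise(harmonic.size, spec.rate_hz, rng) * env
    return Waveform(_mix_to_hnr(harmonic, noise, spec.target_hnr_db), spec.rate_hz)


def synth_instrument(spec: ToneSpec) -> Waveform:
    """Synthesize an instrument-tone stand-in from the 16-timbre registry."""
    if spec.kind != "instrument":
        raise ValueError("spec.kind must be 'instrument'")
    params = _INSTRUMENTS.get(spec.timbre_id)
    if params is None:
        raise ValueError(
            f"unknown instrument {spec.timbre_id!r}; expected one of {INSTRUMENT_NAMES}"
        )
    amps = _harmonic_amps(spec, base_tilt_db_per_oct=params["rolloff"],
                          even_gain=params["even"])
    harmonic = _harmonic_tone(spec, amps, vibrato=params["vibrato"])
    n = harmonic.size
    t = np.arange(n) / spec.rate_hz
    env = np.ones(n)
    n_att = int(round(params["attack"] * 1e-3 * spec.rate_hz))
    n_att = min(n_att, n)
    env[:n_att] = np.linspace(0.0, 1.0, n_att)
    if params["decay"] is not None:
        env *= np.exp(-np.maximum(t - n_att / spec.rate_hz, 0.0) / (params["decay"] * 1e-3))
    harmonic *= env
    rng = np.random.default_rng(spec.seed)
    noise = _band_noise(n, spec.rate_hz, rng) * env
    return Waveform(_mix_to_hnr(harmonic, noise, spec.target_hnr_db), spec.rate_hz)


def synth_tone(spec: ToneSpec) -> Waveform:
    return synth_vowel(spec) if spec.kind == "vowel" else synth_instrument(spec)


# ---------------------------------------------------------------------------
# stimulus bank


@dataclass(frozen=True)
class BankItem:
    stimulus_id: str
    category: str                  # "voice" | "instrument"
    timbre_id: str
    note: str
    spec: ToneSpec
    waveform: Waveform


@dataclass
class StimulusBank:
    """Ramped, RMS-equalized tone collection for one experiment config."""

    items: list[BankItem]
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.items)

    def ids(self) -> list[str]:
        return [it.stimulus_id for it in self.items]

    def by_id(self, stimulus_id: str) -> BankItem:
        for it in self.items:
            if it.stimulus_id == stimulus_id:
                return it
        raise KeyError(stimulus_id)


def default_expt1_config(seed: int = 0) -> dict:
    """Bank configuration matching the first experiment's stimulus set:
    16 voice timbres (4 vowels x 4 singers) and 16 instruments at 12
    equal-tempered pitches A3-G#4, 128 ms, RMS-equalized.

    Per-timbre HNR targets are drawn from the distributions measured on
    the original recordings (voices 24.1 +/- 5.5 dB, instruments
    23.5 +/- 3.5 dB).
    """
    rng = np.random.default_rng(seed)
    voice_timbres = [f"{v}_s{s}" for v in VOWELS for s in (1, 2, 3, 4)]
    instrument_timbres = list(INSTRUMENT_NAMES)
    hnr = {}
    for tid in voice_timbres:
        hnr[tid] = float(np.clip(rng.normal(24.1, 5.5), 5.0, 40.0))
    for tid in instrument_timbres:
        hnr[tid] = float(np.clip(rng.normal(23.5, 3.5), 5.0, 40.0))
    return {
        "categories": ["voice", "instrument"],
        "timbres": {"voice": voice_timbres, "instrument": instrument_timbres},
        "pitches": list(NOTE_NAMES),
        "duration_ms": 128.0,
        "target_hnr_db": hnr,
        "rms": 0.05,
        "rate_hz": 44100.0,
        "seed": seed,
    }


def default_expt2_donor_config(seed: int = 0) -> dict:
    """Chimera donor set: /a/, /i/, violin, cello at 12 pitches, 250 ms."""
    cfg = default_expt1_config(seed)
    cfg["timbres"] = {"voice": ["a_s1", "i_s1"], "instrument": ["violin", "cello"]}
    cfg["duration_ms"] = 250.0
    return cfg


def build_stimulus_bank(config: dict) -> StimulusBank:
    """Synthesize, ramp and RMS-equalize every (category, timbre, pitch)
    combination of the config."""
    categories = config["categories"]
    if not categories or any(not config["timbres"].get(c) for c in categories):
        raise ValueError("every category must list at least one timbre")
    duration_ms = float(config["duration_ms"])
    rms = float(config.get("rms", 0.05))
    rate_hz = float(config.get("rate_hz", 44100.0))
    base_seed = int(config.get("seed", 0))
    hnr = config.get("target_hnr_db", 24.0)

    items: list[BankItem] = []
    for category in categories:
        kind = "vowel" if category == "voice" else "instrument"
        for timbre_id in config["timbres"][category]:
            tgt = hnr[timbre_id] if isinstance(hnr, dict) else float(hnr)
            for note in config["pitches"]:
                f0 = note_to_f0(note)
                # stable per-stimulus seed (crc32 is stable across runs)
                tag = f"{category}/{timbre_id}/{note}".encode()
                seed = (base_seed * 1_000_003 + zlib.crc32(tag)) % (2**31)
                spec = ToneSpec(kind=kind, timbre_id=timbre_id, f0_hz=f0,
                                duration_ms=duration_ms, target_hnr_db=tgt,
                                seed=seed, rate_hz=rate_hz)
                w = synth_tone(spec)
                w = apply_onset_ramp(w, 5.0)
                w = apply_offset_ramp(w, duration_ms, 5.0)
                w = rms_normalize(w, rms)
                items.append(BankItem(
                    stimulus_id=f"{category}-{timbre_id}-{note}",
                    category=category, timbre_id=timbre_id, note=note,
                    spec=spec, waveform=w,
                ))
    return StimulusBank(items=items, config=dict(config))
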