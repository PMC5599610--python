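# Methods

This note documents the models, the parameter choices that matter, and
what the synthetic data can and cannot show.

## Stimulus synthesis

Real experiments of this kind use recorded sung vowels and instrument
notes from a commercial database; those recordings are not
redistributable, so the bank here is synthesized. Each tone is an
additive harmonic series at a fundamental f0 on the equal-tempered
grid A3 = 220 Hz … G#4 (12 semitones), with harmonics up to 5 kHz.

* **Vowels** (/a/ /e/ /i/ /o/): source spectrum with −6 dB/oct tilt
  shaped by a cascade of three second-order formant resonances
  (male-average formant table; per-"singer" vocal-tract scale factors
  1.00, 0.95, 1.12, 1.18 emulate two male and two female singers),
  10-ms onset, sustained.
* **Instruments** (16-name registry: oboe … cello): timbre-specific
  harmonic rolloff (2.5–12 dB/oct), even-harmonic attenuation for the
  clarinet family, attack times of 3–70 ms, exponential decay for
  plucked/struck timbres, and low-rate FM vibrato (5–5.5 Hz) for the
  bowed strings. Vibrato depth is kept at 0.4% of f0: FM decorrelates
  the signal across the pitch period, and deeper vibrato would push
  the periodicity-based HNR measurement outside its ±2 dB targeting
  contract.
* **HNR control**: Gaussian noise, low-passed to the harmonic band
  (0–5 kHz) and gated by the same temporal envelope as the harmonic
  part, is scaled so the harmonic/noise power ratio equals the target
  exactly. Per-timbre HNR targets are drawn from the distributions
  reported for the original recordings (voices 24.1 ± 5.5 dB,
  instruments 23.5 ± 3.5 dB), which makes the two categories matched
  in expectation.
* **Level and windowing**: every stimulus gets a 5-ms raised-cosine
  offset ramp at its nominal duration (128 ms for the one-back bank,
  250 ms for chimera donors) and RMS equalization. A symmetric 5-ms
  onset ramp is also applied — an extension beyond the emulated
  procedure (which specifies only the offset fade) to avoid onset
  clicks.
* Synthesis is deterministic given the spec, including its seed;
  per-stimulus seeds are derived with CRC32 so banks are reproducible
  across processes.

## Auditory model

64 gammatone channels with center frequencies uniformly spaced on the
Glasberg–Moore ERB-rate scale between 80 and 8000 Hz. Each channel
applies the analytic 4th-order gammatone magnitude response
`(1 + (2π(f − cf)τ)²)⁻²` with τ from 1.019 ERB bandwidths, in the
frequency domain (zero phase). Zero-phase filtering keeps all bands
time-aligned, so summing rescaled bands — the chimera resynthesis —
returns a temporally coherent waveform (self-chimera correlation with
the original > 0.99). Time-domain IIR gammatone filters were
numerically unstable at low center frequencies at 44.1 kHz and offer
no benefit here, since chimera construction wants zero-phase bands
anyway.

Band envelopes are computed in the order: half-wave rectification,
then a 4th-order zero-phase Butterworth low-pass at 70 Hz, then
decimation to a 200-Hz frame rate. The auditory spectrum is the
per-channel time mean of the envelope.

## Chimeras

For a (temporal donor, spectral donor) pair decomposed with the same
filterbank, each temporal-donor band is rescaled so its whole-duration
RMS equals the spectral donor's RMS in the corresponding band; bands
whose spectral-donor level lies more than 60 dB below the maximum band
are silenced rather than amplified from numerical noise. The rescaled
bands are summed, ramped, and RMS-normalized. Levels are equalized
over the whole duration, not frame by frame. All 4 donors × 4 donors
ordered pairs (self-pairs included, so every factorial cell shares the
resynthesis artifacts) × 12 pitches give 16 × 12 = 192 labelled
stimuli in the 2×2 temporal-structure × spectrum factorial.

## Acoustic descriptors

* **f0 / HNR**: 40-ms frames, 10-ms hop, normalized cross-correlation
  between the frame and its lagged continuation over a 100–600 Hz
  period range. The winning integer lag and its sub-multiples are
  refined on a 32× band-limited-resampled lag grid (fractional-lag
  quantization otherwise caps measurable HNR near 20 dB and favors
  period multiples whose lag happens to be closer to an integer —
  the classic octave error). Frames with r > 0.3 count as voiced;
  per-frame HNR is `10·log10(r/(1−r))`, capped at +60 dB, averaged
  over voiced frames. f0 is the median voiced-frame 1/lag and raises
  on fully unvoiced input; HNR instead falls back to the all-frame
  mean so noise inputs report a strongly negative value.
* **Spectral centroid**: level-weighted mean of channel center
  frequencies of the auditory spectrum, on the linear Hz axis (the
  scale the quantity is conventionally reported on).
* **Modulation spectrum**: the envelope matrix is interpolated onto a
  uniform log2-frequency grid (128 points) so the spectral-modulation
  axis reads in cycles/octave, compressed with `log(1 + env/ε)` where
  ε = 0.3 × peak — mild on purpose: heavy log compression turns
  sinusoidal envelopes into harmonic stacks and biases the rate
  centroid — and Fourier-transformed in 2-D (4× zero-padding). The
  time-constant part of each channel is separated analytically into
  the rate-0 column, so static spectra concentrate at rate 0 exactly
  instead of leaking through the temporal Hann window. Up/down drift
  directions are folded (magnitudes summed, then squared).
* **Dominant rate / scale**: energy-weighted centroids of |rate| and
  scale within configurable windows, default 1–32 Hz (DC excluded)
  and 0.25–8 cyc/oct. With these choices the dominant rate of 100%
  AM tones tracks the modulator within ±1 Hz over 4–16 Hz, and
  dominant scale rises monotonically with ripple density.

## Trial designs and behavior

One-back run: each of the 384 bank stimuli appears on two base trials
(768), uniformly shuffled; floor(768/20) = 38 repeat trials are
inserted immediately after uniformly chosen distinct originals
(no repeat-of-a-repeat); SOA 2 s; a 20-s pause after every 290 s of
trials (6 blocks, 806 trials). Each trial denotes six identical 128-ms
presentations (768 ms of sound). Categorization run: 192 × 2 = 384
trials, four 250-ms presentations per trial (1 s of sound), pauses
every 296 s (3 blocks).

Button presses are attributed to the unique trial whose onset lies
100–2100 ms before the press; a press exactly on the boundary between
two eligible trials goes to the more recent one (reaction times under
2 s dominate). Categorization tallies count voice-presses over
voice-plus-instrument presses per condition, excluding both/neither
trials; a subject whose pure-condition rates indicate systematic
button reversal (pure voice < 50% "voice" AND pure instrument > 50%)
has labels flipped before tallying. The simulated observer's
per-condition voice rates (0.95 / 0.59 / 0.08 / 0.04, with 1% lapse
and 0.3% double-press rates) reproduce the qualitative pattern
reported for human listeners and drive the behavioral outputs.

## GLM simulation and group statistics

The canonical HRF is the standard double gamma (response delay 6 s,
undershoot delay 16 s, unit dispersions, undershoot ratio 1/6, 32-s
support, unit peak). Event trains are sampled on a 0.1-s microtime
grid, convolved, and read out at TR = 2 s. Parametric modulators
(pitch, HNR, dominant scale, dominant rate, spectral centroid — in
that fixed order) are mean-centered over events, convolved, and
serially residualized against the intercept, the condition columns and
all earlier modulators, the conventional orthogonalization for ordered
modulators. Drift modelling is intercept-only by default (runs are
short).

ROI data are simulated as `y = Xβ + AR(1) noise` (stationary, marginal
SD `noise_sd`, ρ = 0.2 by default) and fit by OLS; the AR(1)
correlation mildly miscalibrates OLS standard errors within a run but
leaves the estimates unbiased, and all group inference uses only the
per-subject point estimates. Group tests are paired/one-sample t-tests
on per-subject contrast values with df = n − 1 (the within-subject
convention; a two-sample test would be wrong for repeated measures),
2×2 repeated-measures ANOVAs via within-subject difference contrasts
(F(1, n−1) = t²), and the one-way repeated-measures ANOVA with
Greenhouse–Geisser epsilon computed from the double-centered condition
covariance, clipped to [1/(k−1), 1], multiplying both dfs.

Parameter recovery simulates cohorts of 22 subjects. The
voice-selective ROI adds a subject-varying amplitude
`δᵢ ~ N(d·σᵦ, σᵦ)` (d = 0.8, σᵦ = 0.3 in beta units) to the voice
condition; the null ROI draws δᵢ with zero mean. Run noise SD is 1.0,
giving a single-run contrast SE of ≈ 0.08 — small relative to σᵦ, as
in a well-powered ROI analysis — so the realized group effect size
stays close to the injected d. With these conditions the voice
contrast is detected in ≈ 90% of cohorts and the null ROI's type-I
rate sits at the nominal 5%.

## Problem sizes

The default test suite and the acceptance script use the full study
combinatorics (384-stimulus bank, 192 chimeras, 806/384-trial
sequences, 22-subject cohorts, 1000 simulated cohorts for the
error-rate estimates); only the per-stimulus feature extraction in the
matching report is evaluated on one representative stimulus per timbre
(32 profiles, mirroring the 16 + 16 layout the category comparison is
made on).

## Limitations

* The synthetic tones are controllable stand-ins, not perceptually
  convincing instruments or singers; conclusions about real recordings
  require the real stimuli. Passing tests show the *pipeline* is
  correct and the descriptors behave lawfully, not that the synthetic
  bank spans natural timbre variation.
* The cortical modulation model is a 2-D Fourier magnitude on the
  auditory spectrogram, not a multi-resolution complex filter model;
  drift direction is discarded by design (folded magnitudes).
* The matched-subset selector is a greedy heuristic with no optimality
  guarantee; it reproduces the *outcome* of stimulus selection, whose
  original algorithm is unknown.
* BOLD simulation is a single ROI time course with AR(1) noise — no
  voxel structure, motion, or physiological confounds; type-I and
  power results apply to this noise model.
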