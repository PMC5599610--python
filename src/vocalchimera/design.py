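"""Timed trial sequences and behavioral scoring for both experiments.

Experiment 1 (one-back): 384 bank stimuli each presented on two trials
(768 base trials) in seeded pseudo-random order at a 2-s SOA; one in
twenty trials is repeated immediately (38 inserted repeat trials, 806
trials total); each trial plays six identical 128-ms repetitions
(768 ms of sound); 20-s pauses every 290 s split the run into six
blocks.

Experiment 2 (categorization): the 192 factorial chimera-set stimuli
each presented twice (384 trials) at a 2-s SOA; four 250-ms
presentations per trial (1 s of sound); 20-s pauses every 296 s, three
blocks; conditions follow the 2x2 temporal-by-spectrum factorial.

Behavioral scoring attributes each button press to the unique trial
whose onset lies 100-2100 ms before the press (ties to the more recent
trial), scores one-back hit/false-alarm rates, and tallies the
proportion of "voice" categorizations per condition with both/neither
trials excluded and systematic button reversal corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOA_S = 2.0
PAUSE_S = 20.0
RESPONSE_WINDOW_S = (0.1, 2.1)

EXPT1_PAUSE_EVERY_S = 290.0
EXPT2_PAUSE_EVERY_S = 296.0
EXPT1_REPEAT_EVERY = 20          # one in twenty trials is repeated
EXPT1_N_SOUND_REPS = 6           # 6 x 128 ms = 768 ms of sound per trial
EXPT2_N_SOUND_REPS = 4           # 4 x 250 ms = 1 s of sound per trial


@dataclass(frozen=True)
class Trial:
    onset_s: float
    condition: str
    stimulus_id: str
    is_repeat: bool
    block: int


@dataclass
class TrialSequence:
    trials: list[Trial]
    soa_s: float = SOA_S
    pause_s: float = PAUSE_S
    pause_every_s: float = EXPT1_PAUSE_EVERY_S
    sound_duration_s: float = 0.768
    experiment: str = "expt1"

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_blocks(self) -> int:
        return self.trials[-1].block + 1 if self.trials else 0

    @property
    def run_duration_s(self) -> float:
        return self.trials[-1].onset_s + self.soa_s if self.trials else 0.0

    def onsets(self) -> np.ndarray:
        return np.array([t.onset_s for t in self.trials])

    def to_events_df(self) -> pd.DataFrame:
        """BIDS-flavoured events table."""
        return pd.DataFrame(
            dict(onset=[t.onset_s for t in self.trials],
                 duration=self.sound_duration_s,
                 trial_type=[t.condition for t in self.trials],
                 stimulus_id=[t.stimulus_id for t in self.trials],
                 is_repeat=[t.is_repeat for t in self.trials],
                 block=[t.block for t in self.trials])
        )

    def write_events_tsv(self, path) -> None:
        self.to_events_df().to_csv(path, sep="\t", index=False)


def _timed_trials(entries: list[tuple[str, str, bool]], soa_s: float,
                  pause_s: float, pause_every_s: float) -> list[Trial]:
    """Assign onsets/blocks: SOA spacing with a pause inserted after
    every ``pause_every_s`` of trial time."""
    per_block = int(round(pause_every_s / soa_s))
    trials = []
    for i, (condition, sid, rep) in enumerate(entries):
        block, pos = divmod(i, per_block)
        onset = i * soa_s + block * pause_s
        trials.append(Trial(onset_s=onset, condition=condition,
                            stimulus_id=sid, is_repeat=rep, block=block))
    return trials


def build_expt1_sequence(bank, seed: int = 0) -> TrialSequence:
    """One-back sequence: every bank stimulus twice, shuffled, plus one
    inserted repeat per twenty base trials."""
    try:
        entries = [(it.category, it.stimulus_id) for it in bank.items]
    except AttributeError:
        entries = [(c, s) for c, s in bank]
    if len(entries) != 384:
        raise ValueError(f"expected a 384-stimulus bank, got {len(entries)}")
    rng = np.random.default_rng(seed)
    base = entries * 2
    order = rng.permutation(len(base))
    base = [base[i] for i in order]
    n_repeats = len(base) // EXPT1_REPEAT_EVERY          # floor(768/20) = 38
    repeat_after = set(rng.choice(len(base), size=n_repeats, replace=False))
    seq: list[tuple[str, str, bool]] = []
    for i, (cond, sid) in enumerate(base):
        seq.append((cond, sid, False))
        if i in repeat_after:
            seq.append((cond, sid, True))
    trials = _timed_trials(seq, SOA_S, PAUSE_S, EXPT1_PAUSE_EVERY_S)
    return TrialSequence(trials=trials, pause_every_s=EXPT1_PAUSE_EVERY_S,
                         sound_duration_s=0.768, experiment="expt1")


def build_expt2_sequence(chimera_set, seed: int = 0) -> TrialSequence:
    """Categorization sequence: each of the 192 factorial stimuli twice."""
    try:
        entries = [(s.condition, s.stimulus_id) for s in chimera_set.stimuli]
    except AttributeError:
        entries = [(c, s) for c, s in chimera_set]
    if len(entries) != 192:
        raise ValueError(f"expected the 192-stimulus factorial set, got {len(entries)}")
    rng = np.random.default_rng(seed)
    base = entries * 2
    order = rng.permutation(len(base))
    seq = [(base[i][0], base[i][1], False) for i in order]
    trials = _timed_trials(seq, SOA_S, PAUSE_S, EXPT2_PAUSE_EVERY_S)
    return TrialSequence(trials=trials, pause_every_s=EXPT2_PAUSE_EVERY_S,
                         sound_duration_s=1.0, experiment="expt2")


# ---------------------------------------------------------------------------
# response attribution and scoring


def attribute_responses(seq: TrialSequence, presses: list[tuple[float, str]]
                        ) -> pd.DataFrame:
    """Map each press to the trial whose onset lies 100-2100 ms before it.

    A press eligible for two trials (exactly on the window boundary) is
    assigned to the more recent trial; presses matching no trial get
    index -1.
    Returns a frame with columns ``time_s, button, trial_index``.
    """
    onsets = seq.onsets()
    lo, hi = RESPONSE_WINDOW_S
    rows = []
    for t, button in presses:
        eligible = np.nonzero((onsets >= t - hi) & (onsets <= t - lo))[0]
        idx = int(eligible[-1]) if eligible.size else -1
        rows.append(dict(time_s=t, button=button, trial_index=idx))
    return pd.DataFrame(rows, columns=["time_s", "button", "trial_index"])


def _buttons_per_trial(seq: TrialSequence, labelled: pd.DataFrame) -> list[set]:
    out: list[set] = [set() for _ in seq.trials]
    for _, row in labelled.iterrows():
        if row["trial_index"] >= 0:
            out[int(row["trial_index"])].add(row["button"])
    return out


def score_one_back(seq: TrialSequence, labelled: pd.DataFrame
                   ) -> tuple[float, float]:
    """(hit rate on repeat trials, false-alarm rate on non-repeat trials)."""
    pressed = [len(b) > 0 for b in _buttons_per_trial(seq, labelled)]
    repeats = np.array([t.is_repeat for t in seq.trials])
    pressed = np.array(pressed)
    n_rep = int(repeats.sum())
    n_non = int((~repeats).sum())
    if n_rep == 0:
        raise ValueError("sequence contains no repeat trials")
    return float(pressed[repeats].mean()), float(pressed[~repeats].mean()) if n_non else 0.0


@dataclass
class CategorizationTally:
    proportion_voice: dict          # condition -> voice-press proportion
    counted: dict                   # condition -> trials entering the denominator
    excluded_fraction: float        # both-or-neither trials / all trials
    reversed_buttons: bool


PURE_VOICE = "TVoice-SVoice"
PURE_INSTRUMENT = "TInstrument-SInstrument"


def tally_categorization(seq: TrialSequence, labelled: pd.DataFrame,
                         voice_button: str = "voice",
                         instrument_button: str = "instrument") -> CategorizationTally:
    """Per-condition proportion of trials categorized as voice.

    Trials where both or neither button was pressed are excluded from
    the denominator.  If the pure-condition pattern indicates the
    observer used the buttons with opposite senses (voice rate < 50%
    for pure voice AND > 50% for pure instrument), their labels are
    flipped before tallying.
    """
    buttons = _buttons_per_trial(seq, labelled)

    def counts(flip: bool):
        voice_key = {voice_button} if not flip else {instrument_button}
        instr_key = {instrument_button} if not flip else {voice_button}
        v: dict[str, int] = {}
        i: dict[str, int] = {}
        excluded = 0
        for trial, b in zip(seq.trials, buttons):
            if b == voice_key:
                v[trial.condition] = v.get(trial.condition, 0) + 1
            elif b == instr_key:
                i[trial.condition] = i.get(trial.condition, 0) + 1
            else:
                excluded += 1
        return v, i, excluded

    v, i, excluded = counts(flip=False)

    def prop(cond):
        tot = v.get(cond, 0) + i.get(cond, 0)
        return v.get(cond, 0) / tot if tot else np.nan

    flip = (prop(PURE_VOICE) < 0.5) and (prop(PURE_INSTRUMENT) > 0.5)
    if flip:
        v, i, excluded = counts(flip=True)

    conditions = sorted({t.condition for t in seq.trials})
    proportion, counted = {}, {}
    for cond in conditions:
        tot = v.get(cond, 0) + i.get(cond, 0)
        if tot == 0:
            raise ValueError(f"condition {cond!r} has no countable trials")
        proportion[cond] = v.get(cond, 0) / tot
        counted[cond] = tot
    return CategorizationTally(proportion_voice=proportion, counted=counted,
                               excluded_fraction=excluded / len(seq.trials),
                               reversed_buttons=flip)


# ---------------------------------------------------------------------------
# simulated observers (for parameter-recovery and behavioral demos)

#: mean observed voice-categorization rates per factorial cell
DEFAULT_P_VOICE = {
    PURE_VOICE: 0.95,
    "TInstrument-SVoice": 0.59,
    PURE_INSTRUMENT: 0.08,
    "TVoice-SInstrument": 0.04,
}


def simulate_categorization_presses(
    seq: TrialSequence,
    p_voice_by_condition: dict | None = None,
    p_neither: float = 0.01,
    p_both: float = 0.003,
    rt_range_s: tuple[float, float] = (0.4, 1.5),
    seed: int = 0,
    reversed_buttons: bool = False,
) -> list[tuple[float, str]]:
    """Presses of a probabilistic categorizer with realistic lapses."""
    p_voice = p_voice_by_condition or DEFAULT_P_VOICE
    rng = np.random.default_rng(seed)
    presses = []
    for trial in seq.trials:
        u = rng.uniform()
        rt = rng.uniform(*rt_range_s)
        if u < p_neither:
            continue
        choice_voice = rng.uniform() < p_voice[trial.condition]
        if reversed_buttons:
            choice_voice = not choice_voice
        button = "voice" if choice_voice else "instrument"
        presses.append((trial.onset_s + rt, button))
        if u > 1.0 - p_both:
            other = "instrument" if button == "voice" else "voice"
            presses.append((trial.onset_s + rt + 0.15, other))
    return presses


def simulate_one_back_presses(seq: TrialSequence, hit_rate: float = 0.9,
                              fa_rate: float = 0.02,
                              rt_range_s: tuple[float, float] = (0.3, 1.2),
                              seed: int = 0) -> list[tuple[float, str]]:
    """Presses of a one-back observer with given hit/false-alarm rates."""
    rng = np.random.default_rng(seed)
    presses = []
    for trial in seq.trials:
        p = hit_rate if trial.is_repeat else fa_rate
        if rng.uniform() < p:
            presses.append((trial.onset_s + rng.uniform(*rt_range_s), "target"))
    return presses
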