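import numpy as np
import pytest

from vocalchimera.synth import (ToneSpec, build_stimulus_bank,
                                default_expt2_donor_config)


@pytest.fixture(scope="session")
def donor_bank_a3():
    """The four chimera donors (/a/, /i/, violin, cello) at A3, 250 ms."""
    cfg = default_expt2_donor_config(seed=0)
    cfg["pitches"] = ["A3"]
    return build_stimulus_bank(cfg)


@pytest.fixture(scope="session")
def vowel_220():
    return ToneSpec(kind="vowel", timbre_id="a_s1", f0_hz=220.0,
                    duration_ms=250.0, target_hnr_db=25.0, seed=3)


@pytest.fixture(scope="session")
def expt1_entries():
    """Lightweight (category, stimulus_id) entries shaped like the
    384-stimulus bank: 2 categories x 16 timbres x 12 pitches."""
    entries = []
    for cat in ("voice", "instrument"):
        for t in range(16):
            for p in range(12):
                entries.append((cat, f"{cat}-t{t:02d}-p{p:02d}"))
    return entries


@pytest.fixture(scope="session")
def factorial_entries():
    from vocalchimera.recovery import mock_factorial_entries

    return mock_factorial_entries()
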