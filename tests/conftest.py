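from __future__ import annotations

from fractions import Fraction

import pytest

from tonalaccent.fixtures import default_familiarity_table, prelude7_skeleton
from tonalaccent.score import NoteEvent, Score, TimeSignature


@pytest.fixture(scope="session")
def familiarity():
    return default_familiarity_table()


@pytest.fixture(scope="session")
def prelude7():
    return prelude7_skeleton()


def make_melody(pitches, beat=Fraction(1, 4), time_signature=(4, 4), bpm=96.0):
    """Monophonic quarter-note score from a pitch list."""
    from tonalaccent.score import renumber_events

    events = [
        NoteEvent(pitch=p, onset=i * beat, duration_wholes=beat, voice_id="1")
        for i, p in enumerate(pitches)
    ]
    score = Score(
        events=events,
        time_signatures=[TimeSignature(Fraction(0), *time_signature)],
        tempo_bpm=bpm,
    )
    return renumber_events(score)
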