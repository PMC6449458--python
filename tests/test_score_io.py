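"""Parsing, chordification, melody extraction and table serialization."""

from __future__ import annotations

from fractions import Fraction

import pytest

import tonalaccent as ta
from tonalaccent.fixtures import FixtureSpec, generate_progression, make
from tonalaccent.io import (
    read_accent_table,
    read_score,
    write_accent_table,
    write_kern,
    write_midi,
    write_musicxml,
)
from tonalaccent.score import (
    AccentTable,
    NoteEvent,
    Score,
    TimeSignature,
    chordify,
    extract_melody,
)

from .conftest import make_melody

F = Fraction

MXL_THREE_QUARTERS = """<?xml version="1.0" encoding="UTF-8"?>
<score-partwise version="3.1">
 <part-list><score-part id="P1"><part-name>one</part-name></score-part></part-list>
 <part id="P1">
  <measure number="1">
   <attributes><divisions>1</divisions>
    <time><beats>3</beats><beat-type>4</beat-type></time></attributes>
   <note><pitch><step>C</step><octave>4</octave></pitch><duration>1</duration></note>
   <note><pitch><step>C</step><octave>4</octave></pitch><duration>1</duration></note>
   <note><pitch><step>C</step><octave>4</octave></pitch><duration>1</duration></note>
  </measure>
 </part>
</score-partwise>
"""

KERN_TIED = """**kern
*M4/4
*MM90
=1
[2c
4c]
4c
=2
*-
"""


def test_musicxml_three_quarter_notes(tmp_path):
    p = tmp_path / "m.musicxml"
    p.write_text(MXL_THREE_QUARTERS)
    score = read_score(p)
    assert len(score.events) == 3
    assert [e.onset for e in score.events] == [F(0), F(1, 4), F(2, 4)]
    assert all(e.pitch == 60 for e in score.events)
    assert score.time_signatures[0].numerator == 3


def test_kern_tie_merges_into_one_logical_note(tmp_path):
    p = tmp_path / "t.krn"
    p.write_text(KERN_TIED)
    score = read_score(p)
    assert len(score.events) == 2  # half+quarter merged, plus the final quarter
    merged = score.events[0]
    assert merged.duration_wholes == F(3, 4)
    assert merged.pitch == 60
    assert score.tempo_bpm == 90


def test_midi_voices_per_channel_and_onset_count(tmp_path):
    score, _ = generate_progression(seed=7, texture="two_voice")
    p = tmp_path / "x.mid"
    write_midi(score, p)
    back = read_score(p)
    # oracle: distinct onset times of the raw event list
    expected_onsets = sorted({e.onset for e in score.events})
    stream = chordify(back)
    assert [s.onset for s in stream] == expected_onsets
    assert len(back.voices()) == len(score.voices())


def test_unreadable_file_raises_parse_error(tmp_path):
    p = tmp_path / "bad.musicxml"
    p.write_text("<score-partwise><unclosed></score-partwise>")
    with pytest.raises(ValueError):
        read_score(p)


def test_missing_time_signature_is_reported(tmp_path):
    p = tmp_path / "no_ts.krn"
    p.write_text("**kern\n4c\n*-\n")
    with pytest.raises(ValueError, match="time signature"):
        read_score(p)


def test_missing_file():
    with pytest.raises(FileNotFoundError):
        read_score("/nonexistent/score.krn")


# -- chordify ---------------------------------------------------------------


def test_chordify_melody_over_held_bass():
    events = [
        NoteEvent(pitch=48, onset=F(0), duration_wholes=F(1), voice_id="bass"),
        NoteEvent(pitch=60, onset=F(0), duration_wholes=F(1, 4), voice_id="mel"),
        NoteEvent(pitch=64, onset=F(1, 4), duration_wholes=F(1, 4), voice_id="mel"),
        NoteEvent(pitch=67, onset=F(2, 4), duration_wholes=F(1, 4), voice_id="mel"),
    ]
    score = Score(events=events, time_signatures=[TimeSignature(F(0), 4, 4)])
    stream = chordify(score)
    assert len(stream) == 3
    assert stream[0].pitches == {48, 60} and stream[0].new_pitches == {48, 60}
    assert stream[1].pitches == {48, 64} and stream[1].new_pitches == {64}
    assert stream[1].prepared and not stream[0].prepared


def test_chordify_homophonic_chorale():
    score, _ = generate_progression(
        seed=0,
        chords=[("maj", 60, 1), ("min", 62, 1), ("dom7", 55, 1), ("maj", 60, 1)],
        hold_probability=0.0,
    )
    stream = chordify(score)
    assert len(stream) == 4
    assert all(s.new_pitches == s.pitches for s in stream)


def test_sonority_count_equals_distinct_onsets_random():
    score, _ = generate_progression(seed=7, texture="two_voice")
    stream = chordify(score)
    assert len(stream) == len({e.onset for e in score.events})
    # every slice's pitch content is sounding at that instant
    for s in stream:
        sounding = {
            e.pitch for e in score.events if e.onset <= s.onset < e.end
        }
        assert s.pitches <= sounding


@pytest.mark.parametrize("writer,ext", [(write_musicxml, "musicxml"), (write_kern, "krn"), (write_midi, "mid")])
def test_chordify_idempotent_under_reserialization(tmp_path, writer, ext):
    score, _ = generate_progression(seed=13, n_slices=10, hold_probability=0.4)
    p = tmp_path / f"s.{ext}"
    writer(score, p)
    s1 = chordify(score)
    s2 = chordify(read_score(p))
    assert len(s1) == len(s2)
    for a, b in zip(s1, s2):
        assert (a.onset, a.pitches, a.new_pitches) == (b.onset, b.pitches, b.new_pitches)


def test_grace_notes_join_pitch_sets_without_duration(tmp_path):
    events = [
        NoteEvent(pitch=62, onset=F(0), duration_wholes=F(0), voice_id="1", grace=True),
        NoteEvent(pitch=60, onset=F(0), duration_wholes=F(1, 4), voice_id="1"),
    ]
    score = Score(events=events, time_signatures=[TimeSignature(F(0), 4, 4)])
    stream = chordify(score)
    assert stream[0].pitches == {60, 62}
    assert stream[0].shortest_duration() == F(1)  # grace excluded from durations


# -- melody extraction -------------------------------------------------------


def test_monophonic_score_identical_under_all_strategies():
    score = make_melody([60, 64, 67, 72])
    for strategy in ("skyline", "top_voice"):
        assert [e.pitch for e in extract_melody(score, strategy)] == [60, 64, 67, 72]


def test_skyline_takes_highest_new_pitch_with_crossing_voices():
    events = []
    upper = [72, 60, 74, 61]  # crosses below the other voice twice
    lower = [65, 66, 65, 67]
    for i, (u, l) in enumerate(zip(upper, lower)):
        events.append(NoteEvent(pitch=u, onset=F(i, 4), duration_wholes=F(1, 4), voice_id="a"))
        events.append(NoteEvent(pitch=l, onset=F(i, 4), duration_wholes=F(1, 4), voice_id="b"))
    score = Score(events=events, time_signatures=[TimeSignature(F(0), 4, 4)])
    got = [e.pitch for e in extract_melody(score, "skyline")]
    expected = [max(u, l) for u, l in zip(upper, lower)]  # per-onset max oracle
    assert got == expected


def test_named_voice_missing_lists_available():
    score = make_melody([60, 62])
    with pytest.raises(ValueError, match="available"):
        extract_melody(score, "named_voice", voice="nope")


# -- accent table serialization ----------------------------------------------


def test_empty_table_writes_header_only(tmp_path):
    score = make_melody([60])
    stream = chordify(score)
    table = AccentTable(1)
    # header check on a no-accent table
    path = tmp_path / "a.csv"
    write_accent_table(table, stream, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "sonority_index,measure,beat,onset_wholes,pitches,M,C,Hv,Hh,H1,H2"


def test_written_value_is_six_decimal(tmp_path):
    score = make_melody([60])
    stream = chordify(score)
    table = AccentTable(1)
    table.set_column("M", [1.216])
    path = tmp_path / "a.csv"
    write_accent_table(table, stream, path)
    assert "1.216000" in path.read_text()


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_accent_table_round_trip(tmp_path, fmt):
    score, _ = make(FixtureSpec(seed=3, kind="progression"))
    stream = chordify(score)
    table = AccentTable(len(stream))
    import numpy as np

    rng = np.random.default_rng(8)
    for col in ("M", "C", "Hv", "Hh", "H1", "H2"):
        table.set_column(col, np.round(rng.uniform(0, 5, len(stream)), 6))
    path = tmp_path / f"a.{fmt}"
    write_accent_table(table, stream, path, fmt)
    _, back = read_accent_table(path, fmt)
    assert back == table


def test_misaligned_table_is_rejected(tmp_path):
    score = make_melody([60, 62])
    stream = chordify(score)
    with pytest.raises(ValueError, match="aligned"):
        write_accent_table(AccentTable(5), stream, tmp_path / "a.csv")
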