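"""Shared layout helper for the notation writers.

Both the MusicXML and the kern writer serialize a score voice by voice as a
sequential stream of pitched segments and rests, split at barlines with ties.
Voices must be internally monophonic-or-chordal: events in one voice that
share an onset must share a duration (a chord); partially overlapping events
within a single voice cannot be notated by these writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from ..score import Score


@dataclass(frozen=True)
class Segment:
    onset: Fraction
    duration: Fraction
    pitches: tuple[int, ...]  # empty = rest
    tie_start: bool = False
    tie_stop: bool = False
    grace: bool = False


def measure_starts(score: Score, until: Fraction) -> list[Fraction]:
    """Onsets of measure boundaries from 0 up to (and beyond) ``until``."""
    starts = [Fraction(0)]
    t = score.pickup_wholes if score.pickup_wholes else Fraction(0)
    if t > 0:
        starts.append(t)
    while t <= until:
        sig = score.signature_at(t)
        t += sig.measure_wholes
        starts.append(t)
    return starts


def layout_voice(score: Score, voice: str) -> list[list[Segment]]:
    """Segments of one voice, grouped per measure, rests filled, ties split."""
    events = [e for e in score.events if e.voice_id == voice]
    if not events:
        return []
    end = max(e.end for e in score.events)
    bars = measure_starts(score, end)
    # group simultaneous same-duration notes into chords
    by_onset: dict[Fraction, list] = {}
    for e in events:
        by_onset.setdefault(e.onset, []).append(e)
    items = []  # (onset, duration, pitches, grace)
    for t in sorted(by_onset):
        group = by_onset[t]
        graces = [e for e in group if e.grace]
        reals = [e for e in group if not e.grace]
        for g in graces:
            items.append((t, Fraction(0), (g.pitch,), True))
        if reals:
            durs = {e.duration_wholes for e in reals}
            if len(durs) > 1:
                raise ValueError(
                    f"voice {voice!r} has simultaneous notes of unequal duration "
                    f"at onset {t}; split them into separate voices to notate"
                )
            items.append(
                (t, durs.pop(), tuple(sorted(e.pitch for e in reals)), False)
            )
    # fill rests and split at barlines
    segments: list[Segment] = []
    cursor = Fraction(0)
    for onset, dur, pitches, grace in items:
        if onset < cursor:
            raise ValueError(f"voice {voice!r} has overlapping notes at {onset}")
        cursor = _emit_rests(segments, cursor, onset, bars)
        if grace:
            segments.append(Segment(onset, Fraction(0), pitches, grace=True))
            continue
        pieces = _split_at_bars(onset, dur, bars)
        for k, (t0, d0) in enumerate(pieces):
            segments.append(
                Segment(
                    t0,
                    d0,
                    pitches,
                    tie_start=k < len(pieces) - 1,
                    tie_stop=k > 0,
                )
            )
        cursor = onset + dur
    # trailing rests to the end of the last measure containing material
    bar_end = next(b for b in bars if b >= cursor)
    _emit_rests(segments, cursor, bar_end, bars)
    # group per measure
    out: list[list[Segment]] = []
    for b0, b1 in zip(bars, bars[1:]):
        in_bar = [s for s in segments if b0 <= s.onset < b1]
        if not in_bar and b0 >= bar_end:
            break
        out.append(in_bar)
    return out


def _emit_rests(
    segments: list[Segment], start: Fraction, end: Fraction, bars: list[Fraction]
) -> Fraction:
    t = start
    while t < end:
        bar_next = next(b for b in bars if b > t)
        d = min(end, bar_next) - t
        segments.append(Segment(t, d, ()))
        t += d
    return end


def _split_at_bars(
    onset: Fraction, dur: Fraction, bars: list[Fraction]
) -> list[tuple[Fraction, Fraction]]:
    pieces = []
    t = onset
    remaining = dur
    while remaining > 0:
        bar_next = next(b for b in bars if b > t)
        d = min(remaining, bar_next - t)
        pieces.append((t, d))
        t += d
        remaining -= d
    return pieces
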