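"""Standard MIDI File (types 0 and 1) reader and a small type-1 writer.

The reader pairs note-on/note-off events into notes, assigns voices per
track and channel, and converts tick time to whole-note units using the
file's division.  Tempo and time-signature meta events are honoured (the
first of each is used; mid-piece changes of meter are kept).  Because MIDI
has no notation layer there are no ties or grace notes; sustained pitches
simply have long durations.
"""

from __future__ import annotations

import struct
from fractions import Fraction
from pathlib import Path

from ..score import NoteEvent, Score, TimeSignature

__all__ = ["read_midi", "write_midi"]


class MidiError(ValueError):
    pass


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def _varlen(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(out))


def read_midi(path: str | Path) -> Score:
    data = Path(path).read_bytes()
    if data[:4] != b"MThd":
        raise MidiError(f"{path}: missing MThd header chunk")
    hlen = struct.unpack(">I", data[4:8])[0]
    fmt, ntracks, division = struct.unpack(">HHH", data[8:14])
    if fmt not in (0, 1):
        raise MidiError(f"{path}: unsupported SMF format {fmt}")
    if division & 0x8000:
        raise MidiError(f"{path}: SMPTE division is not supported")
    pos = 8 + hlen
    events: list[NoteEvent] = []
    time_sigs: list[TimeSignature] = []
    tempo_bpm: float | None = None
    for track_idx in range(ntracks):
        if data[pos : pos + 4] != b"MTrk":
            raise MidiError(f"{path}: expected MTrk chunk for track {track_idx}")
        tlen = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        track = data[pos + 8 : pos + 8 + tlen]
        pos += 8 + tlen
        _read_track(track, track_idx, division, events, time_sigs)
    tempo_bpm = _first_tempo(data)
    if not time_sigs:
        time_sigs = [TimeSignature(Fraction(0), 4, 4)]
    deduped: list[TimeSignature] = []
    for ts in sorted(time_sigs, key=lambda t: t.onset):
        if not deduped or (ts.numerator, ts.denominator) != (
            deduped[-1].numerator,
            deduped[-1].denominator,
        ):
            deduped.append(ts)
    score = Score(events=events, time_signatures=deduped, tempo_bpm=tempo_bpm)
    from ..score import renumber_events

    return renumber_events(score)


def _first_tempo(data: bytes) -> float | None:
    """First set-tempo meta event anywhere in the file."""
    idx = data.find(b"\xff\x51\x03")
    if idx == -1:
        return None
    usec = int.from_bytes(data[idx + 3 : idx + 6], "big")
    return 60_000_000 / usec


def _read_track(
    track: bytes,
    track_idx: int,
    division: int,
    events: list[NoteEvent],
    time_sigs: list[TimeSignature],
) -> None:
    pos = 0
    ticks = 0
    status = 0
    active: dict[tuple[int, int], int] = {}  # (channel, pitch) -> start ticks
    while pos < len(track):
        delta, pos = _read_varlen(track, pos)
        ticks += delta
        b = track[pos]
        if b >= 0x80:
            status = b
            pos += 1
        if status == 0xFF:
            meta = track[pos]
            pos += 1
            length, pos = _read_varlen(track, pos)
            payload = track[pos : pos + length]
            pos += length
            if meta == 0x58 and length >= 2:
                num = payload[0]
                den = 2 ** payload[1]
                onset = Fraction(ticks, division * 4)
                time_sigs.append(TimeSignature(onset, num, den))
            continue
        if status in (0xF0, 0xF7):
            length, pos = _read_varlen(track, pos)
            pos += length
            continue
        kind = status & 0xF0
        channel = status & 0x0F
        if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
            d1, d2 = track[pos], track[pos + 1]
            pos += 2
        elif kind in (0xC0, 0xD0):
            d1 = track[pos]
            pos += 1
            continue
        else:
            raise MidiError(f"unexpected status byte {status:#x}")
        if kind == 0x90 and d2 > 0:
            active[(channel, d1)] = ticks
        elif kind == 0x80 or (kind == 0x90 and d2 == 0):
            start = active.pop((channel, d1), None)
            if start is None:
                continue
            onset = Fraction(start, division * 4)
            dur = Fraction(ticks - start, division * 4)
            if dur > 0:
                events.append(
                    NoteEvent(
                        pitch=d1,
                        onset=onset,
                        duration_wholes=dur,
                        voice_id=f"t{track_idx}c{channel}",
                    )
                )


def write_midi(score: Score, path: str | Path, division: int = 480) -> None:
    """Write a type-1 SMF: one conductor track plus one track per voice."""
    voices = score.voices()
    chunks = []
    # conductor track: tempo + time signature
    conductor = bytearray()
    bpm = score.bpm()
    usec = int(round(60_000_000 / bpm))
    conductor += _varlen(0) + b"\xff\x51\x03" + usec.to_bytes(3, "big")
    cursor = 0
    for ts in score.time_signatures:
        tick = int(ts.onset * division * 4)
        conductor += _varlen(tick - cursor)
        cursor = tick
        denom_pow = ts.denominator.bit_length() - 1
        conductor += b"\xff\x58\x04" + bytes([ts.numerator, denom_pow, 24, 8])
    conductor += _varlen(0) + b"\xff\x2f\x00"
    chunks.append(bytes(conductor))
    for ch, v in enumerate(voices):
        msgs = []  # (ticks, order, bytes)
        for e in score.events:
            if e.voice_id != v or e.grace:
                continue
            on = int(e.onset * division * 4)
            off = int(e.end * division * 4)
            msgs.append((on, 1, bytes([0x90 | (ch % 16), e.pitch, 64])))
            msgs.append((off, 0, bytes([0x80 | (ch % 16), e.pitch, 0])))
        msgs.sort(key=lambda m: (m[0], m[1]))
        track = bytearray()
        t = 0
        for ticks, _, msg in msgs:
            track += _varlen(ticks - t) + msg
            t = ticks
        track += _varlen(0) + b"\xff\x2f\x00"
        chunks.append(bytes(track))
    out = bytearray()
    out += b"MThd" + struct.pack(">IHHH", 6, 1, len(chunks), division)
    for c in chunks:
        out += b"MTrk" + struct.pack(">I", len(c)) + c
    Path(path).write_bytes(bytes(out))
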