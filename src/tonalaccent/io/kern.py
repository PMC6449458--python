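"""Minimal Humdrum **kern reader/writer.

Supports the structural subset of kern needed for chord-slice analysis:
multiple **kern spines (tab-separated, one voice each), recip durations with
dots, chords (space-separated notes in a token), rests, ties ([ _ ]), grace
notes (q), barlines, *M time signatures and *MM tempo.  Spine splits/joins
and layout/editorial signifiers are not supported.
"""

from __future__ import annotations

import re
from fractions import Fraction
from pathlib import Path

from ..score import NoteEvent, Score, TimeSignature
from ._voicelay import layout_voice

__all__ = ["read_kern", "write_kern"]


class KernError(ValueError):
    pass


_NOTE_RE = re.compile(
    r"^(?P<open>\[?)(?P<recip>\d+)(?P<dots>\.*)(?P<grace>q?)"
    r"(?P<letters>[a-gA-G]+)(?P<acc>[#\-n]*)(?P<close>[\]_]?)$"
)
_REST_RE = re.compile(r"^(?P<recip>\d+)(?P<dots>\.*)r$")


def _recip_to_wholes(recip: int, dots: int) -> Fraction:
    if recip == 0:
        base = Fraction(2)  # breve
    else:
        base = Fraction(1, recip)
    return base * (2 - Fraction(1, 2**dots))


def _wholes_to_recip(d: Fraction) -> str:
    for dots in range(0, 4):
        mult = 2 - Fraction(1, 2**dots)
        base = d / mult
        if base.numerator == 1:
            return f"{base.denominator}{'.' * dots}"
        if base == 2:
            return f"0{'.' * dots}"
    raise KernError(f"duration {d} not expressible as a dotted recip value")


def _kern_pitch_to_midi(letters: str, acc: str) -> int:
    base = {"c": 0, "d": 2, "e": 4, "f": 5, "g": 7, "a": 9, "b": 11}
    ch = letters[0]
    if letters != ch * len(letters):
        raise KernError(f"malformed kern pitch {letters!r}")
    if ch.islower():
        octave = 3 + len(letters)  # c = C4, cc = C5
    else:
        octave = 4 - len(letters)  # C = C3, CC = C2
    pc = base[ch.lower()]
    alter = acc.count("#") - acc.count("-")
    return 12 * (octave + 1) + pc + alter


def _midi_to_kern_pitch(midi: int) -> str:
    names = {0: "c", 2: "d", 4: "e", 5: "f", 7: "g", 9: "a", 11: "b"}
    pc = midi % 12
    acc = ""
    if pc not in names:
        pc -= 1
        acc = "#"
    letter = names[pc]
    octave = midi // 12 - 1
    if octave >= 4:
        s = letter * (octave - 3)
    else:
        s = letter.upper() * (4 - octave)
    return s + acc


def read_kern(path: str | Path) -> Score:
    text = Path(path).read_text()
    lines = text.splitlines()
    n_spines = 0
    spine_time: list[Fraction] = []
    open_ties: list[dict[int, int]] = []
    events: list[NoteEvent] = []
    time_sigs: list[TimeSignature] = []
    tempo_bpm: float | None = None
    tempo_word: str | None = None
    title = ""
    first_bar_at: Fraction | None = None

    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        if line.startswith("!!!OTL"):
            title = line.split(":", 1)[-1].strip()
            continue
        if line.startswith("!!!OMD"):
            tempo_word = line.split(":", 1)[-1].strip()
            continue
        if line.startswith("!"):
            continue
        tokens = line.split("\t")
        if line.startswith("**"):
            if any(t != "**kern" for t in tokens):
                raise KernError(f"{path}:{lineno}: only **kern spines are supported")
            n_spines = len(tokens)
            spine_time = [Fraction(0)] * n_spines
            open_ties = [dict() for _ in range(n_spines)]
            continue
        if n_spines == 0:
            raise KernError(f"{path}:{lineno}: data before **kern header")
        if line.startswith("*"):
            for t in tokens:
                m = re.match(r"^\*M(\d+)/(\d+)$", t)
                if m:
                    onset = min(spine_time) if spine_time else Fraction(0)
                    num, den = int(m.group(1)), int(m.group(2))
                    if not any(
                        ts.numerator == num and ts.denominator == den
                        for ts in time_sigs
                        if ts.onset == onset
                    ):
                        time_sigs.append(TimeSignature(onset, num, den))
                m = re.match(r"^\*MM([\d.]+)$", t)
                if m:
                    tempo_bpm = float(m.group(1))
            continue
        if line.startswith("="):
            if first_bar_at is None:
                first_bar_at = max(spine_time)
            continue
        # data line
        if len(tokens) != n_spines:
            raise KernError(
                f"{path}:{lineno}: expected {n_spines} spine tokens, got {len(tokens)}"
            )
        for s, token in enumerate(tokens):
            if token == ".":
                continue
            _read_token(path, lineno, token, s, spine_time, open_ties, events)

    if not time_sigs:
        raise KernError(
            f"{path}: no *M time signature found; supply one via configuration override"
        )
    pickup = Fraction(0)
    nominal = time_sigs[0].measure_wholes
    if first_bar_at is not None and 0 < first_bar_at < nominal:
        pickup = first_bar_at
    score = Score(
        events=events,
        time_signatures=time_sigs,
        tempo_bpm=tempo_bpm,
        tempo_word=tempo_word,
        pickup_wholes=pickup,
        title=title,
    )
    from ..score import renumber_events

    return renumber_events(score)


def _read_token(path, lineno, token, s, spine_time, open_ties, events) -> None:
    t0 = spine_time[s]
    advance: Fraction | None = None
    for chunk in token.split(" "):
        m = _REST_RE.match(chunk)
        if m:
            d = _recip_to_wholes(int(m.group("recip")), len(m.group("dots")))
            advance = d if advance is None else min(advance, d)
            continue
        m = _NOTE_RE.match(chunk)
        if not m:
            raise KernError(f"{path}:{lineno}: unsupported kern token {chunk!r}")
        grace = bool(m.group("grace"))
        d = (
            Fraction(0)
            if grace
            else _recip_to_wholes(int(m.group("recip")), len(m.group("dots")))
        )
        midi = _kern_pitch_to_midi(m.group("letters"), m.group("acc"))
        closing = m.group("close")
        if closing in ("]", "_") and midi in open_ties[s]:
            idx = open_ties[s][midi]
            prev = events[idx]
            events[idx] = NoteEvent(
                pitch=prev.pitch,
                onset=prev.onset,
                duration_wholes=prev.duration_wholes + d,
                voice_id=prev.voice_id,
                grace=prev.grace,
            )
            if closing == "]":
                del open_ties[s][midi]
        else:
            events.append(
                NoteEvent(
                    pitch=midi,
                    onset=t0,
                    duration_wholes=d,
                    voice_id=f"spine{s+1}",
                    grace=grace,
                )
            )
            if m.group("open") == "[" or closing == "_":
                open_ties[s][midi] = len(events) - 1
        if not grace:
            advance = d if advance is None else min(advance, d)
    if advance:
        spine_time[s] = t0 + advance


def write_kern(score: Score, path: str | Path) -> None:
    """Serialize a score, one kern spine per voice (spine 1 = first voice)."""
    voices = score.voices()
    per_voice = {v: layout_voice(score, v) for v in voices}
    n_measures = max((len(m) for m in per_voice.values()), default=0)
    lines = []
    if score.title:
        lines.append(f"!!!OTL: {score.title}")
    if score.tempo_word:
        lines.append(f"!!!OMD: {score.tempo_word}")
    lines.append("\t".join(["**kern"] * len(voices)))
    sig = score.time_signatures[0]
    lines.append("\t".join([f"*M{sig.numerator}/{sig.denominator}"] * len(voices)))
    if score.tempo_bpm:
        bpm = score.tempo_bpm
        bpm_s = str(int(bpm)) if bpm == int(bpm) else str(bpm)
        lines.append("\t".join([f"*MM{bpm_s}"] * len(voices)))
    number_offset = 0 if score.pickup_wholes else 1
    for m_idx in range(n_measures):
        if m_idx > 0 or not score.pickup_wholes:
            lines.append(
                "\t".join([f"={m_idx + number_offset}"] * len(voices))
            )
        # merge the voices' segments into rows by onset
        columns = []
        for v in voices:
            measures = per_voice[v]
            columns.append(measures[m_idx] if m_idx < len(measures) else [])
        onsets = sorted({s.onset for col in columns for s in col})
        for t in onsets:
            row = []
            for col in columns:
                here = [s for s in col if s.onset == t]
                row.append(" ".join(_seg_token(s) for s in here) if here else ".")
            lines.append("\t".join(row))
    lines.append("\t".join(["*-"] * len(voices)))
    Path(path).write_text("\n".join(lines) + "\n")


def _seg_token(seg) -> str:
    if not seg.pitches:
        return f"{_wholes_to_recip(seg.duration)}r"
    notes = []
    for p in seg.pitches:
        recip = "8q" if seg.grace else _wholes_to_recip(seg.duration)
        core = f"{recip}{_midi_to_kern_pitch(p)}"
        if seg.tie_start and seg.tie_stop:
            core = core + "_"
        elif seg.tie_start:
            core = "[" + core
        elif seg.tie_stop:
            core = core + "]"
        notes.append(core)
    return " ".join(notes)
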