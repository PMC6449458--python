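"""Minimal uncompressed MusicXML reader/writer (score-partwise).

Covers the subset of MusicXML needed for score analysis: pitched notes,
rests, chords, voices (one part per voice on write; parts x voices on read),
ties (merged into logical notes on read), grace notes, time signatures and
tempo (numeric per-quarter tempo and/or a tempo word).  Engraving details are
ignored.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from fractions import Fraction
from pathlib import Path

from ..score import NoteEvent, Score, TimeSignature, renumber_events
from ._voicelay import layout_voice

__all__ = ["read_musicxml", "write_musicxml"]

_STEP_TO_PC = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}
_PC_TO_STEP = {0: ("C", 0), 1: ("C", 1), 2: ("D", 0), 3: ("E", -1), 4: ("E", 0),
               5: ("F", 0), 6: ("F", 1), 7: ("G", 0), 8: ("A", -1), 9: ("A", 0),
               10: ("B", -1), 11: ("B", 0)}


class MusicXMLError(ValueError):
    pass


def read_musicxml(path: str | Path) -> Score:
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise MusicXMLError(f"unparseable MusicXML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "score-partwise":
        raise MusicXMLError(
            f"{path}: expected a <score-partwise> document, found <{root.tag}>"
        )
    title = (root.findtext("work/work-title") or "").strip()
    events: list[NoteEvent] = []
    time_sigs: list[TimeSignature] = []
    tempo_bpm: float | None = None
    tempo_word: str | None = None
    first_measure_span: Fraction | None = None

    for part in root.findall("part"):
        part_id = part.get("id", "P1")
        divisions = Fraction(1)
        pos = Fraction(0)
        open_ties: dict[tuple[str, int], int] = {}  # (voice, pitch) -> event idx
        part_events: list[NoteEvent] = []
        for m_idx, measure in enumerate(part.findall("measure")):
            measure_start = pos
            for el in measure:
                if el.tag == "attributes":
                    div = el.findtext("divisions")
                    if div:
                        divisions = Fraction(int(div))
                    time_el = el.find("time")
                    if time_el is not None:
                        num = int(time_el.findtext("beats"))
                        den = int(time_el.findtext("beat-type"))
                        if not any(
                            ts.numerator == num and ts.denominator == den and ts.onset == pos
                            for ts in time_sigs
                        ):
                            time_sigs.append(TimeSignature(pos, num, den))
                elif el.tag == "direction":
                    words = el.findtext("direction-type/words")
                    if words and tempo_word is None:
                        tempo_word = words.strip()
                    sound = el.find("sound")
                    if sound is not None and sound.get("tempo") and tempo_bpm is None:
                        tempo_bpm = float(sound.get("tempo"))
                elif el.tag == "sound":
                    if el.get("tempo") and tempo_bpm is None:
                        tempo_bpm = float(el.get("tempo"))
                elif el.tag == "backup":
                    pos -= _dur_wholes(el, divisions)
                elif el.tag == "forward":
                    pos += _dur_wholes(el, divisions)
                elif el.tag == "note":
                    pos = _read_note(
                        el, part_id, part_events, open_ties, pos, divisions
                    )
            if m_idx == 0:
                span = pos - measure_start
                if first_measure_span is None or span < first_measure_span:
                    first_measure_span = span
        events.extend(part_events)

    if not time_sigs:
        raise MusicXMLError(
            f"{path}: no time signature found; supply one via configuration override"
        )
    pickup = Fraction(0)
    nominal = time_sigs[0].measure_wholes
    if first_measure_span is not None and 0 < first_measure_span < nominal:
        pickup = first_measure_span
    score = Score(
        events=events,
        time_signatures=time_sigs,
        tempo_bpm=tempo_bpm,
        tempo_word=tempo_word,
        pickup_wholes=pickup,
        title=title,
    )
    return renumber_events(score)


def _dur_wholes(el: ET.Element, divisions: Fraction) -> Fraction:
    return Fraction(int(el.findtext("duration"))) / divisions / 4


def _read_note(
    el: ET.Element,
    part_id: str,
    events: list[NoteEvent],
    open_ties: dict,
    pos: Fraction,
    divisions: Fraction,
) -> Fraction:
    is_chord = el.find("chord") is not None
    is_grace = el.find("grace") is not None
    dur = Fraction(0) if is_grace else _dur_wholes(el, divisions)
    voice = el.findtext("voice") or "1"
    voice_id = f"{part_id}.{voice}"
    onset = pos if not is_chord else (events[-1].onset if events else pos)
    new_pos = pos if is_chord or is_grace else pos + dur
    if el.find("rest") is not None:
        return new_pos
    pitch_el = el.find("pitch")
    if pitch_el is None:
        raise MusicXMLError("note without <pitch> or <rest>")
    step = pitch_el.findtext("step")
    if step not in _STEP_TO_PC:
        raise MusicXMLError(f"bad <step> {step!r}")
    alter = int(float(pitch_el.findtext("alter") or 0))
    octave = int(pitch_el.findtext("octave"))
    midi = 12 * (octave + 1) + _STEP_TO_PC[step] + alter
    tie_types = {t.get("type") for t in el.findall("tie")}
    key = (voice_id, midi)
    if "stop" in tie_types and key in open_ties:
        idx = open_ties.pop(key)
        prev = events[idx]
        events[idx] = NoteEvent(
            pitch=prev.pitch,
            onset=prev.onset,
            duration_wholes=prev.duration_wholes + dur,
            voice_id=prev.voice_id,
            grace=prev.grace,
        )
        if "start" in tie_types:
            open_ties[key] = idx
        return new_pos
    events.append(
        NoteEvent(
            pitch=midi,
            onset=onset,
            duration_wholes=dur,
            voice_id=voice_id,
            grace=is_grace,
        )
    )
    if "start" in tie_types:
        open_ties[key] = len(events) - 1
    return new_pos




def write_musicxml(score: Score, path: str | Path) -> None:
    """Serialize a score, one MusicXML part per voice."""
    voices = score.voices()
    divisions = _choose_divisions(score)
    root = ET.Element("score-partwise", version="3.1")
    if score.title:
        work = ET.SubElement(root, "work")
        ET.SubElement(work, "work-title").text = score.title
    part_list = ET.SubElement(root, "part-list")
    for i, v in enumerate(voices, 1):
        sp = ET.SubElement(part_list, "score-part", id=f"P{i}")
        ET.SubElement(sp, "part-name").text = str(v)
    for i, v in enumerate(voices, 1):
        part = ET.SubElement(root, "part", id=f"P{i}")
        _write_part(part, score, v, divisions, first=(i == 1))
    ET.indent(root)
    Path(path).write_bytes(
        b'<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(root)
    )


def _choose_divisions(score: Score) -> int:
    div = 1
    for e in score.events:
        q = e.duration_wholes * 4
        div = _lcm(div, q.denominator)
        q = e.onset * 4
        div = _lcm(div, q.denominator)
    return div


def _lcm(a: int, b: int) -> int:
    from math import gcd

    return a * b // gcd(a, b)


def _write_part(
    part: ET.Element, score: Score, voice: str, divisions: int, first: bool
) -> None:
    measures = layout_voice(score, voice)
    sig0 = score.time_signatures[0]
    number_offset = 0 if score.pickup_wholes else 1
    for m_idx, segs in enumerate(measures):
        attrs_needed = m_idx == 0
        m_el = ET.SubElement(part, "measure", number=str(m_idx + number_offset))
        if score.pickup_wholes and m_idx == 0:
            m_el.set("implicit", "yes")
        if attrs_needed:
            attrs = ET.SubElement(m_el, "attributes")
            ET.SubElement(attrs, "divisions").text = str(divisions)
            t = ET.SubElement(attrs, "time")
            ET.SubElement(t, "beats").text = str(sig0.numerator)
            ET.SubElement(t, "beat-type").text = str(sig0.denominator)
            if first and (score.tempo_word or score.tempo_bpm):
                d = ET.SubElement(m_el, "direction", placement="above")
                dt = ET.SubElement(d, "direction-type")
                ET.SubElement(dt, "words").text = score.tempo_word or ""
                if score.tempo_bpm:
                    ET.SubElement(d, "sound", tempo=str(score.tempo_bpm))
        for seg in segs:
            _write_segment(m_el, seg, divisions)


def _write_segment(m_el: ET.Element, seg, divisions: int) -> None:
    ticks = int(seg.duration * 4 * divisions)
    if not seg.pitches:
        n = ET.SubElement(m_el, "note")
        ET.SubElement(n, "rest")
        ET.SubElement(n, "duration").text = str(ticks)
        return
    for k, midi in enumerate(seg.pitches):
        n = ET.SubElement(m_el, "note")
        if seg.grace:
            ET.SubElement(n, "grace")
        if k > 0:
            ET.SubElement(n, "chord")
        p = ET.SubElement(n, "pitch")
        step, alter = _PC_TO_STEP[midi % 12]
        ET.SubElement(p, "step").text = step
        if alter:
            ET.SubElement(p, "alter").text = str(alter)
        ET.SubElement(p, "octave").text = str(midi // 12 - 1)
        if not seg.grace:
            ET.SubElement(n, "duration").text = str(ticks)
        if seg.tie_stop:
            ET.SubElement(n, "tie", type="stop")
        if seg.tie_start:
            ET.SubElement(n, "tie", type="start")
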