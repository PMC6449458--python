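"""Core score representation: note events, sonorities and accent tables.

Score time is measured in whole-note units with exact rational arithmetic
(:class:`fractions.Fraction`), so that metrical subdivision tests are exact.
Pitches are MIDI semitone integers (middle C = 60).

A *sonority* is the model's atomic event: a vertical chord slice created at
every instant where at least one voice has a note onset.  Slicing performs no
reduction -- ornamental notes are included -- and tones held over from earlier
onsets remain members of later slices ("prepared" tones).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterator, Sequence

__all__ = [
    "NoteEvent",
    "TimeSignature",
    "Score",
    "Sonority",
    "SonorityStream",
    "AccentTable",
    "ACCENT_COLUMNS",
    "STYLES",
    "TEMPO_WORDS",
    "FAST_TEMPO_WORDS",
    "beat_duration_wholes",
    "chordify",
    "extract_melody",
    "score_bpm",
    "is_fast_tempo",
]

#: The three style classes understood by the harmonic accent model.
STYLES = ("baroque_classical", "romantic", "late_romantic")

#: Default mapping from Italian tempo words to beats per minute.  An explicit
#: numeric BPM on the score always overrides this table.
TEMPO_WORDS = {
    "largo": 50,
    "adagio": 60,
    "andante": 72,
    "andantino": 80,
    "moderato": 96,
    "allegretto": 112,
    "allegro": 132,
    "vivace": 152,
    "presto": 180,
}

#: Tempo words treated as "fast" for the duration-halving rule of the
#: harmonic accent model.
FAST_TEMPO_WORDS = frozenset({"allegretto", "allegro", "vivace", "presto"})

#: BPM at and above which a numeric tempo counts as fast (the slowest word in
#: :data:`FAST_TEMPO_WORDS` under the default word table).
FAST_BPM_THRESHOLD = 112

#: Columns of an accent table, in serialization order.
ACCENT_COLUMNS = ("M", "C", "Hv", "Hh", "H1", "H2")


@dataclass(frozen=True)
class NoteEvent:
    """One logical note (ties merged) in score time.

    ``duration_wholes`` may be zero only for grace notes, which participate in
    pitch sets but never in duration computations.
    """

    pitch: int
    onset: Fraction
    duration_wholes: Fraction
    voice_id: str = "1"
    measure: int = 1
    beat_in_measure: Fraction = Fraction(1)
    tied_from_previous: bool = False
    grace: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.pitch <= 127):
            raise ValueError(f"pitch {self.pitch} outside MIDI range 0..127")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration_wholes < 0 or (self.duration_wholes == 0 and not self.grace):
            raise ValueError("duration must be positive (zero only for grace notes)")

    @property
    def end(self) -> Fraction:
        return self.onset + self.duration_wholes


@dataclass(frozen=True)
class TimeSignature:
    onset: Fraction
    numerator: int
    denominator: int

    @property
    def measure_wholes(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def beat_wholes(self) -> Fraction:
        return beat_duration_wholes(self.numerator, self.denominator)

    @property
    def beats_per_measure(self) -> Fraction:
        return self.measure_wholes / self.beat_wholes


def beat_duration_wholes(numerator: int, denominator: int) -> Fraction:
    """Notated beat duration for a meter, in whole notes.

    Compound meters (3/8, 6/8, 9/8, 12/8) have a dotted-quarter beat; all
    other meters take the denominator as the beat unit.
    """
    if denominator == 8 and numerator in (3, 6, 9, 12):
        return Fraction(3, 8)
    return Fraction(1, denominator)


@dataclass
class Score:
    """A parsed symbolic score.

    ``pickup_wholes`` is the length of an initial incomplete (anacrusis)
    measure; notes inside it are numbered measure 0 so that measure 1 is the
    first complete notated measure, matching conventional analysis numbering.
    """

    events: list[NoteEvent]
    time_signatures: list[TimeSignature]
    tempo_bpm: float | None = None
    tempo_word: str | None = None
    style: str = "romantic"
    half_time_signature: bool = False
    consonant_passing_tones: bool = False
    pickup_wholes: Fraction = Fraction(0)
    title: str = ""

    def __post_init__(self) -> None:
        if not self.time_signatures:
            raise ValueError(
                "score has no time signature; supply one via configuration override"
            )
        if self.style not in STYLES:
            raise ValueError(f"style must be one of {STYLES}, got {self.style!r}")
        self.events = sorted(
            self.events, key=lambda e: (e.onset, -e.pitch, e.voice_id)
        )

    # -- tempo ---------------------------------------------------------------

    def bpm(self, tempo_words: dict[str, float] | None = None) -> float:
        return score_bpm(self, tempo_words)

    def seconds_per_beat(self, tempo_words: dict[str, float] | None = None) -> float:
        return 60.0 / self.bpm(tempo_words)

    # -- meter ---------------------------------------------------------------

    def signature_at(self, onset: Fraction) -> TimeSignature:
        active = self.time_signatures[0]
        for ts in self.time_signatures:
            if ts.onset <= onset:
                active = ts
            else:
                break
        return active

    def measure_and_beat(self, onset: Fraction) -> tuple[int, Fraction]:
        """Measure number and 1-based beat position of a score time.

        Beat positions are fractional for off-beat onsets (beat 1.5 is the
        second eighth of a quarter-note beat).
        """
        if self.pickup_wholes and onset < self.pickup_wholes:
            ts = self.time_signatures[0]
            # count beats backwards from the barline so a one-beat pickup in
            # 3/4 sits on beat 3
            beats_before_bar = (self.pickup_wholes - onset) / ts.beat_wholes
            beat = ts.beats_per_measure - beats_before_bar + 1
            return 0, beat
        start = self.pickup_wholes
        measure = 1
        sigs = [ts for ts in self.time_signatures]
        active = sigs[0]
        next_idx = 1
        while True:
            if next_idx < len(sigs) and sigs[next_idx].onset <= start:
                active = sigs[next_idx]
                next_idx += 1
            if start + active.measure_wholes > onset:
                beat = (onset - start) / active.beat_wholes + 1
                return measure, beat
            start += active.measure_wholes
            measure += 1

    def voices(self) -> list[str]:
        return sorted({e.voice_id for e in self.events})

    def transposed(self, semitones: int) -> "Score":
        events = [replace(e, pitch=e.pitch + semitones) for e in self.events]
        return replace(self, events=events)


def renumber_events(score: Score) -> Score:
    """Recompute each event's measure and beat from its onset (in place)."""
    renumbered = []
    for e in score.events:
        m, b = score.measure_and_beat(e.onset)
        renumbered.append(replace(e, measure=m, beat_in_measure=b))
    score.events = renumbered
    return score


def score_bpm(score: Score, tempo_words: dict[str, float] | None = None) -> float:
    """Resolve the working tempo of a score to beats per minute.

    Explicit numeric BPM wins; otherwise the tempo word is looked up in the
    (configurable) word table; with neither, a moderate 96 BPM is assumed.
    """
    if score.tempo_bpm is not None:
        return float(score.tempo_bpm)
    table = dict(TEMPO_WORDS)
    if tempo_words:
        table.update({k.lower(): v for k, v in tempo_words.items()})
    if score.tempo_word:
        word = score.tempo_word.strip().lower()
        if word in table:
            return float(table[word])
    return 96.0


def is_fast_tempo(score: Score) -> bool:
    """Whether the notated tempo triggers the duration-halving rescale."""
    if score.tempo_word and score.tempo_word.strip().lower() in FAST_TEMPO_WORDS:
        return True
    if score.tempo_bpm is not None:
        return score.tempo_bpm >= FAST_BPM_THRESHOLD
    return False


@dataclass(frozen=True)
class Sonority:
    """One chord slice: everything sounding at a single onset instant."""

    index: int
    onset: Fraction
    pitches: frozenset[int]
    new_pitches: frozenset[int]
    notated_durations: dict[int, Fraction]  # per pitch, in beats
    measure: int
    beat_in_measure: Fraction

    def __post_init__(self) -> None:
        if not self.new_pitches:
            raise ValueError("a sonority exists only at an onset")
        if not self.new_pitches <= self.pitches:
            raise ValueError("new_pitches must be a subset of pitches")

    @property
    def prepared(self) -> bool:
        """True when at least one tone is held over from an earlier onset."""
        return self.pitches != self.new_pitches

    def shortest_duration(self) -> Fraction:
        ds = [d for d in self.notated_durations.values() if d > 0]
        return min(ds) if ds else Fraction(0)

    def longest_duration(self) -> Fraction:
        ds = [d for d in self.notated_durations.values() if d > 0]
        return max(ds) if ds else Fraction(0)


@dataclass
class SonorityStream:
    """Time-ordered chord slices plus the meter/tempo context they live in."""

    sonorities: list[Sonority]
    beats_per_measure: Fraction
    beat_duration_wholes: Fraction
    seconds_per_beat: float
    measure_wholes: Fraction
    anchor: Fraction = Fraction(0)  # onset of the first notated downbeat

    def __post_init__(self) -> None:
        onsets = [s.onset for s in self.sonorities]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("sonority onsets must be strictly increasing")
        if self.beats_per_measure < 1:
            raise ValueError("beats_per_measure must be >= 1")

    def __len__(self) -> int:
        return len(self.sonorities)

    def __iter__(self) -> Iterator[Sonority]:
        return iter(self.sonorities)

    def __getitem__(self, i: int) -> Sonority:
        return self.sonorities[i]


def chordify(score: Score, tempo_words: dict[str, float] | None = None) -> SonorityStream:
    """Slice a score into sonorities, one per distinct note-onset time.

    Every pitch sounding at the slice instant is included without reduction.
    Per-pitch notated durations are expressed in beats of the prevailing
    meter; for tones held over from an earlier onset the *remaining* notated
    duration from the slice onset is used.  Grace notes join the pitch sets
    but contribute no duration.
    """
    onsets = sorted({e.onset for e in score.events})
    first_sig = score.time_signatures[0]
    beat = first_sig.beat_wholes
    sonorities: list[Sonority] = []
    for i, t in enumerate(onsets):
        sig = score.signature_at(t)
        beat_here = sig.beat_wholes
        new_pitches: set[int] = set()
        pitches: set[int] = set()
        durations: dict[int, Fraction] = {}
        for e in score.events:
            if e.onset == t:
                new_pitches.add(e.pitch)
                pitches.add(e.pitch)
                if not e.grace:
                    d = e.duration_wholes / beat_here
                    durations[e.pitch] = max(durations.get(e.pitch, Fraction(0)), d)
            elif e.onset < t < e.end:
                pitches.add(e.pitch)
                d = (e.end - t) / beat_here
                if d > 0:
                    durations[e.pitch] = max(durations.get(e.pitch, Fraction(0)), d)
        measure, beat_pos = score.measure_and_beat(t)
        sonorities.append(
            Sonority(
                index=i,
                onset=t,
                pitches=frozenset(pitches),
                new_pitches=frozenset(new_pitches),
                notated_durations=durations,
                measure=measure,
                beat_in_measure=beat_pos,
            )
        )
    return SonorityStream(
        sonorities=sonorities,
        beats_per_measure=first_sig.beats_per_measure,
        beat_duration_wholes=beat,
        seconds_per_beat=score.seconds_per_beat(tempo_words),
        measure_wholes=first_sig.measure_wholes,
        anchor=score.pickup_wholes,
    )


def extract_melody(
    score: Score, strategy: str = "skyline", voice: str | None = None
) -> list[NoteEvent]:
    """Extract a monophonic melodic line from a score.

    ``skyline`` (default) takes the highest newly struck pitch at every
    sonority; ``top_voice`` the voice with the highest-sorting label;
    ``named_voice`` an explicitly named voice.
    """
    if not score.events:
        raise ValueError("cannot extract a melody from an empty score")
    if strategy == "named_voice":
        if voice is None or voice not in score.voices():
            raise ValueError(
                f"voice {voice!r} not found; available voices: {score.voices()}"
            )
        return [e for e in score.events if e.voice_id == voice and not e.grace]
    if strategy == "top_voice":
        top = score.voices()[-1]
        return [e for e in score.events if e.voice_id == top and not e.grace]
    if strategy == "skyline":
        by_onset: dict[Fraction, NoteEvent] = {}
        for e in score.events:
            if e.grace:
                continue
            cur = by_onset.get(e.onset)
            if cur is None or e.pitch > cur.pitch:
                by_onset[e.onset] = e
        return [by_onset[t] for t in sorted(by_onset)]
    raise ValueError(f"unknown melody strategy {strategy!r}")


class AccentTable:
    """Per-sonority accent saliences for the six model columns.

    All values live on the 0-5 salience scale; category cutoffs zero small
    values before the table is filled, so stored values are either exactly 0
    or at least the category cutoff.
    """

    def __init__(self, n: int, provenance: str = "") -> None:
        self.n = n
        self.provenance = provenance
        self._cols: dict[str, list[float]] = {c: [0.0] * n for c in ACCENT_COLUMNS}

    def __len__(self) -> int:
        return self.n

    def column(self, name: str) -> list[float]:
        return list(self._cols[name])

    def set_column(self, name: str, values: Sequence[float]) -> None:
        if name not in ACCENT_COLUMNS:
            raise KeyError(name)
        vals = [float(v) for v in values]
        if len(vals) != self.n:
            raise ValueError(
                f"column {name} has {len(vals)} values for {self.n} sonorities"
            )
        if any(v < 0 or v > 5 for v in vals):
            raise ValueError("accent saliences must lie in [0, 5]")
        self._cols[name] = vals

    def rows(self) -> Iterator[dict[str, float]]:
        for i in range(self.n):
            yield {c: self._cols[c][i] for c in ACCENT_COLUMNS}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AccentTable):
            return NotImplemented
        return self.n == other.n and all(
            all(abs(a - b) < 5e-7 for a, b in zip(self._cols[c], other._cols[c]))
            for c in ACCENT_COLUMNS
        )
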