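"""Deterministic synthetic fixtures: scores, corpora and rating matrices.

Every generator is a pure function of its seed and parameters, and emits
machine-readable ground truth beside the score so that each model can be
tested without any external corpus or recording:

* metrically gridded scores for the supported time signatures,
* monophonic melodies with controlled leaps, peaks and valleys,
* homophonic chord progressions with known Tn types and held tones,
* multi-rater accent-mark matrices as noisy copies of a model output,
* a hand-encoded melodic skeleton of Chopin's Prelude Op. 28 No. 7.

The skeleton encodes only documented melodic facts of that piece -- the 3/4
meter, the accent pitches and the leaps that precede them (M6 into the m.1
C#5, P5 into the m.2 F#5, P4 into the m.3 A5 and the m.11 C#6, the m.6
contour valley, m.9 repeating m.1) -- not a full edition.  The free filler
notes between those fixed points were chosen so that the documented
qualitative orderings of the contour accents emerge under default model
parameters (in particular, the m.3 accent stays below saturation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .evaluation import RatingSet
from .harmonic import FamiliarityTable, tn_type
from .metrical import TABLE_LEVELS
from .score import (
    NoteEvent,
    Score,
    TimeSignature,
    beat_duration_wholes,
    renumber_events,
)

__all__ = [
    "FixtureSpec",
    "CHORD_TEMPLATES",
    "generate_metrical_grid",
    "generate_melody",
    "generate_progression",
    "prelude7_skeleton",
    "generate_ratings",
    "default_familiarity_table",
    "make",
]

F = Fraction

#: Interval templates (semitones above the bass) for progression chords.
CHORD_TEMPLATES: dict[str, tuple[int, ...]] = {
    "single": (0,),
    "fifth": (0, 7),
    "maj": (0, 4, 7),
    "min": (0, 3, 7),
    "dim": (0, 3, 6),
    "aug": (0, 4, 8),
    "dom7": (0, 4, 7, 10),
    "maj7": (0, 4, 7, 11),
    "min7": (0, 3, 7, 10),
    "dom9": (0, 2, 4, 7, 10),
    "cluster": (0, 1, 2),
}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    kind: str = "melody"
    params: dict = field(default_factory=dict)


def make(spec: FixtureSpec):
    """Dispatch a fixture spec to its generator."""
    fns = {
        "metrical_grid": generate_metrical_grid,
        "melody": generate_melody,
        "progression": generate_progression,
        "prelude7_skeleton": lambda seed, **_: (prelude7_skeleton(), {}),
    }
    if spec.kind == "ratings":
        raise ValueError("ratings fixtures need a truth table; call generate_ratings")
    if spec.kind not in fns:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return fns[spec.kind](seed=spec.seed, **spec.params)


# -- metrical grid -----------------------------------------------------------


def generate_metrical_grid(
    seed: int = 0,
    time_signature: tuple[int, int] = (3, 4),
    n_measures: int = 4,
    bpm: float = 60.0,
    subdivision: str = "eighth",
    pitch: int = 72,
) -> tuple[Score, dict]:
    """Score with one note on every grid subdivision, plus level ground truth.

    Ground truth maps each onset (str of the whole-note Fraction) to the
    metrical levels it occupies, computed arithmetically from the pulse
    durations of the time signature.
    """
    if time_signature not in TABLE_LEVELS:
        raise ValueError(f"unsupported time signature {time_signature}")
    levels = TABLE_LEVELS[time_signature]
    step = levels[0] if subdivision == "eighth" else levels[1]
    measure = Fraction(*time_signature)
    total = n_measures * measure
    events = []
    truth: dict[str, list[int]] = {}
    t = Fraction(0)
    while t < total:
        events.append(
            NoteEvent(pitch=pitch, onset=t, duration_wholes=step, voice_id="1")
        )
        truth[str(t)] = [i for i, d in enumerate(levels) if t % d == 0]
        t += step
    score = Score(
        events=events,
        time_signatures=[TimeSignature(F(0), *time_signature)],
        tempo_bpm=bpm,
    )
    return renumber_events(score), {
        "levels_by_onset": truth,
        "time_signature": list(time_signature),
    }


# -- melodies ----------------------------------------------------------------


def generate_melody(
    seed: int = 0,
    kind: str = "random_walk",
    n_notes: int = 24,
    time_signature: tuple[int, int] = (4, 4),
    bpm: float = 96.0,
    start_pitch: int = 72,
    leap_choices: Sequence[int] = (-9, -5, -2, -1, 1, 2, 5, 9),
    rise: int = 2,
    apex_leap: int = 9,
) -> tuple[Score, dict]:
    """Monophonic melody with controlled contour, plus extrema ground truth.

    Kinds: ``arch`` (up by ``rise`` steps then down, one peak), ``sawtooth``
    (repeated rises of ``apex_leap`` then a fall), ``random_walk`` (seeded
    draws from ``leap_choices``).  Ground truth lists the indices of strict
    local maxima (peaks) and minima (valleys) of the pitch sequence.
    """
    if n_notes < 2:
        raise ValueError("a melody needs at least two notes")
    rng = np.random.default_rng(seed)
    pitches = [start_pitch]
    if kind == "arch":
        half = n_notes // 2
        for i in range(1, n_notes):
            delta = rise if i <= half else -rise
            pitches.append(pitches[-1] + delta)
    elif kind == "sawtooth":
        for i in range(1, n_notes):
            delta = apex_leap if i % 2 == 1 else -apex_leap
            pitches.append(pitches[-1] + delta)
    elif kind == "random_walk":
        for _ in range(1, n_notes):
            p = pitches[-1] + int(rng.choice(leap_choices))
            pitches.append(min(108, max(36, p)))
    else:
        raise ValueError(f"unknown melody kind {kind!r}")
    beat = beat_duration_wholes(*time_signature)
    events = [
        NoteEvent(pitch=p, onset=i * beat, duration_wholes=beat, voice_id="1")
        for i, p in enumerate(pitches)
    ]
    peaks = [
        i
        for i in range(1, n_notes - 1)
        if pitches[i - 1] < pitches[i] > pitches[i + 1]
    ]
    valleys = [
        i
        for i in range(1, n_notes - 1)
        if pitches[i - 1] > pitches[i] < pitches[i + 1]
    ]
    score = Score(
        events=events,
        time_signatures=[TimeSignature(F(0), *time_signature)],
        tempo_bpm=bpm,
    )
    return renumber_events(score), {
        "pitches": pitches,
        "peaks": peaks,
        "valleys": valleys,
    }


# -- progressions ------------------------------------------------------------


def generate_progression(
    seed: int = 0,
    chords: Sequence[tuple[str, int, float]] | None = None,
    n_slices: int = 12,
    time_signature: tuple[int, int] = (4, 4),
    bpm: float = 96.0,
    texture: str = "homophonic",
    hold_probability: float = 0.25,
    template_names: Sequence[str] | None = None,
) -> tuple[Score, dict]:
    """Chord-slice progression with known Tn types.

    ``chords`` fixes an explicit sequence of (template, bass midi, beats);
    otherwise ``n_slices`` chords are drawn with the seeded generator.  With
    probability ``hold_probability`` a chord's bass is tied through the next
    slice, making that slice a prepared sonority.  ``texture='two_voice'``
    instead emits a quarter-note upper line over a half-note bass line with
    deliberately interleaved onsets.

    Ground truth: per-slice Tn type, preparedness and onset.
    """
    rng = np.random.default_rng(seed)
    beat = beat_duration_wholes(*time_signature)
    names = list(template_names or ("maj", "maj", "min", "dom7", "dim", "min7"))

    if texture == "two_voice":
        events = []
        t = Fraction(0)
        for i in range(n_slices):
            p = 72 + int(rng.integers(-5, 8))
            d = beat if rng.random() < 0.7 else beat / 2
            events.append(NoteEvent(pitch=p, onset=t, duration_wholes=d, voice_id="v2"))
            t += d
        tb = Fraction(0)
        end = t
        while tb < end:
            p = 48 + int(rng.integers(0, 12))
            events.append(
                NoteEvent(pitch=p, onset=tb, duration_wholes=2 * beat, voice_id="v1")
            )
            tb += 2 * beat
        score = Score(
            events=events,
            time_signatures=[TimeSignature(F(0), *time_signature)],
            tempo_bpm=bpm,
        )
        return renumber_events(score), {"n_upper_notes": n_slices}

    if chords is None:
        chords = [
            (
                names[int(rng.integers(0, len(names)))],
                48 + int(rng.integers(0, 12)),
                float(rng.choice([0.5, 1.0, 2.0])),
            )
            for _ in range(n_slices)
        ]
    holds = [
        chords[i][0] != "single" and rng.random() < hold_probability
        for i in range(len(chords) - 1)
    ] + [False]

    events: list[NoteEvent] = []
    truth_rows = []
    t = Fraction(0)
    durs = [Fraction(c[2]).limit_denominator(16) * beat for c in chords]
    for i, (name, bass, _) in enumerate(chords):
        if name not in CHORD_TEMPLATES:
            raise ValueError(f"unknown chord template {name!r}")
        intervals = CHORD_TEMPLATES[name]
        d = durs[i]
        for v, iv in enumerate(intervals):
            dur = d
            voice = f"v{v+1}"
            if v == 0 and holds[i]:
                # bass tied through the next slice; alternate voices so
                # consecutive holds stay monophonic per voice
                dur = d + durs[i + 1]
                voice = f"hold{i % 2}"
            events.append(
                NoteEvent(pitch=bass + iv, onset=t, duration_wholes=dur, voice_id=voice)
            )
        t += d
    t = Fraction(0)
    for i, (name, bass, _) in enumerate(chords):
        pitches = {bass + iv for iv in CHORD_TEMPLATES[name]}
        held = {chords[i - 1][1]} if i > 0 and holds[i - 1] else set()
        prepared = not held <= pitches
        truth_rows.append(
            {
                "index": i,
                "onset": str(t),
                "tn_type": list(tn_type(pitches | held)),
                "prepared": prepared,
            }
        )
        t += durs[i]
    score = Score(
        events=events,
        time_signatures=[TimeSignature(F(0), *time_signature)],
        tempo_bpm=bpm,
    )
    return renumber_events(score), {"slices": truth_rows}


# -- Prelude Op. 28 No. 7 melodic skeleton -----------------------------------

# (measure, beat, duration in beats, midi); measure 0 is the pickup.
_PRELUDE7_NOTES: tuple[tuple[int, float, float, int], ...] = (
    (0, 3, 1, 64),                                  # E4 upbeat
    (1, 1, 1, 73), (1, 2, 0.5, 74), (1, 2.5, 0.5, 80),
    (1, 3, 0.5, 80), (1, 3.5, 0.5, 80),             # C#5 accent after the M6
    (2, 1, 1, 81), (2, 2, 1, 71),
    (2, 3, 0.5, 78), (2, 3.5, 0.5, 81),             # B4 -> F#5 (P5) accent
    (3, 1, 0.25, 83), (3, 1.25, 0.25, 83), (3, 1.5, 0.25, 83),
    (3, 1.75, 0.25, 76), (3, 2, 2, 81),             # E5 -> A5 (P4) accent, b2
    (4, 1, 1, 80), (4, 2, 1, 78), (4, 3, 1, 76),
    (5, 1, 1, 74), (5, 2, 1, 73), (5, 3, 1, 71),
    (6, 1, 1, 71), (6, 2, 1, 73), (6, 3, 1, 64),    # contour valley, b3
    (7, 1, 1, 69), (7, 2, 1, 71), (7, 3, 1, 73),
    (8, 1, 1, 68), (8, 2, 1, 66), (8, 3, 1, 64),    # E4 again before m.9
    (9, 1, 1, 73), (9, 2, 0.5, 74), (9, 2.5, 0.5, 80),
    (9, 3, 0.5, 80), (9, 3.5, 0.5, 80),             # m.9 repeats m.1
    (10, 1, 1, 76), (10, 2, 1, 78), (10, 3, 1, 80),
    (11, 1, 1, 80), (11, 2, 2, 85),                 # G#5 -> C#6 (P4) climax, b2
    (12, 1, 1, 83), (12, 2, 1, 81), (12, 3, 1, 80),
    (13, 1, 1, 78), (13, 2, 1, 76), (13, 3, 1, 74),
    (14, 1, 1, 73), (14, 2, 1, 71), (14, 3, 1, 68),
    (15, 1, 3, 69),                                 # final A4
)


def prelude7_skeleton() -> Score:
    """Melodic skeleton of Chopin's Prelude Op. 28 No. 7 (3/4, Andantino).

    Hand-encoded from documented melodic facts only (see module docstring);
    the filler between the fixed accent points is synthetic.
    """
    beat = F(1, 4)
    pickup = beat  # one-beat upbeat: the pickup E4 sits on beat 3 of measure 0
    events = []
    for measure, beat_pos, dur, midi in _PRELUDE7_NOTES:
        b = F(beat_pos).limit_denominator(16)
        if measure == 0:
            onset = (b - 3) * beat + pickup - beat
        else:
            onset = pickup + ((measure - 1) * 3 + (b - 1)) * beat
        events.append(
            NoteEvent(
                pitch=midi,
                onset=onset,
                duration_wholes=F(dur).limit_denominator(16) * beat,
                voice_id="melody",
                measure=measure,
                beat_in_measure=b,
            )
        )
    return Score(
        events=events,
        time_signatures=[TimeSignature(F(0), 3, 4)],
        tempo_word="Andantino",
        pickup_wholes=F(1, 4),
        title="Prelude Op. 28 No. 7 melodic skeleton (synthetic filler)",
    )


# -- ratings -----------------------------------------------------------------


def generate_ratings(
    truth: Sequence[float],
    n_raters: int = 5,
    noise_sd: float = 0.8,
    mark_prob: float = 0.9,
    seed: int = 0,
    category: str = "C",
) -> RatingSet:
    """Raters as rounded, clipped, noisy copies of a truth vector.

    Each rater marks round(clip(truth + N(0, noise_sd), 0, 5)) and
    independently drops every note with probability 1 - mark_prob.
    """
    if n_raters < 1 or noise_sd < 0 or not (0 < mark_prob <= 1):
        raise ValueError("invalid rating-generator parameters")
    rng = np.random.default_rng(seed)
    base = np.asarray(truth, dtype=float)
    mat = np.zeros((n_raters, base.shape[0]))
    for r in range(n_raters):
        noisy = np.round(np.clip(base + rng.normal(0, noise_sd, base.shape), 0, 5))
        keep = rng.random(base.shape) < mark_prob
        mat[r] = np.where(keep, noisy, 0.0)
    return RatingSet(matrix=mat, category=category)


# -- bundled familiarity table ----------------------------------------------


def default_familiarity_table(seed: int = 2023, n_slices: int = 200) -> FamiliarityTable:
    """Synthetic familiarity table from a generated 200-slice corpus.

    The template mix is weighted so the major triad is the most frequent
    sonority type, echoing the rank order a tonal-piano corpus would give,
    but the counts are synthetic and carry a provenance note saying so.
    """
    rng = np.random.default_rng(seed)
    names = list(CHORD_TEMPLATES)
    weights = {
        "maj": 0.30, "min": 0.16, "single": 0.14, "fifth": 0.08, "dom7": 0.10,
        "dim": 0.06, "min7": 0.06, "maj7": 0.04, "aug": 0.02, "dom9": 0.02,
        "cluster": 0.02,
    }
    probs = np.array([weights[n] for n in names])
    probs = probs / probs.sum()
    chords = [
        (
            names[int(rng.choice(len(names), p=probs))],
            48 + int(rng.integers(0, 12)),
            float(rng.choice([0.5, 1.0, 2.0])),
        )
        for _ in range(n_slices)
    ]
    score, _ = generate_progression(seed=seed + 1, chords=chords)
    from .corpus import count_scores

    summary = count_scores([score], provenance=f"synthetic corpus (seed={seed})")
    return summary.table
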