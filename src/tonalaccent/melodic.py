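"""Melodic contour accent model.

Two factors multiply to give the salience of a contour accent on a note: the
signed distance I1 of its pitch from a running mean pitch (the local centre
of the melody's ambitus), and the signed size I2 of the immediately
preceding melodic interval.  Falling/below-mean motion is attenuated
asymmetrically:

    CS1 = I1 if I1 > 0 else 0.7 * I1
    CS2 = I2 if I2 > 0 else 0.2 * I2
    CS  = CS1 * CS2 / N          (N = 2.5)

so only peak-after-rise and valley-after-fall configurations (I1, I2 of equal
sign) yield positive salience, and a magnitude-matched valley scores exactly
0.14 of its mirror peak.  Positive CS values are then pruned: the middle note
of three in same-direction stepwise motion is removed, only the largest CS in
any window of three consecutive notes is retained, values below the cutoff
(default 1) are zeroed, and values above 5 saturate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .score import NoteEvent

__all__ = [
    "MelodicParams",
    "running_mean_pitch",
    "contour_terms",
    "melodic_accents",
    "melodic_saliences",
]


@dataclass(frozen=True)
class MelodicParams:
    N_norm: float = 2.5
    below_mean_weight: float = 0.7
    falling_interval_weight: float = 0.2
    window_measures: int = 2
    min_context_notes: int = 10
    cutoff: float = 1.0
    saturation: float = 5.0
    stepwise_max_semitones: int = 2
    include_current_in_mean: bool = False

    def __post_init__(self) -> None:
        if self.N_norm <= 0 or self.cutoff < 0:
            raise ValueError("N_norm must be positive and cutoff nonnegative")
        for w in (self.below_mean_weight, self.falling_interval_weight):
            if not (0 < w <= 1):
                raise ValueError("branch weights must lie in (0, 1]")


def running_mean_pitch(
    melody: Sequence[NoteEvent], index: int, params: MelodicParams | None = None
) -> float:
    """Mean pitch of the melodic context preceding ``melody[index]``.

    The context is every melody note starting at or after the barline two
    full measures before the current note's measure and strictly before the
    current note.  If that range holds fewer than 10 notes it is extended
    backwards to the last 10 notes; with no preceding notes at all the
    current pitch is returned (so I1 = 0 for the first note).
    """
    params = params or MelodicParams()
    if not (0 <= index < len(melody)):
        raise IndexError(index)
    note = melody[index]
    window_measure = note.measure - params.window_measures
    context = [
        e
        for i, e in enumerate(melody)
        if i < index and e.measure >= window_measure
    ]
    if len(context) < params.min_context_notes:
        context = list(melody[max(0, index - params.min_context_notes) : index])
    if params.include_current_in_mean:
        context = context + [note]
    if not context:
        return float(note.pitch)
    return sum(e.pitch for e in context) / len(context)


def contour_terms(
    I1: float, I2: float, params: MelodicParams | None = None
) -> tuple[float, float]:
    """The two multiplicative contour terms CS1(I1) and CS2(I2)."""
    params = params or MelodicParams()
    cs1 = I1 if I1 > 0 else params.below_mean_weight * I1
    cs2 = I2 if I2 > 0 else params.falling_interval_weight * I2
    if I1 == 0:
        cs1 = 0.0
    if I2 == 0:
        cs2 = 0.0
    return cs1, cs2


def _stepwise_middle(melody: Sequence[NoteEvent], i: int, max_step: int) -> bool:
    """Is note i the middle of three in same-direction stepwise motion?"""
    if i == 0 or i >= len(melody) - 1:
        return False
    a = melody[i].pitch - melody[i - 1].pitch
    b = melody[i + 1].pitch - melody[i].pitch
    if a == 0 or b == 0:
        return False  # repeated tones break stepwise chains
    if (a > 0) != (b > 0):
        return False
    return abs(a) <= max_step and abs(b) <= max_step


def melodic_saliences(
    melody: Sequence[NoteEvent], params: MelodicParams | None = None
) -> list[float]:
    """Post-processed contour salience CS for each melody note.

    Pruning order: stepwise-middle removal, three-note local-max retention
    (sliding window, ties keep the earliest note), cutoff, saturation.
    """
    params = params or MelodicParams()
    n = len(melody)
    cs = [0.0] * n
    for i in range(1, n):  # first note has no preceding interval
        mean = running_mean_pitch(melody, i, params)
        I1 = melody[i].pitch - mean
        I2 = melody[i].pitch - melody[i - 1].pitch
        cs1, cs2 = contour_terms(I1, I2, params)
        val = cs1 * cs2 / params.N_norm
        if val > 0:
            cs[i] = val
    for i in range(n):
        if cs[i] > 0 and _stepwise_middle(melody, i, params.stepwise_max_semitones):
            cs[i] = 0.0
    for i in range(n - 2):
        window = cs[i : i + 3]
        best = max(window)
        if best <= 0:
            continue
        keep = i + window.index(best)  # earliest on ties
        for j in range(i, i + 3):
            if j != keep:
                cs[j] = 0.0
    for i in range(n):
        if cs[i] < params.cutoff:
            cs[i] = 0.0
        elif cs[i] > params.saturation:
            cs[i] = params.saturation
    return cs


def melodic_accents(
    melody: Sequence[NoteEvent], params: MelodicParams | None = None
):
    """Melodic accent table (column C), one row per melody note."""
    from .score import AccentTable

    params = params or MelodicParams()
    values = melodic_saliences(melody, params)
    table = AccentTable(len(melody), provenance=f"melodic {params}")
    table.set_column("C", values)
    return table
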