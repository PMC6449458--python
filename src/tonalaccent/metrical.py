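"""Metrical accent model: pulse grids and Gaussian pulse salience.

Each time signature implies four pulse trains (metrical levels 0-3, the beat
being level 1).  A note starting on a level's subdivision is marked with that
level.  The perceptual salience of a pulse depends on its physical period P
through a Gaussian in log-period,

    PS(P) = k * exp(-0.5 * ((log P - log M) / log S)**2)

peaking at the preferred period M (default 2 s) with spread S (default 1.65).
The metrical accent of a note is the sum of the saliences of its marked
levels; sums below the cutoff (default 1) are removed for clarity and values
above 5 saturate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .score import AccentTable, SonorityStream

__all__ = [
    "TABLE_LEVELS",
    "PulseGrid",
    "MetricalParams",
    "pulse_grid",
    "pulse_salience",
    "mark_levels",
    "metrical_accents",
]

F = Fraction

#: Notated pulse durations (whole-note units) implied by each supported time
#: signature, for metrical levels 0..3 (level 1 is the beat).
TABLE_LEVELS: dict[tuple[int, int], tuple[Fraction, ...]] = {
    (2, 2): (F(1, 4), F(1, 2), F(2, 2), F(4, 2)),
    (4, 2): (F(1, 4), F(1, 2), F(2, 2), F(4, 2)),
    (2, 4): (F(1, 8), F(1, 4), F(2, 4), F(4, 4)),
    (3, 4): (F(1, 8), F(1, 4), F(3, 4), F(6, 4)),
    (4, 4): (F(1, 8), F(1, 4), F(2, 4), F(4, 4)),
    (3, 8): (F(1, 8), F(3, 8), F(6, 8), F(12, 8)),
    (6, 8): (F(1, 8), F(3, 8), F(6, 8), F(12, 8)),
    (9, 8): (F(1, 8), F(3, 8), F(9, 8), F(18, 8)),
    (12, 8): (F(1, 8), F(3, 8), F(6, 8), F(12, 8)),
}


@dataclass(frozen=True)
class PulseGrid:
    """Four pulse durations (whole notes) and physical periods (seconds)."""

    level_durations: tuple[Fraction, Fraction, Fraction, Fraction]
    level_periods: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        d = self.level_durations
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("level durations must strictly increase")


@dataclass(frozen=True)
class MetricalParams:
    k: float = 1.0
    M: float = 2.0
    S: float = 1.65
    cutoff: float = 1.0
    saturation: float = 5.0
    hypermeter_phase: int = 0  # measures by which level 3 is shifted

    def __post_init__(self) -> None:
        if self.k <= 0 or self.M <= 0:
            raise ValueError("k and M must be positive")
        if self.S <= 1:
            raise ValueError("S must exceed 1")
        if self.cutoff < 0:
            raise ValueError("cutoff must be nonnegative")


def pulse_grid(
    time_signature: tuple[int, int],
    seconds_per_beat: float,
    extension_rule: bool = False,
) -> PulseGrid:
    """Pulse durations and periods implied by a time signature at a tempo.

    Only the nine tabulated signatures are supported unless
    ``extension_rule`` is enabled, which falls back to half-beat / beat /
    measure / two measures for other signatures.
    """
    num, den = time_signature
    if time_signature in TABLE_LEVELS:
        durations = TABLE_LEVELS[time_signature]
    elif extension_rule:
        from .score import beat_duration_wholes

        beat = beat_duration_wholes(num, den)
        measure = Fraction(num, den)
        durations = (beat / 2, beat, measure, 2 * measure)
    else:
        raise ValueError(
            f"unsupported time signature {num}/{den}: supported signatures are "
            f"{sorted(TABLE_LEVELS)}; enable extension_rule or supply an "
            "explicit pulse grid"
        )
    beat_dur = durations[1]
    periods = tuple(float(d / beat_dur) * seconds_per_beat for d in durations)
    return PulseGrid(level_durations=tuple(durations), level_periods=periods)


def pulse_salience(P: float, params: MetricalParams | None = None) -> float:
    """Gaussian (in log period) salience of a single pulse train."""
    params = params or MetricalParams()
    if P <= 0:
        raise ValueError("pulse period must be positive")
    z = (math.log(P) - math.log(params.M)) / math.log(params.S)
    return params.k * math.exp(-0.5 * z * z)


def mark_levels(
    onset: Fraction,
    grid: PulseGrid,
    anchor: Fraction = Fraction(0),
    measure_wholes: Fraction | None = None,
    hypermeter_phase: int = 0,
) -> list[int]:
    """Metrical levels (0..3) whose subdivision grid contains ``onset``.

    Positions are taken relative to the first notated downbeat (``anchor``);
    the hypermetric level 3 may be phase-shifted by whole measures.
    """
    rel = onset - anchor
    marked = []
    for lvl, dur in enumerate(grid.level_durations):
        r = rel
        if lvl == 3 and hypermeter_phase and measure_wholes:
            r = rel - hypermeter_phase * measure_wholes
        if r % dur == 0:
            marked.append(lvl)
    return marked


def metrical_accents(
    stream: SonorityStream,
    grid: PulseGrid,
    params: MetricalParams | None = None,
) -> AccentTable:
    """Metrical accent salience per sonority (column M).

    The salience is the sum of pulse saliences over the marked levels; sums
    below the cutoff are zeroed and values above 5 saturate.
    """
    params = params or MetricalParams()
    table = AccentTable(len(stream), provenance=f"metrical {params}")
    level_sal = [pulse_salience(P, params) for P in grid.level_periods]
    values = []
    for son in stream:
        levels = mark_levels(
            son.onset,
            grid,
            anchor=stream.anchor,
            measure_wholes=stream.measure_wholes,
            hypermeter_phase=params.hypermeter_phase,
        )
        m = sum(level_sal[lvl] for lvl in levels)
        if m < params.cutoff:
            m = 0.0
        values.append(min(m, params.saturation))
    table.set_column("M", values)
    return table
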