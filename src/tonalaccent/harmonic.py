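"""Harmonic accent model: vertical familiarity and horizontal surprise.

*Vertical* harmonic accents treat dissonance as unfamiliarity: every sonority
is classified as a Tn type (a transpositional pitch-class-set class in which
inversionally related sets such as major and minor triads stay distinct) and
looked up in a corpus familiarity table.  The accent is

    Hv = (1 - Tn(h, k) / max[Tn(k)]) ** (Pv**2) * S * d

where the count ratio is the type's corpus frequency relative to the most
frequent type, Pv is a style-dependent coefficient, S = 5 rescales to the
0-5 salience range and d is the scaled duration of the sonority (shortest
notated duration, piecewise scaling below).

*Horizontal* harmonic accents measure surprise as decorrelation between
pitch-class salience profiles of successive sonorities.  A profile assigns
each of the 12 chromas the summed root-support weight of the chord tones
above it, so missing fundamentals (e.g. G under the diminished triad B-D-F)
receive salience.  Profiles of the sonorities inside a one-measure window
before the current one are compared by Pearson correlation, recency-weighted
by w_j = 1/j, and

    Hh = (1 - sum(r_j * w_j) / sum(w_j)) ** Ph * S * d

with d from the longest notated duration.  Negative correlations are clamped
to 0 (a rescale-to-[0,1] variant is available).

Scaled duration (in beats, n_b = beats per bar; d_n halved first at fast
notated tempi):

    d = d_n        if d_n <= 1
    d = sqrt(d_n)  if 1 < d_n < n_b
    d = sqrt(n_b)  if d_n >= n_b

The two components combine either as their maximum (Model 1) or through the
style-parameterized Model 2, which below the vertical threshold x2 adds a
1/x1 share of the horizontal accent to the vertical one (clipped at 5) and
applies the clarity cutoff x3.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .score import AccentTable, Sonority, SonorityStream

__all__ = [
    "TnType",
    "tn_type",
    "FamiliarityTable",
    "StyleParams",
    "STYLE_TABLE",
    "RootSupportWeights",
    "PcSalienceProfile",
    "pc_salience_profile",
    "scaled_duration",
    "vertical_accent",
    "horizontal_accent",
    "combine_harmonic",
    "harmonic_accents",
]

log = logging.getLogger(__name__)

TnType = tuple[int, ...]


def tn_type(pitches: Iterable[int]) -> TnType:
    """Tn type of a set of pitches.

    Pitches are reduced to pitch classes; the normal-order rotation (minimal
    span, ties broken by left packing, i.e. lexicographically smallest) is
    transposed to start at 0.  Inversions are *not* equated: the major triad
    (0,4,7) and minor triad (0,3,7) are distinct types.
    """
    pcs = sorted({p % 12 for p in pitches})
    if not pcs:
        raise ValueError("cannot classify an empty pitch set")
    n = len(pcs)
    best: TnType | None = None
    best_key = None
    for r in range(n):
        rot = [pcs[(r + i) % n] + (12 if r + i >= n else 0) for i in range(n)]
        norm = tuple(x - rot[0] for x in rot)
        key = (norm[-1], norm)
        if best_key is None or key < best_key:
            best_key = key
            best = norm
    assert best is not None
    return best


def _tn_key(t: TnType) -> str:
    return ",".join(str(x) for x in t)


def _tn_from_key(s: str) -> TnType:
    return tuple(int(x) for x in s.split(","))


@dataclass
class FamiliarityTable:
    """Corpus occurrence counts of Tn types, split prepared/unprepared.

    A *prepared* sonority holds at least one tone over from a previous onset;
    an *unprepared* one has all tones struck simultaneously.
    """

    counts: dict[TnType, dict[str, int]] = field(default_factory=dict)
    total_events: int = 0
    provenance: str = ""

    def add(self, t: TnType, prepared: bool, n: int = 1) -> None:
        entry = self.counts.setdefault(t, {"prepared": 0, "unprepared": 0})
        entry["prepared" if prepared else "unprepared"] += n
        self.total_events += n

    def combined(self, t: TnType, mode: str = "both") -> int:
        entry = self.counts.get(t)
        if entry is None:
            return 0
        if mode == "unprepared":
            return entry["unprepared"]
        if mode == "prepared":
            return entry["prepared"]
        return entry["prepared"] + entry["unprepared"]

    def max_combined(self, mode: str = "both") -> int:
        if not self.counts:
            raise ValueError("familiarity table is empty")
        return max(self.combined(t, mode) for t in self.counts)

    def familiarity(self, t: TnType, mode: str = "both") -> float:
        """Occurrence of ``t`` normalized by the most frequent type's count."""
        return self.combined(t, mode) / self.max_combined(mode)

    # -- JSON round trip -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "total_events": self.total_events,
            "provenance": self.provenance,
            "counts": {
                _tn_key(t): dict(entry) for t, entry in sorted(self.counts.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FamiliarityTable":
        payload = json.loads(Path(path).read_text())
        counts = {
            _tn_from_key(k): {
                "prepared": int(v.get("prepared", 0)),
                "unprepared": int(v.get("unprepared", 0)),
            }
            for k, v in payload["counts"].items()
        }
        return cls(
            counts=counts,
            total_events=int(payload["total_events"]),
            provenance=str(payload.get("provenance", "")),
        )


#: Style-dependent harmonic parameters (Pv, Ph, x1, x2, x3).
STYLE_TABLE: dict[str, tuple[float, float, float, float, float]] = {
    "baroque_classical": (2, 2, 5, 0.6, 1),
    "romantic": (2, 2, 4, 0.3, 1),
    "late_romantic": (3, 3, 4, 0.2, 1.5),
}


@dataclass(frozen=True)
class StyleParams:
    P_v: float = 2.0
    P_h: float = 2.0
    x1: float = 4.0
    x2: float = 0.3
    x3: float = 1.0
    S_scale: float = 5.0

    @classmethod
    def for_style(cls, style: str) -> "StyleParams":
        if style not in STYLE_TABLE:
            raise ValueError(f"unknown style {style!r}; expected {sorted(STYLE_TABLE)}")
        pv, ph, x1, x2, x3 = STYLE_TABLE[style]
        return cls(P_v=pv, P_h=ph, x1=x1, x2=x2, x3=x3)


@dataclass(frozen=True)
class RootSupportWeights:
    """Root-support weight per interval (chord tone above a candidate root).

    Defaults support the root itself, its perfect fifth, major third, minor
    seventh and major second/ninth, in decreasing order.  The exact values are
    configurable; they are applied as published intervals of an
    octave-generalized virtual-pitch root-finding scheme.
    """

    weights: Mapping[int, float] = field(
        default_factory=lambda: {0: 10.0, 7: 5.0, 4: 3.0, 10: 2.0, 2: 1.0}
    )

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be nonnegative")
        if w and w.get(0, 0.0) < max(w.values()):
            raise ValueError("weight at interval 0 must be the maximum")

    def vector(self) -> np.ndarray:
        v = np.zeros(12)
        for iv, w in self.weights.items():
            v[iv % 12] = w
        return v


PcSalienceProfile = np.ndarray  # 12 nonnegative reals indexed by pitch class


def pc_salience_profile(
    pitches: Iterable[int], weights: RootSupportWeights | None = None
) -> PcSalienceProfile:
    """Pitch-class salience 12-vector of a sonority.

    sal[p] = sum over chord pitch classes q of weight[(q - p) mod 12], so a
    chroma absent from the chord can still be salient as a missing
    fundamental.
    """
    weights = weights or RootSupportWeights()
    pcs = {p % 12 for p in pitches}
    if not pcs:
        raise ValueError("cannot profile an empty pitch set")
    w = weights.vector()
    sal = np.zeros(12)
    for p in range(12):
        sal[p] = sum(w[(q - p) % 12] for q in pcs)
    return sal


def scaled_duration(d_n: float, n_b: float, fast_tempo: bool = False) -> float:
    """Perceptually scaled duration of a sonority (beats)."""
    d_n = float(d_n)
    n_b = float(n_b)
    if d_n <= 0 or n_b < 1:
        raise ValueError("d_n must be positive and n_b >= 1")
    if fast_tempo:
        d_n = d_n / 2.0
    if d_n <= 1:
        return d_n
    if d_n < n_b:
        return math.sqrt(d_n)
    return math.sqrt(n_b)


def vertical_accent(
    sonority: Sonority,
    table: FamiliarityTable,
    style: StyleParams,
    n_b: float,
    fast_tempo: bool = False,
    count_mode: str = "both",
) -> float:
    """Vertical (familiarity-based) harmonic accent Hv of one sonority."""
    f = table.familiarity(tn_type(sonority.pitches), count_mode)
    d_n = sonority.shortest_duration()
    if d_n <= 0:
        return 0.0
    d = scaled_duration(float(d_n), n_b, fast_tempo)
    return (1.0 - f) ** (style.P_v**2) * style.S_scale * d


def _window_profiles(
    stream: SonorityStream,
    i: int,
    weights: RootSupportWeights,
    window_measures: int,
) -> list[np.ndarray]:
    """Profiles of window sonorities, most recent first."""
    t_i = stream[i].onset
    span = window_measures * stream.measure_wholes
    out = []
    for j in range(i - 1, -1, -1):
        if stream[j].onset < t_i - span:
            break
        out.append(pc_salience_profile(stream[j].pitches, weights))
    return out


def _clamped_correlation(a: np.ndarray, b: np.ndarray, rescale: bool) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        log.warning("degenerate pitch-class profile (zero variance); r set to 0")
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    if rescale:
        return (r + 1.0) / 2.0
    return max(r, 0.0)


def horizontal_accent(
    stream: SonorityStream,
    i: int,
    style: StyleParams,
    weights: RootSupportWeights | None = None,
    half_time_signature: bool = False,
    consonant_passing_tones: bool = False,
    fast_tempo: bool = False,
    rescale_negative: bool = False,
) -> float:
    """Horizontal (surprise-based) harmonic accent Hh of sonority ``i``."""
    if not (0 <= i < len(stream)):
        raise IndexError(i)
    weights = weights or RootSupportWeights()
    window_measures = 2 if half_time_signature else 1
    profiles = _window_profiles(stream, i, weights, window_measures)
    if not profiles:
        return 0.0
    own = pc_salience_profile(stream[i].pitches, weights)
    num = 0.0
    den = 0.0
    for j, prof in enumerate(profiles, start=1):
        w = 1.0 / j
        num += _clamped_correlation(own, prof, rescale_negative) * w
        den += w
    n_b = float(stream.beats_per_measure) * (2 if half_time_signature else 1)
    d_n = float(stream[i].longest_duration())
    if d_n <= 0:
        return 0.0
    if consonant_passing_tones:
        d_n = d_n / 2.0
    d = scaled_duration(d_n, n_b, fast_tempo)
    surprise = 1.0 - num / den
    if surprise < 1e-12:  # exact repetition up to rounding
        return 0.0
    return surprise**style.P_h * style.S_scale * d


def combine_harmonic(
    H_v: float, H_h: float, model: int, style: StyleParams, model1_cutoff: float = 0.0
) -> float:
    """Combined harmonic accent (Model 1: max; Model 2: thresholded blend).

    Model 2 below the vertical threshold x2 returns min(Hv + Hh/x1, 5) so that
    familiar passing chords with a root change are suppressed; values below
    the clarity cutoff x3 are zeroed.  Model 1 applies no cutoff by default.
    Both saturate at 5.
    """
    if H_v < 0 or H_h < 0:
        raise ValueError("component accents must be nonnegative")
    if model == 1:
        h = max(H_v, H_h)
        cutoff = model1_cutoff
    elif model == 2:
        if H_v <= style.x2:
            h = min(H_v + H_h / style.x1, 5.0)
        else:
            h = max(H_v, H_h)
        cutoff = style.x3
    else:
        raise ValueError("model must be 1 or 2")
    if h < cutoff:
        return 0.0
    return min(h, 5.0)


def harmonic_accents(
    stream: SonorityStream,
    table: FamiliarityTable,
    style: StyleParams | str,
    weights: RootSupportWeights | None = None,
    half_time_signature: bool = False,
    consonant_passing_tones: bool = False,
    fast_tempo: bool = False,
    count_mode: str = "both",
    rescale_negative: bool = False,
) -> AccentTable:
    """Hv, Hh, H1 and H2 columns for every sonority of a stream."""
    if isinstance(style, str):
        style = StyleParams.for_style(style)
    weights = weights or RootSupportWeights()
    n_b = float(stream.beats_per_measure) * (2 if half_time_signature else 1)
    hv, hh, h1, h2 = [], [], [], []
    for son in stream:
        v = vertical_accent(son, table, style, n_b, fast_tempo, count_mode)
        h = horizontal_accent(
            stream,
            son.index,
            style,
            weights,
            half_time_signature,
            consonant_passing_tones,
            fast_tempo,
            rescale_negative,
        )
        hv.append(v)
        hh.append(h)
        h1.append(combine_harmonic(v, h, 1, style))
        h2.append(combine_harmonic(v, h, 2, style))
    out = AccentTable(len(stream), provenance=f"harmonic {style}")
    out.set_column("Hv", [min(v, 5.0) for v in hv])
    out.set_column("Hh", [min(v, 5.0) for v in hh])
    out.set_column("H1", h1)
    out.set_column("H2", h2)
    return out
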