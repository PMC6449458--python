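# Methods

This note documents the models implemented by `tonalaccent`, the choices
made where the underlying formulation leaves room, and what the synthetic
fixtures do and do not establish.

## Score representation and sonorities

Score time is kept in exact whole-note rationals (`fractions.Fraction`);
pitches are MIDI integers. A *sonority* is created at every distinct onset
in any voice and contains all pitches sounding at that instant, without any
reduction. Tones held over from earlier onsets make a slice *prepared*;
their notated duration, where a duration is needed, is the remaining
duration from the slice onset. Grace notes (zero notated duration) join
pitch sets but are excluded from all duration computations, keeping d_n
positive. Ties are merged into single logical notes at parse time, so a tied
continuation never creates a sonority of its own.

Beats follow the time-signature denominator except in compound meters
(3/8, 6/8, 9/8, 12/8), where the beat is the dotted quarter. Measures are
1-based; an anacrusis is numbered measure 0 so that measure 1 is the first
complete measure. Tempo resolves as: explicit BPM, else a configurable
tempo-word table (Largo 50 … Presto 180), else 96 BPM. "Fast" tempo (the
duration-halving rule of the harmonic model) means a tempo word in
{Allegretto, Allegro, Vivace, Presto} or, for numeric-only tempi, ≥ 112 BPM
(the Allegretto value of the default word table).

The three notation readers (MusicXML, `**kern`, SMF MIDI types 0/1) are
self-contained implementations of the structural subset needed here —
pitches, durations, voices, chords, ties, grace notes, meter, tempo — not
full-format engines. Engraving and layout information is ignored. The
matching writers serialize one part/spine per voice, splitting notes at
barlines with ties; voices must be internally monophonic or chordal.

## Metrical accents

Four pulse levels per time signature (level 1 = beat, level 3 = two-bar
hypermeter, except 9/8 where level 3 is two measures of 9/8). A sonority is
marked with every level whose subdivision grid contains its onset; the
accent is the sum of the levels' pulse saliences

    PS(P) = k · exp(−0.5 · ((ln P − ln M) / ln S)²)

with defaults k = 1, M = 2 s, S = 1.65. The expression uses a ratio of
logarithms, so the base is immaterial (a property test asserts ln/log10
agreement to 1e-12). Sums below the cutoff (default 1) are zeroed *after*
summation and before the saturation at 5. The base salience k is
configurable; k = 1 makes downbeats in 3/4 at moderate tempi (~60–100 BPM)
exceed the cutoff while beats 2 and 3 (raw ≈ 0.405 at 60 BPM) fall below
it, the intended qualitative behaviour. The hypermetric level anchors at the
first notated downbeat (after any anacrusis), strong measures odd; a phase
offset parameter can shift it by whole measures. Signatures outside the
nine supported ones raise an error by default; an opt-in extension rule
(half-beat / beat / measure / two measures) is available.

## Melodic contour accents

For each melody note, I₁ is the signed distance to the running mean pitch
and I₂ the signed preceding interval. The running-mean window contains the
melody notes from the barline two full measures before the current note's
measure up to (but excluding) the current note; if it holds fewer than 10
notes it is extended backwards to the last 10. The current note is excluded
from its own mean (switchable); the first note of a piece has no preceding
interval and never carries an accent.

CS₁ = I₁ for rises above the mean, 0.7·I₁ below; CS₂ = I₂ for rising
approaches, 0.2·I₂ for falling; CS = CS₁·CS₂ / N with N = 2.5. Only
same-sign products are kept, so a valley scores exactly 0.14 (= 0.7 × 0.2)
of its mirror-image peak. Post-processing happens in a fixed order:
(1) remove the middle note of three in same-direction stepwise motion (both
intervals ≤ 2 semitones; repeated tones break chains), (2) keep only the
largest positive CS within every sliding window of three consecutive notes
(ties keep the earliest note; windows are processed left to right and
zeroing persists), (3) cutoff below 1, (4) saturate at 5.

Melody extraction defaults to the *skyline* (highest newly struck pitch per
onset); a named voice or the highest-labelled voice can be selected instead.
In the full pipeline a melody note's salience is attached to the sonority
sharing its onset.

## Harmonic accents

**Tn classification.** Pitch sets reduce to pitch classes, then to the
normal-order rotation (minimal span, lexicographic tie-break) transposed to
start at 0. Inversionally related sets stay distinct — (0,4,7) ≠ (0,3,7).
A brute-force oracle over all 4095 non-empty pitch-class subsets guards the
implementation.

**Vertical.** Familiarity f of a sonority's Tn type is its count in a
familiarity table divided by the table's maximum count over *all* types (the
most frequent type, no per-cardinality normalizer); prepared and unprepared
counts are summed by default (unprepared-only is available). Then
Hv = (1 − f)^(Pv²) · 5 · d with d the scaled duration of the *shortest*
notated duration in the slice. The exponent squares Pv; the horizontal
exponent Ph is applied unsquared. This asymmetry is kept as the models'
definition.

**Scaled duration.** d = d_n for d_n ≤ 1 beat, √d_n for 1 < d_n < n_b, and
√n_b from one bar upwards; at fast tempi d_n is halved before branching.

**Horizontal.** Each sonority gets a 12-vector pitch-class salience profile,
sal[p] = Σ_q w[(q−p) mod 12] over chord pitch classes q, using
root-support weights {unison 10, fifth 5, major third 3, minor seventh 2,
major second 1}. These weights follow the interval set of octave-generalized
virtual-pitch root finding and are fully configurable, as the exact values
are a modelling choice. Profiles give absent chromas salience (G under
B–D–F), which is the point: root changes move the profile. The accent
compares the current profile with every sonority whose onset lies within the
preceding measure (membership by onset; two measures under the half-time
flag, which also doubles n_b), via Pearson correlations weighted 1/j by
recency rank. Negative correlations clamp to 0 (a rescale-to-[0,1] variant
is provided); zero-variance profiles contribute r = 0 with a warning.
Hh = (1 − Σrw/Σw)^(Ph) · 5 · d with d from the *longest* notated duration,
halved first when the consonant-passing-tones flag is set (a per-piece
manual flag, never auto-detected). The first sonority has Hh = 0. A
residual below 1e-12 in the surprise term (exact repetition up to floating
point) is treated as 0.

**Combination.** Model 1: H₁ = max(Hv, Hh), no cutoff by default. Model 2:
for Hv ≤ x₂, H₂ = min(Hv + Hh/x₁, 5) — the clip at 5 implements the
saturation rule, which a literal outer `max(…, 5)` would contradict — else
the maximum; H₂ < x₃ is zeroed. Both saturate at 5, as do the stored Hv/Hh
columns. Style parameter sets: Baroque–Classical (2, 2, 5, 0.6, 1),
Romantic (2, 2, 4, 0.3, 1), Late-Romantic (3, 3, 4, 0.2, 1.5).

## Corpus statistics

`corpus_stats` classifies every slice of every piece by Tn type and
preparedness (unprepared = all tones struck simultaneously) and aggregates
counts order-independently; unreadable files are logged and skipped. Single
notes and dyads are counted — the vertical model's cardinality range is
1–12 — although percentage plots usually show cardinalities 3–5.
Percentages divide by the total event count over all cardinalities
(per-cardinality normalization behind a flag). Repeats are not expanded;
scores count as encoded.

## Evaluation machinery

Raters × notes matrices per category, zeros for unmarked notes, over the
full sonority universe. Agreement = mean (and range of) Pearson r over all
rater pairs; all-zero raters are excluded pairwise with a warning.
Categories combine by element-wise maximum (MC, CH, MCH), identically for
ratings and model output. The m-consensus keeps, per note, the mean of the
*nonzero* (marking) raters' values wherever at least m raters marked; the
model is correlated with the consensus over a grid of m and the best
(r, m) reported, ties preferring the smallest m. Correlations are computed
over the concatenated note universe of the pieces being evaluated.

## Synthetic fixtures: what they show

All fixtures are deterministic functions of a seed and emit ground truth
beside the score. The metrical grids, controlled melodies and template
progressions exercise exactly the code paths of the three models; the
rating generator produces raters as rounded, clipped, noisy copies of a
truth vector with independent dropout. The bundled familiarity table comes
from a generated 200-slice corpus whose template mix makes the major triad
the most frequent type; it reproduces the *rank shape* a tonal piano corpus
would give, not real corpus statistics, and is labelled synthetic. Building
a real table from a kern corpus with `corpus-count` is supported and
recommended for substantive analyses.

The Prelude Op. 28 No. 7 skeleton encodes only documented melodic facts of
the piece (meter, accent pitches, the leap into each accent, the m.6 valley,
m.9 = m.1, the m.11 climax); the filler notes between them are free and were
chosen so that the documented qualitative orderings of the contour accents
emerge under default parameters — in particular the m.3 A5 accent stays
below saturation, without which order comparisons would be vacuous. Passing
these checks shows the model reproduces the documented orderings on a
melody with those interval facts; it does not validate the model against
the full piece or against human ratings.

Because rating fixtures are noisy copies of model output, evaluation tests
demonstrate the *machinery* (consensus beats mean individual correlation,
improves with rater count) under a known generative model — not that human
raters behave this way.

## Problem sizes and numerics

Default test and acceptance runs use small problems (50-sonority skeleton,
45-slice corpora, 400-note rating matrices, 100 random chord sequences for
the correlation oracle), chosen to pin down the arithmetic exactly; all
deterministic checks use exact rational score time and double precision.
File output rounds saliences to six decimals. Known limitations: octave
register, spacing and doubling are ignored by the Tn representation; meter
is taken from the notation (no meter induction); melodic accents assume a
single extractable line; style must be declared by the user.
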