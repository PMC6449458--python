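# tonalaccent

Automatic analysis of **immanent accents** in tonal music: score-inherent
events — metrical, melodic-contour and harmonic — that attract a listener's
attention, each predicted with a perceptual salience on a 0–5 scale.
The package is aimed at computational musicologists and researchers in music
cognition and expressive performance who need reproducible, parameterized
accent annotations of symbolic scores (MusicXML, Humdrum `**kern`, MIDI).

## The model

A score is sliced into **sonorities** — one chord slice at every onset in any
voice, with no reduction — and each sonority receives six salience values:

* **Metrical (M).** Each time signature implies four pulse levels (level 1 is
  the beat; level 3 is a two-bar hypermeter). A pulse with physical period
  *P* (seconds) has salience

  `PS = k · exp(−½ ((log P − log M) / log S)²)`

  with preferred period *M* = 2 s and spread *S* = 1.65, so pulses near
  ~60 events/min are most salient. A note's metrical accent is the sum over
  the levels it starts on; sums below 1 are removed.

* **Melodic contour (C).** Two multiplicative factors: the distance *I₁* of
  the note from a running mean pitch (the window reaching back to the barline
  two measures earlier, extended to the last 10 notes when sparse), and the
  preceding interval *I₂*, both in semitones:

  `CS₁ = I₁ (I₁>0) or 0.7·I₁;  CS₂ = I₂ (I₂>0) or 0.2·I₂;  CS = CS₁·CS₂ / 2.5`

  Only same-sign configurations (peak-after-rise, valley-after-fall) score
  positively; stepwise middle notes are pruned, only the largest of any three
  consecutive saliences is kept, values < 1 are dropped and values > 5
  saturate.

* **Harmonic vertical (Hv)** — dissonance as *unfamiliarity*. Sonorities are
  classified as Tn types (transpositional pitch-class-set classes where major
  (0,4,7) and minor (0,3,7) remain distinct) and looked up in a corpus count
  table: `Hv = (1 − Tn(h,k)/max Tn)^(Pv²) · 5 · d`, with *d* a piecewise
  scaled duration (√-compressed above one beat, capped at √n_b).

* **Harmonic horizontal (Hh)** — *surprise* as decorrelation of pitch-class
  salience profiles (virtual-pitch root-support weights, so missing
  fundamentals count) between the current sonority and the sonorities of the
  preceding measure, recency-weighted by 1/j:
  `Hh = (1 − Σ rⱼwⱼ/Σ wⱼ)^(Ph) · 5 · d`.

* **Combined (H1, H2).** Model 1 takes `max(Hv, Hh)`. Model 2 blends below a
  style threshold: for `Hv ≤ x₂`, `H₂ = min(Hv + Hh/x₁, 5)` (suppressing
  familiar passing chords that merely change root), else the maximum; values
  below the style cutoff x₃ are dropped. Style parameter sets
  (Pv, Ph, x₁, x₂, x₃) are provided for Baroque–Classical (2, 2, 5, 0.6, 1),
  Romantic (2, 2, 4, 0.3, 1) and Late-Romantic (3, 3, 4, 0.2, 1.5) music.

An evaluation module implements the matching agreement machinery for human
accent marks: pairwise Pearson correlations between raters, category
combination by element-wise maximum, and the *m*-consensus (per-note mean of
marking raters where at least *m* raters marked, correlated with the model
over a grid of *m*).

## Worked example

The bundled fixture module generates a melodic skeleton of Chopin's Prelude
Op. 28 No. 7 (3/4, Andantino; synthetic filler between documented accent
points):

```bash
tonalaccent fixtures make prelude7_skeleton --out demo
tonalaccent analyze demo/prelude7_skeleton.krn --out demo/accents.csv
```

prints `wrote demo/accents.csv and demo/accents.json (50 sonorities)`, and
the CSV begins (columns: index, measure, beat, onset, pitches, then the six
saliences):

```
sonority_index,measure,beat,onset_wholes,pitches,M,C,Hv,Hh,H1,H2
1,1,1,1/4,73,1.392862,5.000000,0.774978,5.000000,5.000000,5.000000
...
8,2,3,3/2,78,0.000000,5.000000,0.387489,2.089988,2.089988,2.089988
14,3,2,2,81,0.000000,4.615385,1.095984,5.000000,5.000000,5.000000
23,6,3,9/2,64,0.000000,5.000000,0.774978,4.221618,4.221618,4.221618
```

Reading the C column: the m.1 C♯5 after its rising major sixth saturates at
5; the m.2 F♯5 reached by a perfect fifth (5.0) outranks the m.3 A5 reached
by the smaller perfect fourth (4.615); the m.6 E4 is an accented contour
valley. Downbeats carry metrical accents ≈ 1.12–1.39 at the Andantino tempo
while other beats fall below the cutoff, and harmonic accents respond to the
unfamiliarity and profile changes of the synthetic-default familiarity table
(pass `--familiarity` to use corpus statistics built with
`tonalaccent corpus-count`).

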