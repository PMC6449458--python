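"""Tn classification, scaled duration, vertical/horizontal accents, combining."""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

import tonalaccent as ta
from tonalaccent.fixtures import generate_progression
from tonalaccent.harmonic import (
    FamiliarityTable,
    RootSupportWeights,
    StyleParams,
    combine_harmonic,
    harmonic_accents,
    horizontal_accent,
    pc_salience_profile,
    scaled_duration,
    tn_type,
    vertical_accent,
)

F = Fraction


# -- Tn types ---------------------------------------------------------------


def oracle_tn(pcs: frozenset[int]) -> tuple[int, ...]:
    """Brute force: best rotation by (span, lexicographic), start at 0."""
    pcs_sorted = sorted(pcs)
    n = len(pcs_sorted)
    candidates = []
    for r in range(n):
        rot = pcs_sorted[r:] + [p + 12 for p in pcs_sorted[:r]]
        norm = tuple(x - rot[0] for x in rot)
        candidates.append(norm)
    return min(candidates, key=lambda c: (c[-1], c))


def test_tn_type_paper_triads():
    assert tn_type({60, 64, 67}) == (0, 4, 7)  # major
    assert tn_type({62, 65, 69}) == (0, 3, 7)  # minor
    assert tn_type({71, 62, 65}) == (0, 3, 6)  # diminished
    assert tn_type({60, 64, 67}) != tn_type({60, 63, 67})


def test_tn_type_matches_oracle_on_all_subsets():
    for bits in range(1, 4096):
        pcs = frozenset(i for i in range(12) if bits >> i & 1)
        assert tn_type(pcs) == oracle_tn(pcs), pcs


def test_tn_type_transposition_invariance():
    rng = np.random.default_rng(5)
    for _ in range(200):
        pcs = set(rng.choice(12, size=rng.integers(1, 7), replace=False).tolist())
        shift = int(rng.integers(1, 12))
        assert tn_type(pcs) == tn_type({(p + shift) % 12 for p in pcs})


def test_tn_type_rejects_empty_set():
    with pytest.raises(ValueError):
        tn_type(set())


# -- scaled duration ---------------------------------------------------------


@pytest.mark.parametrize(
    "d_n,n_b,fast,expected",
    [
        (0.5, 3, False, 0.5),
        (1.0, 3, False, 1.0),
        (2.0, 3, False, math.sqrt(2)),
        (4.0, 3, False, math.sqrt(3)),
        (3.0, 3, False, math.sqrt(3)),
        # fast tempo halves the notated duration before branching
        (1.0, 3, True, 0.5),
        (4.0, 3, True, math.sqrt(2)),
        (8.0, 3, True, math.sqrt(3)),
    ],
)
def test_scaled_duration_piecewise(d_n, n_b, fast, expected):
    assert scaled_duration(d_n, n_b, fast) == pytest.approx(expected, abs=1e-9)


def test_scaled_duration_rejects_bad_inputs():
    with pytest.raises(ValueError):
        scaled_duration(0, 3)
    with pytest.raises(ValueError):
        scaled_duration(1, 0.5)


# -- vertical accents --------------------------------------------------------


def _table(counts):
    t = FamiliarityTable()
    for tn, n in counts.items():
        t.add(tn, prepared=False, n=n)
    return t


def _sonority(pitches, d_beats=F(1), index=0, new=None):
    from tonalaccent.score import Sonority

    return Sonority(
        index=index,
        onset=F(0),
        pitches=frozenset(pitches),
        new_pitches=frozenset(new or pitches),
        notated_durations={p: d_beats for p in pitches},
        measure=1,
        beat_in_measure=F(1),
    )


def test_most_frequent_type_has_zero_vertical_accent():
    table = _table({(0, 4, 7): 10, (0, 3, 7): 5})
    style = StyleParams.for_style("romantic")
    assert vertical_accent(_sonority({60, 64, 67}), table, style, 4) == 0.0


def test_vertical_accent_worked_value_at_half_familiarity():
    # f = 0.5, Pv = 2, d = 1 -> 0.5**4 * 5 = 0.3125
    table = _table({(0, 4, 7): 10, (0, 3, 7): 5})
    style = StyleParams.for_style("romantic")
    hv = vertical_accent(_sonority({60, 63, 67}), table, style, 4)
    assert hv == pytest.approx(0.3125, abs=1e-12)


def test_unseen_cluster_gets_full_scale():
    table = _table({(0, 4, 7): 10})
    style = StyleParams.for_style("romantic")
    hv = vertical_accent(_sonority({60, 61, 62}), table, style, 4)
    assert hv == pytest.approx(5.0)


def test_vertical_uses_shortest_notated_duration():
    from tonalaccent.score import Sonority

    table = _table({(0, 4, 7): 10, (0, 3, 7): 5})
    style = StyleParams.for_style("romantic")
    son = Sonority(
        index=0,
        onset=F(0),
        pitches=frozenset({60, 63, 67}),
        new_pitches=frozenset({60, 63, 67}),
        notated_durations={60: F(4), 63: F(1, 2), 67: F(1)},
        measure=1,
        beat_in_measure=F(1),
    )
    assert vertical_accent(son, table, style, 4) == pytest.approx(0.3125 * 0.5)


def test_vertical_monotone_in_familiarity_and_pv():
    style2 = StyleParams(P_v=2)
    style3 = StyleParams(P_v=3)
    table = _table({(0, 4, 7): 10, (0, 3, 7): 6, (0, 3, 6): 2})
    hv_rare = vertical_accent(_sonority({60, 63, 66}), table, style2, 4)
    hv_mid = vertical_accent(_sonority({60, 63, 67}), table, style2, 4)
    assert hv_rare > hv_mid
    # for fixed f in (0,1), larger Pv shrinks the accent
    assert vertical_accent(_sonority({60, 63, 67}), table, style3, 4) < hv_mid


# -- pitch-class salience profiles -------------------------------------------


def test_profile_major_triad_root_strictly_maximal():
    sal = pc_salience_profile({60, 64, 67})
    assert sal[0] == 18.0 and sal[4] == 10.0 and sal[7] == 10.0
    assert np.argmax(sal) == 0 and np.sum(sal == sal.max()) == 1


def test_profile_missing_fundamental_of_diminished_triad():
    sal = pc_salience_profile({71, 62, 65})  # B D F
    assert sal[7] == 10.0  # G, absent from the chord


def test_profile_single_pitch_class_weight_layout():
    sal = pc_salience_profile({60})
    assert sal[0] == 10.0 and sal[5] == 5.0 and sal[8] == 3.0
    assert sal[2] == 2.0 and sal[10] == 1.0
    assert all(sal[i] == 0.0 for i in (1, 3, 4, 6, 7, 9, 11))


def test_weights_must_peak_at_unison():
    with pytest.raises(ValueError):
        RootSupportWeights({0: 1.0, 7: 5.0})


# -- horizontal accents ------------------------------------------------------


def _chord_stream(chord_list, d_beats=1.0):
    from tonalaccent.score import NoteEvent, Score, TimeSignature, renumber_events

    beat = F(1, 4)
    events = []
    t = F(0)
    d = F(d_beats).limit_denominator(16) * beat
    for pitches in chord_list:
        for v, p in enumerate(sorted(pitches)):
            events.append(
                NoteEvent(pitch=p, onset=t, duration_wholes=d, voice_id=f"v{v}")
            )
        t += d
    score = Score(
        events=events, time_signatures=[TimeSignature(F(0), 4, 4)], tempo_bpm=96
    )
    return ta.chordify(renumber_events(score))


def test_repeated_chord_has_zero_horizontal_accent():
    stream = _chord_stream([{60, 64, 67}] * 4)
    style = StyleParams.for_style("romantic")
    assert horizontal_accent(stream, 3, style) == 0.0


def test_first_sonority_has_zero_horizontal_accent():
    stream = _chord_stream([{60, 64, 67}, {61, 65, 68}])
    style = StyleParams.for_style("romantic")
    assert horizontal_accent(stream, 0, style) == 0.0


def test_horizontal_against_independent_oracle():
    """Windowed weighted-correlation oracle over random chord sequences."""
    rng = np.random.default_rng(11)
    style = StyleParams.for_style("romantic")
    weights = RootSupportWeights()
    for _ in range(100):
        n = int(rng.integers(3, 9))
        chords = [
            frozenset(rng.choice(range(48, 84), size=rng.integers(2, 5), replace=False).tolist())
            for _ in range(n)
        ]
        stream = _chord_stream(chords, d_beats=1.0)
        i = n - 1
        got = horizontal_accent(stream, i, style, weights)
        # oracle: profiles via the weight table, scipy Pearson, 1/j weights
        t_i = stream[i].onset
        window = [
            j for j in range(i - 1, -1, -1) if stream[j].onset >= t_i - F(1)
        ]
        own = pc_salience_profile(stream[i].pitches, weights)
        num = den = 0.0
        for rank, j in enumerate(window, start=1):
            other = pc_salience_profile(stream[j].pitches, weights)
            if np.std(own) == 0 or np.std(other) == 0:
                r = 0.0
            else:
                r = stats.pearsonr(own, other).statistic
            num += max(r, 0.0) / rank
            den += 1.0 / rank
        d = scaled_duration(float(stream[i].longest_duration()), 4)
        expected = (1 - num / den) ** style.P_h * 5 * d
        assert got == pytest.approx(expected, abs=1e-10)


def test_stream_transposition_leaves_harmonic_columns_unchanged(familiarity):
    score, _ = generate_progression(seed=11, n_slices=10)
    shifted = score.transposed(3)
    style = StyleParams.for_style("romantic")
    t1 = harmonic_accents(ta.chordify(score), familiarity, style)
    t2 = harmonic_accents(ta.chordify(shifted), familiarity, style)
    for col in ("Hv", "Hh", "H1", "H2"):
        assert t1.column(col) == pytest.approx(t2.column(col), abs=1e-12)


# -- combining ---------------------------------------------------------------


def test_model1_takes_the_maximum():
    style = StyleParams.for_style("romantic")
    assert combine_harmonic(2.0, 3.0, 1, style) == 3.0
    assert combine_harmonic(3.0, 2.0, 1, style) == 3.0


def test_model2_romantic_worked_example():
    style = StyleParams.for_style("romantic")  # x1=4, x2=0.3, x3=1
    # Hv=0.2 <= x2: 0.2 + 2/4 = 0.7 < x3 -> cut to 0
    assert combine_harmonic(0.2, 2.0, 2, style) == 0.0
    # Hv=0.5 > x2: plain maximum
    assert combine_harmonic(0.5, 2.0, 2, style) == 2.0


def test_model2_branch_switch_at_threshold():
    style = StyleParams.for_style("baroque_classical")  # x1=5, x2=0.6, x3=1
    at = combine_harmonic(0.6, 4.0, 2, style)  # on the threshold: blended
    above = combine_harmonic(0.6 + 1e-9, 4.0, 2, style)  # just above: max
    assert at == pytest.approx(0.6 + 4.0 / 5)
    assert above == pytest.approx(4.0)


def test_model2_suppresses_familiar_root_changes():
    """H2 <= H1 whenever Hv <= x2, x1 >= 2 and Hh >= 2 Hv (parameter sweep)."""
    for style_name in ("baroque_classical", "romantic", "late_romantic"):
        style = StyleParams.for_style(style_name)
        for hv in np.linspace(0, style.x2, 7):
            for hh in np.linspace(2 * hv, 5, 7):
                h1 = combine_harmonic(hv, hh, 1, style)
                h2 = combine_harmonic(hv, hh, 2, style)
                assert h2 <= h1 + 1e-12


def test_combined_saturates_at_five():
    style = StyleParams(x1=1.0, x2=10.0, x3=0.0)
    assert combine_harmonic(4.0, 4.0, 2, style) == 5.0


# -- full-stream wiring ------------------------------------------------------


def test_repeated_single_note_has_no_harmonic_accent():
    table = _table({(0,): 50, (0, 4, 7): 10})
    stream = _chord_stream([{60}] * 4)
    out = harmonic_accents(stream, table, StyleParams.for_style("romantic"))
    assert out.column("Hv") == [0.0] * 4
    assert out.column("Hh") == [0.0] * 4
    assert out.column("H1") == [0.0] * 4
    assert out.column("H2") == [0.0] * 4


def test_single_sonority_piece(familiarity):
    stream = _chord_stream([{60, 63, 66}])
    style = StyleParams.for_style("romantic")
    out = harmonic_accents(stream, familiarity, style)
    assert out.column("Hh") == [0.0]
    expected = vertical_accent(stream[0], familiarity, style, 4)
    assert out.column("Hv")[0] == pytest.approx(min(expected, 5.0))


def test_harmonic_columns_match_elementwise_recomputation(familiarity):
    score, _ = generate_progression(seed=11, n_slices=12)
    stream = ta.chordify(score)
    style = StyleParams.for_style("romantic")
    out = harmonic_accents(stream, familiarity, style)
    n_b = float(stream.beats_per_measure)
    for son in stream:
        hv = vertical_accent(son, familiarity, style, n_b)
        hh = horizontal_accent(stream, son.index, style)
        assert out.column("Hv")[son.index] == pytest.approx(min(hv, 5.0))
        assert out.column("Hh")[son.index] == pytest.approx(min(hh, 5.0))
        assert out.column("H1")[son.index] == combine_harmonic(hv, hh, 1, style)
        assert out.column("H2")[son.index] == combine_harmonic(hv, hh, 2, style)
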