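"""End-to-end pipeline: score in, combined accent table out."""

from __future__ import annotations

from dataclasses import dataclass, field

from .harmonic import (
    FamiliarityTable,
    RootSupportWeights,
    StyleParams,
    harmonic_accents,
)
from .melodic import MelodicParams, melodic_saliences
from .metrical import MetricalParams, metrical_accents, pulse_grid
from .score import AccentTable, Score, SonorityStream, chordify, extract_melody, is_fast_tempo

__all__ = ["AnalysisConfig", "analyze_score"]


@dataclass
class AnalysisConfig:
    metrical: MetricalParams = field(default_factory=MetricalParams)
    melodic: MelodicParams = field(default_factory=MelodicParams)
    style: StyleParams | None = None  # defaults to the score's style class
    weights: RootSupportWeights = field(default_factory=RootSupportWeights)
    melody_strategy: str = "skyline"
    melody_voice: str | None = None
    count_mode: str = "both"
    rescale_negative: bool = False
    tempo_words: dict[str, float] | None = None
    grid_extension_rule: bool = False

    def describe(self) -> str:
        style = self.style
        return (
            f"metrical(k={self.metrical.k}, M={self.metrical.M}, "
            f"S={self.metrical.S}, cutoff={self.metrical.cutoff}) "
            f"melodic(N={self.melodic.N_norm}, cutoff={self.melodic.cutoff}) "
            f"style({style}) melody={self.melody_strategy}"
        )


def analyze_score(
    score: Score,
    familiarity: FamiliarityTable,
    config: AnalysisConfig | None = None,
) -> tuple[SonorityStream, AccentTable]:
    """Compute all six accent columns for one score.

    Metrical and harmonic accents live on sonorities directly; melodic
    contour saliences are computed on the extracted melody and attached to
    the sonority sharing the melody note's onset.
    """
    config = config or AnalysisConfig()
    stream = chordify(score, config.tempo_words)
    sig = score.time_signatures[0]
    grid = pulse_grid(
        (sig.numerator, sig.denominator),
        stream.seconds_per_beat,
        extension_rule=config.grid_extension_rule,
    )
    table = AccentTable(len(stream), provenance=config.describe())
    table.set_column("M", metrical_accents(stream, grid, config.metrical).column("M"))

    melody = extract_melody(score, config.melody_strategy, config.melody_voice)
    cs = melodic_saliences(melody, config.melodic)
    onset_to_idx = {s.onset: s.index for s in stream}
    c_col = [0.0] * len(stream)
    for note, val in zip(melody, cs):
        if val > 0 and note.onset in onset_to_idx:
            c_col[onset_to_idx[note.onset]] = val
    table.set_column("C", c_col)

    style = config.style or StyleParams.for_style(score.style)
    harm = harmonic_accents(
        stream,
        familiarity,
        style,
        weights=config.weights,
        half_time_signature=score.half_time_signature,
        consonant_passing_tones=score.consonant_passing_tones,
        fast_tempo=is_fast_tempo(score),
        count_mode=config.count_mode,
        rescale_negative=config.rescale_negative,
    )
    for col in ("Hv", "Hh", "H1", "H2"):
        table.set_column(col, harm.column(col))
    return stream, table
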