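"""Corpus Tn-type statistics: building familiarity tables from score files.

Every piece is sliced into sonorities (no reduction; one slice per onset in
any voice), each slice is classified by Tn type and by preparedness
(unprepared = all tones struck simultaneously, prepared = at least one tone
held over), and counts are aggregated into a familiarity table usable by the
vertical harmonic accent model.  Single notes and dyads are counted alongside
larger chords.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .harmonic import FamiliarityTable, TnType, tn_type
from .score import Score, Sonority, chordify

__all__ = [
    "CorpusSummary",
    "classify_preparedness",
    "count_corpus",
    "count_scores",
    "to_percentages",
]

log = logging.getLogger(__name__)


@dataclass
class CorpusSummary:
    n_pieces: int
    n_events: int
    per_cardinality: dict[int, int]
    table: FamiliarityTable
    n_warnings: int = 0


def classify_preparedness(sonority: Sonority) -> str:
    """'unprepared' when all tones onset at the slice, else 'prepared'."""
    return "prepared" if sonority.prepared else "unprepared"


def count_scores(scores: Iterable[Score], provenance: str = "") -> CorpusSummary:
    """Aggregate Tn-type counts over already parsed scores."""
    table = FamiliarityTable(provenance=provenance)
    per_card: dict[int, int] = {}
    n_pieces = 0
    for score in scores:
        n_pieces += 1
        for son in chordify(score):
            t = tn_type(son.pitches)
            table.add(t, prepared=son.prepared)
            per_card[len(t)] = per_card.get(len(t), 0) + 1
    return CorpusSummary(
        n_pieces=n_pieces,
        n_events=table.total_events,
        per_cardinality=per_card,
        table=table,
    )


def count_corpus(paths: Sequence[str | Path]) -> CorpusSummary:
    """Count Tn types over a corpus of score files.

    Unreadable pieces are logged and skipped; their number is reported in the
    summary's warning count.  Aggregation is independent of file order.
    """
    from .io import read_score

    if not paths:
        raise ValueError("corpus must contain at least one score file")
    scores = []
    warnings = 0
    for p in sorted(str(x) for x in paths):
        try:
            scores.append(read_score(p))
        except Exception as exc:  # noqa: BLE001 - skip-and-log is the contract
            log.warning("skipping unreadable piece %s: %s", p, exc)
            warnings += 1
    if not scores:
        raise ValueError("no readable score in corpus")
    summary = count_scores(scores, provenance=f"corpus of {len(scores)} files")
    summary.n_warnings = warnings
    return summary


def to_percentages(
    summary: CorpusSummary, cardinality: int, per_cardinality: bool = False
) -> dict[TnType, float]:
    """Occurrence of each Tn type of one cardinality, as percentages.

    The denominator is the total number of counted sonorities over all
    cardinalities (the corpus-wide event count); ``per_cardinality`` switches
    to normalizing within the requested cardinality only.
    """
    if summary.n_events == 0:
        raise ValueError("empty corpus summary")
    if per_cardinality:
        denom = summary.per_cardinality.get(cardinality, 0)
        if denom == 0:
            return {}
    else:
        denom = summary.n_events
    out = {}
    for t in summary.table.counts:
        if len(t) == cardinality:
            out[t] = 100.0 * summary.table.combined(t) / denom
    return out
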