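"""Accent table serialization (CSV and JSON).

The CSV dialect has exactly the columns
``sonority_index, measure, beat, onset_wholes, pitches, M, C, Hv, Hh, H1, H2``
with pitches as space-separated MIDI integers, exact rational strings for
onset and beat, and saliences printed to six decimal places so that a
write-read round trip reproduces the table.
"""

from __future__ import annotations

import csv
import json
from fractions import Fraction
from pathlib import Path

from ..score import ACCENT_COLUMNS, AccentTable, SonorityStream

__all__ = ["write_accent_table", "read_accent_table"]

_FIELDS = ["sonority_index", "measure", "beat", "onset_wholes", "pitches", *ACCENT_COLUMNS]


def _rows(table: AccentTable, stream: SonorityStream) -> list[dict]:
    if len(table) != len(stream):
        raise ValueError(
            f"accent table ({len(table)} rows) and sonority stream "
            f"({len(stream)} slices) are not index-aligned"
        )
    rows = []
    for son, accents in zip(stream, table.rows()):
        row = {
            "sonority_index": son.index,
            "measure": son.measure,
            "beat": str(son.beat_in_measure),
            "onset_wholes": str(son.onset),
            "pitches": " ".join(str(p) for p in sorted(son.pitches)),
        }
        row.update({c: f"{accents[c]:.6f}" for c in ACCENT_COLUMNS})
        rows.append(row)
    return rows


def write_accent_table(
    table: AccentTable,
    stream: SonorityStream,
    path: str | Path,
    format: str = "csv",
) -> None:
    rows = _rows(table, stream)
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS, lineterminator="\n")
            writer.writeheader()
            writer.writerows(rows)
    elif format == "json":
        payload = {"provenance": table.provenance, "rows": rows}
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown accent table format {format!r}")


def read_accent_table(path: str | Path, format: str | None = None) -> tuple[list[dict], AccentTable]:
    """Read back an accent table file; returns (context rows, AccentTable)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv"
    if format == "csv":
        with path.open() as fh:
            raw = list(csv.DictReader(fh))
    else:
        raw = json.loads(path.read_text())["rows"]
    table = AccentTable(len(raw))
    for col in ACCENT_COLUMNS:
        table.set_column(col, [float(r[col]) for r in raw])
    context = [
        {
            "sonority_index": int(r["sonority_index"]),
            "measure": int(r["measure"]),
            "beat": Fraction(r["beat"]),
            "onset_wholes": Fraction(r["onset_wholes"]),
            "pitches": frozenset(int(p) for p in str(r["pitches"]).split()),
        }
        for r in raw
    ]
    return context, table
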