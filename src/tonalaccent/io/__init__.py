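"""Score file I/O: format dispatch plus the individual format modules."""

from __future__ import annotations

from pathlib import Path

from ..score import Score
from .kern import read_kern, write_kern
from .midi import read_midi, write_midi
from .musicxml import read_musicxml, write_musicxml
from .tables import read_accent_table, write_accent_table

__all__ = [
    "read_score",
    "read_musicxml",
    "write_musicxml",
    "read_kern",
    "write_kern",
    "read_midi",
    "write_midi",
    "read_accent_table",
    "write_accent_table",
]

_EXTENSIONS = {
    ".musicxml": "musicxml",
    ".xml": "musicxml",
    ".krn": "kern",
    ".kern": "kern",
    ".mid": "midi",
    ".midi": "midi",
}


def read_score(path: str | Path, format: str = "auto") -> Score:
    """Parse a symbolic score file (MusicXML, Humdrum kern, or SMF MIDI).

    With ``format='auto'`` the file extension decides; unknown extensions are
    sniffed (MThd header = MIDI, '<' start = MusicXML, else kern).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt == "auto":
        fmt = _EXTENSIONS.get(path.suffix.lower(), "")
        if not fmt:
            head = path.read_bytes()[:4]
            if head == b"MThd":
                fmt = "midi"
            elif head.startswith(b"<"):
                fmt = "musicxml"
            else:
                fmt = "kern"
    if fmt == "musicxml":
        return read_musicxml(path)
    if fmt == "kern":
        return read_kern(path)
    if fmt == "midi":
        return read_midi(path)
    raise ValueError(f"unknown score format {format!r}")
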