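"""TSV/JSON report writers with fixed column order.

Every TSV written by the package has a JSON mirror (same rows, same keys) so
downstream tooling can consume either.  User-facing coordinates are 1-based
inclusive; the helpers here do not convert — callers pass display values.
"""

from __future__ import annotations

import json
from pathlib import Path


def write_tsv(path, columns: list[str], rows: list[dict]) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_cell(row.get(c)) for c in columns) + "\n")


def write_json(path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_report(prefix, columns: list[str], rows: list[dict]) -> None:
    """Write ``<prefix>.tsv`` and its JSON mirror ``<prefix>.json``."""
    prefix = Path(prefix)
    write_tsv(prefix.with_suffix(".tsv"), columns, rows)
    write_json(prefix.with_suffix(".json"), rows)


def _cell(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def to_display_interval(iv: tuple[int, int], seqlen: int) -> str:
    """0-based half-open -> 1-based inclusive 'start-end' (wrap-aware)."""
    start, end = iv
    if end <= start:
        end += seqlen
    return f"{start + 1}-{end}"
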