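"""Loaders for the packaged plain-text data tables.

All tables are TSV files with ``#`` comment lines; keys are upper-cased on
load so lookups are case-insensitive.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def _iter_rows(name_or_path: str | Path, package_file: bool) -> list[list[str]]:
    if package_file:
        text = (resources.files("yappis.data") / str(name_or_path)).read_text()
    else:
        text = Path(name_or_path).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_table(name_or_path: str | Path, *, packaged: bool = True) -> dict[str, float]:
    """Read a two-column ``key<TAB>value`` TSV into a dict of floats."""
    out: dict[str, float] = {}
    for row in _iter_rows(name_or_path, packaged):
        if len(row) < 2:
            raise ValueError(f"malformed table row: {row!r}")
        out[row[0].upper()] = float(row[1])
    return out


def load_columns(name_or_path: str | Path, ncol: int, *, packaged: bool = True) -> dict[str, tuple[float, ...]]:
    """Read a ``key<TAB>v1<TAB>...<TAB>v{ncol}`` TSV into a dict of tuples."""
    out: dict[str, tuple[float, ...]] = {}
    for row in _iter_rows(name_or_path, packaged):
        if len(row) < ncol + 1:
            raise ValueError(f"malformed table row: {row!r}")
        out[row[0].upper()] = tuple(float(v) for v in row[1 : ncol + 1])
    return out
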