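"""Result emitters: commented-header CSV and JSON-lines episode logs.

Data files carry their provenance in ``#``-prefixed header lines (tool
version, seed, config hash) so that any output can be traced back to
the run that produced it; numeric columns are written with 12
significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__

__all__ = ["emit_csv", "read_emitted_csv", "emit_jsonl"]

FLOAT_FORMAT = "%.12g"


def _header_lines(metadata: Mapping[str, object] | None) -> str:
    lines = [f"# tool: partnerchoice {__version__}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def emit_csv(
    frame: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a DataFrame as CSV with a commented metadata header."""
    path = Path(path)
    try:
        with path.open("w") as fh:
            fh.write(_header_lines(metadata))
            frame.to_csv(fh, index=False, float_format=FLOAT_FORMAT)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_emitted_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`emit_csv`, skipping the header."""
    return pd.read_csv(path, comment="#")


def emit_jsonl(
    records: Iterable[Mapping[str, object]],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write records as JSON-lines; metadata goes into a leading line."""
    path = Path(path)
    try:
        with path.open("w") as fh:
            head = {"tool": f"partnerchoice {__version__}", **(metadata or {})}
            fh.write(json.dumps({"_meta": head}) + "\n")
            for rec in records:
                fh.write(json.dumps(rec) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write episode log to {path}: {exc}") from exc
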