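"""CSV/JSON readers and writers with decimal-separator dialects.

Questionnaire exports from spreadsheet software in locales that print
decimal commas use ';' as the field separator; these helpers accept both
that dialect and plain dot-decimal CSV, sniffing when not told, and can
write either.  Also provides the provenance record that makes every
pipeline run replayable.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "ParseError",
    "read_table",
    "write_table",
    "read_long_scores",
    "write_bounds_csv",
    "write_survivor_csv",
    "provenance_record",
]


class ParseError(ValueError):
    """A file failed to parse; carries file and field context."""

    def __init__(self, path, detail: str):
        self.path = str(path)
        super().__init__(f"{path}: {detail}")


def _dialect(path: Path, decimal: str | None) -> tuple[str, str]:
    """(sep, decimal): ';'+',' for comma-decimal files, ','+'.' otherwise."""
    if decimal == ",":
        return ";", ","
    if decimal == ".":
        return ",", "."
    header = path.open(encoding="utf-8").readline()
    return (";", ",") if ";" in header else (",", ".")


def read_table(path: str | Path, *, decimal: str | None = None) -> pd.DataFrame:
    """Read a CSV table in either decimal dialect."""
    path = Path(path)
    if not path.exists():
        raise ParseError(path, "file not found")
    if path.stat().st_size == 0:
        raise ParseError(path, "file is empty")
    sep, dec = _dialect(path, decimal)
    try:
        return pd.read_csv(path, sep=sep, decimal=dec, encoding="utf-8")
    except Exception as err:
        raise ParseError(path, f"malformed CSV ({err})") from err


def write_table(df: pd.DataFrame, path: str | Path, *, decimal: str = ".", index=True):
    """Write a CSV table; decimal ',' switches the separator to ';'."""
    sep = ";" if decimal == "," else ","
    df.to_csv(path, sep=sep, decimal=decimal, index=index)


def read_long_scores(
    path: str | Path,
    columns: tuple[str, str, str],
    *,
    decimal: str | None = None,
) -> pd.DataFrame:
    """Read a long-format score file and validate its columns.

    ``columns`` names the expected (entity, subcriterion, value) triple,
    e.g. ('alternative', 'subcriterion', 'score').
    """
    df = read_table(path, decimal=decimal)
    missing = set(columns) - set(df.columns)
    if missing:
        raise ParseError(path, f"missing columns {sorted(missing)}")
    value_col = columns[2]
    bad = df[pd.to_numeric(df[value_col], errors="coerce").isna()]
    if len(bad):
        raise ParseError(
            path,
            f"non-numeric {value_col!r} at data row(s) {list(bad.index[:5])}",
        )
    df[value_col] = pd.to_numeric(df[value_col])
    return df[list(columns)]


def write_bounds_csv(bounds, path: str | Path, *, decimal: str = ".") -> None:
    df = pd.DataFrame(
        {
            "criterion": bounds.criteria,
            "minimum_limit": bounds.lower,
            "maximum_limit": bounds.upper,
        }
    )
    write_table(df, path, decimal=decimal, index=False)


def write_survivor_csv(pos, path: str | Path, *, decimal: str = ".") -> None:
    """Survivor table: one row per potentially optimal alternative with its
    LP maximum value and the maximizing weights, one column per criterion."""
    rows = []
    for alt in pos.survivors:
        row = {"alternative": alt}
        row.update({f"k_{c}": w for c, w in pos.argmax_weights[alt].items()})
        row["maximum_value"] = pos.max_values[alt]
        rows.append(row)
    write_table(pd.DataFrame(rows), path, decimal=decimal, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def provenance_record(
    inputs: Mapping[str, str | Path], settings: Mapping, path: str | Path | None = None
) -> dict:
    """Hash the inputs and snapshot the settings of a pipeline run.

    The record (inputs' SHA-256 digests plus every numeric setting) is
    sufficient to replay the run exactly; no timestamps, so reruns with the
    same config produce byte-identical output.
    """
    from . import __version__

    rec = {
        "package": "fitradeoff",
        "version": __version__,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
        },
        "settings": dict(settings),
    }
    if path is not None:
        Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
    return rec
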