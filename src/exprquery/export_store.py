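"""Result serialization (CSV, JSON), plot-series extraction and the query store.

CSV output is RFC-4180-style: comma separator, LF line ends, header always
emitted, fields containing comma/quote/newline double-quoted, numbers at
full precision (``repr``) so an export → reload round-trip is lossless.
The JSON result document carries ``{columns, rows, matched, total_scanned}``
with undefined values encoded as ``null``.

The query store is one human-readable JSON file keyed by query name; writes
are atomic (temp file + rename) so a failed save leaves the previous store
intact.
"""

from __future__ import annotations

import csv
import io
import json
import math
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datamodel import format_cell
from .engine import ResultTable
from .errors import NotFoundError, SelectionError, StoreConflictError
from .query_language import QuerySpec

__all__ = [
    "SavedQuery",
    "export_csv",
    "serialize_result",
    "deserialize_result",
    "extract_series",
    "save_query",
    "load_query",
    "list_queries",
]


# ---------------------------------------------------------------------------
# CSV / JSON result serialization
# ---------------------------------------------------------------------------


def export_csv(result: ResultTable, selection: Sequence[int] | None = None) -> str:
    """Render a result (or a row selection of it) as CSV text.

    ``selection`` is a sequence of 0-based row indices into the result, in
    the order they should be emitted; ``None`` exports every row. An
    out-of-range index raises :class:`SelectionError`.
    """
    df = result.data
    if selection is not None:
        bad = [i for i in selection if i < 0 or i >= len(df)]
        if bad:
            raise SelectionError(
                f"selection indices out of range 0..{len(df) - 1}: {bad}"
            )
        df = df.iloc[list(selection)]
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(result.columns)
    for row in df.itertuples(index=False):
        writer.writerow([format_cell(v) for v in row])
    return buf.getvalue()


def serialize_result(result: ResultTable) -> str:
    """Serialize a result to the JSON response document; stable key order."""
    rows = []
    for row in result.data.itertuples(index=False):
        rows.append(
            [None if isinstance(v, float) and math.isnan(v) else v for v in row]
        )
    doc = {
        "columns": result.columns,
        "rows": rows,
        "matched": result.matched,
        "total_scanned": result.total_scanned,
    }
    return json.dumps(doc, ensure_ascii=False, sort_keys=False)


def deserialize_result(text: str) -> ResultTable:
    """Inverse of :func:`serialize_result`."""
    doc = json.loads(text)
    columns = doc["columns"]
    cols: dict[str, list] = {c: [] for c in columns}
    for row in doc["rows"]:
        for c, v in zip(columns, row):
            cols[c].append(v)
    series = {}
    for c, values in cols.items():
        kinds = {type(v) for v in values if v is not None}
        if kinds and kinds <= {int, float}:
            series[c] = pd.Series(
                [float("nan") if v is None else float(v) for v in values], dtype=float
            )
        else:
            series[c] = pd.Series(values, dtype=object)
    df = pd.DataFrame(series, columns=columns) if columns else pd.DataFrame()
    return ResultTable(
        data=df, total_scanned=doc["total_scanned"], matched=doc["matched"]
    )


def extract_series(result: ResultTable, columns: list[str]) -> dict[str, list]:
    """Pull per-column value series (for plotting) out of a result.

    One list per requested numeric column, in result-row order, with missing
    values preserved as ``None`` gaps. The appended sorter column is a valid
    choice; text columns raise :class:`SelectionError`.
    """
    out: dict[str, list] = {}
    for col in columns:
        if col not in result.data.columns:
            raise SelectionError(f"unknown column {col!r}")
        s = result.data[col]
        if not pd.api.types.is_numeric_dtype(s):
            raise SelectionError(f"column {col!r} is not numeric")
        out[col] = [None if pd.isna(v) else float(v) for v in s]
    return out


# ---------------------------------------------------------------------------
# Saved queries
# ---------------------------------------------------------------------------


@dataclass
class SavedQuery:
    """A named, reusable query plus the dataset names it runs on."""

    name: str
    spec: QuerySpec
    datasets: list[str] = field(default_factory=list)
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat(timespec="seconds")


def _read_store(path: Path) -> dict:
    if not path.exists():
        return {}
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _write_store(path: Path, doc: dict) -> None:
    # atomic at file level: temp file in the same directory, then rename
    fd, tmp = tempfile.mkstemp(dir=str(path.parent) or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, ensure_ascii=False)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_query(store: str | Path, q: SavedQuery, overwrite: bool = False) -> None:
    """Persist a query under its name; duplicate names need ``overwrite=True``."""
    path = Path(store)
    doc = _read_store(path)
    if q.name in doc and not overwrite:
        raise StoreConflictError(
            f"query {q.name!r} already exists (pass overwrite to replace)"
        )
    doc[q.name] = {
        "filter": q.spec.filter_text,
        "sorter": q.spec.sorter_text,
        "maxrows": q.spec.maxrows,
        "descending": q.spec.descending,
        "datasets": list(q.datasets),
        "created": q.created,
    }
    _write_store(path, doc)


def load_query(store: str | Path, name: str) -> SavedQuery:
    """Load a saved query by name; unknown names raise :class:`NotFoundError`."""
    doc = _read_store(Path(store))
    if name not in doc:
        raise NotFoundError(f"no saved query named {name!r}")
    e = doc[name]
    return SavedQuery(
        name=name,
        spec=QuerySpec(
            filter_text=e["filter"],
            sorter_text=e["sorter"],
            maxrows=e["maxrows"],
            descending=e["descending"],
        ),
        datasets=list(e["datasets"]),
        created=e["created"],
    )


def list_queries(store: str | Path) -> list[str]:
    """Names of saved queries in insertion order."""
    return list(_read_store(Path(store)))
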