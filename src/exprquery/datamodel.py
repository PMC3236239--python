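"""Expression-table data model: loading, annotation, joining, links.

Tables are delimited text (CSV/TSV) with a mandatory header row. Each
dataset has one identifier column (gene, transcript or probe id), any number
of numeric sample columns (normalized expression values, binding scores,
...), and optionally the annotation columns ``description`` and ``goterms``.
Queries never run on a single dataset directly: all datasets participating
in a query are pre-joined on a shared identifier into one
:class:`JoinedTable`, mirroring how a pre-joined SQL table would hold the
union of columns.

GO annotations are serialized into a single ``goterms`` text cell as
``GO:0003677|DNA binding;GO:0045893|...`` — entries separated by ``;``, ID
and name by ``|``, IDs zero-padded to 7 digits with a ``GO:`` prefix. This
makes both name queries (``find("dna binding",goterms)``) and bare-ID
queries (``find("3677",goterms)``) plain substring matches on the cell.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, JoinError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "GoAnnotation",
    "JoinedTable",
    "MISSING_TOKENS",
    "UNKNOWN_TERM",
    "DEFAULT_LINK_TEMPLATES",
    "load_dataset",
    "write_dataset",
    "join_datasets",
    "parse_goterms",
    "serialize_goterms",
    "normalize_go_id",
    "load_go_mapping",
    "goterm_name",
    "record_link",
    "load_registry",
]

#: Cell values treated as missing on load (matched case-insensitively).
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})

#: Annotation column names recognized (case-insensitively) in headers.
ANNOTATION_NAMES = ("description", "goterms")

#: Sentinel returned by :func:`goterm_name` for IDs absent from the mapping.
UNKNOWN_TERM = "unknown term"

_GO_ID_RE = re.compile(r"^GO:[0-9]{7}$")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GoAnnotation:
    """One GO term attached to a record: accession plus human-readable name.

    ``go_id`` is ``GO:`` plus seven zero-padded digits, or ``None`` for a
    malformed entry kept as name-only.
    """

    go_id: str | None
    go_name: str

    def __post_init__(self) -> None:
        if self.go_id is not None and not _GO_ID_RE.match(self.go_id):
            raise ValueError(f"malformed GO id {self.go_id!r}")

    def serialize(self) -> str:
        if self.go_id is None:
            return self.go_name
        return f"{self.go_id}|{self.go_name}"


@dataclass
class ExpressionDataset:
    """One loaded expression table.

    Attributes
    ----------
    name:
        Short dataset label (used to disambiguate columns at join time).
    id_column:
        Name of the identifier column.
    data:
        The table; sample columns are float64 (NaN = missing), the id and
        annotation columns are strings.
    sample_columns:
        Ordered numeric column names.
    annotation_columns:
        Subset of ``("description", "goterms")`` present.
    """

    name: str
    id_column: str
    data: pd.DataFrame
    sample_columns: list[str]
    annotation_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.sample_columns) & ({self.id_column} | set(ANNOTATION_NAMES))
        if overlap:
            raise SchemaError(
                f"dataset {self.name!r}: sample columns collide with "
                f"id/annotation columns: {sorted(overlap)}"
            )
        ids = self.data[self.id_column]
        if len(ids) and (ids.isna() | (ids.astype(str).str.strip() == "")).any():
            raise SchemaError(f"dataset {self.name!r}: empty identifier value")

    @property
    def keys(self) -> list[str]:
        return list(self.data[self.id_column])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class JoinedTable:
    """The pre-joined table all queries run against: one row per shared key."""

    key_column: str
    data: pd.DataFrame
    numeric_columns: list[str]
    annotation_columns: list[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# Loading and writing
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _is_missing(value: str) -> bool:
    return value.strip().lower() in MISSING_TOKENS


def _parse_float(value: str) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise ValueError(f"non-finite value {value!r}")
    return v


def load_dataset(
    path: str | Path,
    id_column: str,
    name: str | None = None,
    delimiter: str | None = None,
    prefix: str | None = None,
) -> ExpressionDataset:
    """Load a delimited expression table.

    Columns other than the id and the annotation columns (``description`` /
    ``goterms``, matched case-insensitively in the header) are auto-detected:
    a column whose every non-missing value parses as a finite number becomes
    a numeric sample column; anything else stays text. Missing-value tokens
    are the empty string, ``NA``, ``NaN`` and ``null`` (case-insensitive).
    ``prefix`` renames every sample column to ``<prefix>_<column>`` so that
    datasets with identical sample names can still be joined.

    Raises :class:`SchemaError` for a missing id column or duplicate header
    names, :class:`InputError` for an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    delim = delimiter or _sniff_delimiter(path)
    name = name or path.stem

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise InputError(f"{path}: empty file") from None
        rows = [r for r in reader if r and any(c.strip() for c in r)]

    header = [h.strip() for h in header]
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise SchemaError(f"{path}: duplicate header names: {sorted(dupes)}")
    if id_column not in header:
        raise SchemaError(f"{path}: id column {id_column!r} not in header {header}")

    # pad short rows so every record has every column
    width = len(header)
    table = {h: [] for h in header}
    for r in rows:
        r = list(r) + [""] * (width - len(r))
        for h, cell in zip(header, r):
            table[h].append(cell)

    rename: dict[str, str] = {}
    annotation_columns: list[str] = []
    sample_columns: list[str] = []
    columns: dict[str, object] = {}

    for h in header:
        cells = table[h]
        lower = h.lower()
        if h == id_column:
            columns[h] = pd.Series(cells, dtype=object)
        elif lower in ANNOTATION_NAMES:
            if lower != h:
                rename[h] = lower
            annotation_columns.append(lower)
            columns[lower] = pd.Series(
                ["" if _is_missing(c) else c for c in cells], dtype=object
            )
        else:
            parsed: list[float] = []
            numeric = True
            for c in cells:
                if _is_missing(c):
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(_parse_float(c))
                except ValueError:
                    numeric = False
                    break
            target = h if prefix is None else f"{prefix}_{h}"
            if numeric:
                sample_columns.append(target)
                columns[target] = pd.Series(parsed, dtype=float)
            else:
                columns[target] = pd.Series(cells, dtype=object)

    df = pd.DataFrame(columns)
    return ExpressionDataset(
        name=name,
        id_column=id_column,
        data=df,
        sample_columns=sample_columns,
        annotation_columns=annotation_columns,
    )


def format_cell(value) -> str:
    """Render one cell for delimited-text output; full float precision, '' for missing."""
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)
    return str(value)


def write_dataset(ds: ExpressionDataset, path: str | Path, delimiter: str | None = None) -> None:
    """Write a dataset back to delimited text; round-trips through :func:`load_dataset`."""
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(ds.data.columns)
        for row in ds.data.itertuples(index=False):
            writer.writerow([format_cell(v) for v in row])


# ---------------------------------------------------------------------------
# Joining
# ---------------------------------------------------------------------------


def join_datasets(
    datasets: list[ExpressionDataset],
    key: str,
    policy: str = "inner",
) -> JoinedTable:
    """Pre-join datasets on a shared identifier column.

    ``inner`` keeps the intersection of all key sets; ``left`` keeps the
    first dataset's keys, with absent cells missing. Annotation columns come
    from the first dataset providing them; later duplicates are suffixed with
    their source dataset name. Sample-column name collisions and duplicate
    keys within one dataset raise :class:`JoinError` (use the loader's
    ``prefix`` to disambiguate sample names).
    """
    if policy not in ("inner", "left"):
        raise ConfigError(f"unknown join policy {policy!r}")
    if not datasets:
        raise JoinError("no datasets to join")
    for ds in datasets:
        if ds.id_column != key:
            raise JoinError(
                f"dataset {ds.name!r} is keyed by {ds.id_column!r}, not {key!r}"
            )
        keys = ds.data[key]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise JoinError(f"dataset {ds.name!r}: duplicate key {dup!r}")

    numeric_columns: list[str] = []
    annotation_columns: list[str] = []
    provenance: dict[str, str] = {}
    seen: dict[str, str] = {}  # column -> owning dataset

    frames: list[pd.DataFrame] = []
    for ds in datasets:
        frame = ds.data.copy()
        renames: dict[str, str] = {}
        for col in frame.columns:
            if col == key:
                continue
            if col in ds.annotation_columns:
                if col in seen:
                    renames[col] = f"{col}_{ds.name}"
            elif col in seen:
                raise JoinError(
                    f"column {col!r} appears in both {seen[col]!r} and "
                    f"{ds.name!r}; load with a per-dataset prefix to disambiguate"
                )
        frame = frame.rename(columns=renames)
        for col in frame.columns:
            if col == key:
                continue
            seen[col] = ds.name
            provenance[col] = ds.name
            original = next((o for o, n in renames.items() if n == col), col)
            if original in ds.sample_columns or col in ds.sample_columns:
                numeric_columns.append(col)
            elif original in ds.annotation_columns:
                annotation_columns.append(col)
        frames.append(frame)

    how = "inner" if policy == "inner" else "left"
    joined = frames[0]
    for frame in frames[1:]:
        joined = joined.merge(frame, on=key, how=how, sort=False)

    return JoinedTable(
        key_column=key,
        data=joined.reset_index(drop=True),
        numeric_columns=numeric_columns,
        annotation_columns=annotation_columns,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------


def parse_goterms(cell: str) -> list[GoAnnotation]:
    """Parse a serialized goterms cell into annotations.

    Entries are ``;``-separated, each ``GO:<7 digits>|<name>``. A malformed
    entry (no recognizable GO id) is kept as a name-only annotation and
    logged as a warning, never dropped silently. An empty cell yields ``[]``.
    """
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    out: list[GoAnnotation] = []
    for raw in str(cell).split(";"):
        entry = raw.strip()
        if not entry:
            continue
        go_id, _, go_name = entry.partition("|")
        go_id = go_id.strip()
        if _GO_ID_RE.match(go_id) and go_name:
            out.append(GoAnnotation(go_id, go_name.strip()))
        else:
            logger.warning("malformed goterms entry %r kept as name-only", entry)
            out.append(GoAnnotation(None, entry))
    return out


def serialize_goterms(annotations: list[GoAnnotation]) -> str:
    """Inverse of :func:`parse_goterms` on well-formed entries."""
    return ";".join(a.serialize() for a in annotations)


def normalize_go_id(go_id: str) -> str:
    """Normalize bare digits or a GO accession to canonical ``GO:NNNNNNN`` form."""
    text = go_id.strip()
    if text.upper().startswith("GO:"):
        text = text[3:]
    if not text.isdigit():
        raise ValueError(f"not a GO id: {go_id!r}")
    return f"GO:{int(text):07d}"


def load_go_mapping(path: str | Path) -> dict[str, str]:
    """Load a two-column headerless TSV of GO id → term name."""
    mapping: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) < 2:
                continue
            mapping[normalize_go_id(row[0])] = row[1].strip()
    return mapping


def goterm_name(go_id: str, mapping: Mapping[str, str]) -> str:
    """Resolve a GO id (accession or bare digits) to its term name.

    The lookup is total: an unknown or unparseable id returns the
    :data:`UNKNOWN_TERM` sentinel rather than raising.
    """
    try:
        canonical = normalize_go_id(go_id)
    except ValueError:
        return UNKNOWN_TERM
    return mapping.get(canonical, UNKNOWN_TERM)


# ---------------------------------------------------------------------------
# External record links
# ---------------------------------------------------------------------------

#: URL templates per identifier source; ``{id}`` is replaced by the
#: percent-encoded record key.
DEFAULT_LINK_TEMPLATES = {
    "ensembl": "https://www.ensembl.org/id/{id}",
    "refseq": "https://www.ncbi.nlm.nih.gov/nuccore/{id}",
}


def record_link(
    record: Mapping[str, object],
    key_column: str,
    id_source: str,
    templates: Mapping[str, str] | None = None,
) -> str:
    """Build the external gene-page URL for one result row.

    ``id_source`` selects a template (``ensembl`` or ``refseq`` by default);
    an id_source with no configured template raises :class:`ConfigError`.
    The key value is percent-encoded before substitution.
    """
    templates = DEFAULT_LINK_TEMPLATES if templates is None else templates
    if id_source not in templates:
        raise ConfigError(f"no URL template configured for id source {id_source!r}")
    key = str(record[key_column]).strip()
    if not key:
        raise ConfigError("record has an empty key value")
    return templates[id_source].format(id=urllib.parse.quote(key, safe=""))


# ---------------------------------------------------------------------------
# Dataset registry
# ---------------------------------------------------------------------------


def load_registry(path: str | Path) -> dict[str, dict]:
    """Load the dataset registry: a JSON document listing, per dataset,
    ``{name, path, id_column, prefix?, delimiter?}``. Relative dataset paths
    are resolved against the registry file's directory.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"registry not found: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"registry {path} is not valid JSON: {exc}") from exc
    entries = doc["datasets"] if isinstance(doc, dict) and "datasets" in doc else doc
    registry: dict[str, dict] = {}
    for entry in entries:
        if "name" not in entry or "path" not in entry or "id_column" not in entry:
            raise ConfigError(
                f"registry entry {entry!r} needs name, path and id_column"
            )
        entry = dict(entry)
        p = Path(entry["path"])
        entry["path"] = str(p if p.is_absolute() else path.parent / p)
        registry[entry["name"]] = entry
    return registry


def load_registered(registry: Mapping[str, dict], names: list[str]) -> list[ExpressionDataset]:
    """Load the named datasets from a registry mapping."""
    from .errors import NotFoundError

    out = []
    for n in names:
        if n not in registry:
            raise NotFoundError(f"dataset {n!r} not in registry")
        e = registry[n]
        out.append(
            load_dataset(
                e["path"],
                id_column=e["id_column"],
                name=e["name"],
                delimiter=e.get("delimiter"),
                prefix=e.get("prefix"),
            )
        )
    return out
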