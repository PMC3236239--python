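"""Query execution: per-row expression evaluation and the full pipeline.

The pipeline mirrors a ``SELECT ... WHERE <filter> ORDER BY <sorter> LIMIT
<maxrows>`` over the pre-joined table, evaluated natively:

1. rows where the FILTER evaluates to *true* are kept;
2. the SORTER value is computed per matching row and appended as the last
   column;
3. rows are sorted by that value (descending by default; "inverted" =
   ascending), undefined values last, ties kept in input order;
4. the sorted result is truncated to MAXROWS.

Numeric evaluation is three-valued: a missing cell or a division by zero
makes the subexpression *undefined* (NaN), which propagates through
arithmetic and comparisons; AND/OR/NOT follow Kleene logic, so e.g.
``sg3>200 OR mes1>5`` is still true when ``mes1`` is missing but ``sg3``
exceeds 200. ``find()`` is two-valued — searching an absent annotation is a
definite non-match. A row is selected only when the filter is definitely
true.

Internally boolean series are float64 with 1.0/0.0/NaN for true/false/
undefined; AND/OR are NaN-propagating min/max with the dominant value
(false for AND, true for OR) forced through, which is exactly the Kleene
truth table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import JoinedTable
from .errors import ValidationError
from .query_language import (
    And,
    Arith,
    ColumnRef,
    Compare,
    ExpressionNode,
    FindCall,
    Neg,
    Not,
    NumberLiteral,
    Or,
    QuerySpec,
    parse_filter,
    parse_sorter,
    validate_columns,
)

__all__ = ["ResultTable", "SORTER_COLUMN", "run_query", "eval_numeric", "eval_boolean", "eval_find"]

#: Name of the appended sorter-value column (always last in a ResultTable).
SORTER_COLUMN = "sorter_value"


@dataclass
class ResultTable:
    """A query result: matching rows in sorted order plus bookkeeping counts.

    ``matched`` counts rows passing the filter before truncation, so a
    "213 out of 24662" style report is ``matched`` out of ``total_scanned``;
    ``len(rows)`` is ``min(matched, maxrows)`` when a limit is set. When a
    sorter was given its per-row value is the last column.
    """

    data: pd.DataFrame
    total_scanned: int
    matched: int

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "ResultTable") -> bool:
        return (
            self.columns == other.columns
            and self.total_scanned == other.total_scanned
            and self.matched == other.matched
            and self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
        )


# ---------------------------------------------------------------------------
# Vectorized three-valued evaluation
# ---------------------------------------------------------------------------


def _numeric_series(df: pd.DataFrame, node: ExpressionNode) -> pd.Series:
    if isinstance(node, NumberLiteral):
        return pd.Series(np.full(len(df), node.value), index=df.index)
    if isinstance(node, ColumnRef):
        return df[node.name].astype(float)
    if isinstance(node, Neg):
        return -_numeric_series(df, node.child)
    if isinstance(node, Arith):
        left = _numeric_series(df, node.left)
        right = _numeric_series(df, node.right)
        if node.op == "+":
            return left + right
        if node.op == "-":
            return left - right
        if node.op == "*":
            return left * right
        if node.op == "/":
            # division by zero is undefined, not an error
            with np.errstate(divide="ignore", invalid="ignore"):
                out = left / right.where(right != 0)
            return out
        raise TypeError(f"unknown arithmetic op {node.op!r}")
    raise TypeError(f"not a numeric node: {node!r}")


_CMP = {
    ">": np.greater,
    "<": np.less,
    ">=": np.greater_equal,
    "<=": np.less_equal,
    "=": np.equal,
    "!=": np.not_equal,
}


def _boolean_series(df: pd.DataFrame, node: ExpressionNode) -> pd.Series:
    if isinstance(node, Compare):
        left = _numeric_series(df, node.left)
        right = _numeric_series(df, node.right)
        out = _CMP[node.op](left.to_numpy(), right.to_numpy()).astype(float)
        out[np.isnan(left.to_numpy()) | np.isnan(right.to_numpy())] = np.nan
        return pd.Series(out, index=df.index)
    if isinstance(node, And):
        a = _boolean_series(df, node.left).to_numpy()
        b = _boolean_series(df, node.right).to_numpy()
        # NaN-propagating min, but a definite false dominates undefined
        out = np.minimum(a, b)
        out[(a == 0.0) | (b == 0.0)] = 0.0
        return pd.Series(out, index=df.index)
    if isinstance(node, Or):
        a = _boolean_series(df, node.left).to_numpy()
        b = _boolean_series(df, node.right).to_numpy()
        # NaN-propagating max, but a definite true dominates undefined
        out = np.maximum(a, b)
        out[(a == 1.0) | (b == 1.0)] = 1.0
        return pd.Series(out, index=df.index)
    if isinstance(node, Not):
        return 1.0 - _boolean_series(df, node.child)
    if isinstance(node, FindCall):
        cells = df[node.column].fillna("").astype(str)
        hits = cells.str.contains(node.needle, case=False, regex=False)
        return hits.astype(float)
    raise TypeError(f"not a boolean node: {node!r}")


# ---------------------------------------------------------------------------
# Single-row convenience evaluators
# ---------------------------------------------------------------------------


def _row_frame(row) -> pd.DataFrame:
    return pd.DataFrame({k: [v] for k, v in dict(row).items()})


def eval_numeric(row, node: ExpressionNode) -> float | None:
    """Evaluate an arithmetic node on one record; ``None`` when undefined."""
    v = _numeric_series(_row_frame(row), node).iloc[0]
    return None if pd.isna(v) else float(v)


def eval_boolean(row, node: ExpressionNode) -> bool | None:
    """Evaluate a boolean node on one record under Kleene three-valued logic."""
    v = _boolean_series(_row_frame(row), node).iloc[0]
    return None if pd.isna(v) else bool(v)


def eval_find(row, call: FindCall) -> bool:
    """Evaluate a find() predicate on one record; always definite."""
    return bool(_boolean_series(_row_frame(row), call).iloc[0])


# ---------------------------------------------------------------------------
# Full query pipeline
# ---------------------------------------------------------------------------


def _validated(node: ExpressionNode, table: JoinedTable, what: str) -> ExpressionNode:
    findings = validate_columns(node, table)
    if findings:
        raise ValidationError(f"unknown columns in {what}: " + ", ".join(findings))
    return node


def run_query(table: JoinedTable, query: QuerySpec) -> ResultTable:
    """Execute a complete query against a joined table.

    Parse and validation errors surface before any row is scanned. With an
    empty filter every row matches; with an empty sorter the input order is
    kept and no sorter column is appended.
    """
    filter_node = (
        _validated(parse_filter(query.filter_text), table, "filter")
        if query.filter_text.strip()
        else None
    )
    sorter_node = (
        _validated(parse_sorter(query.sorter_text), table, "sorter")
        if query.sorter_text.strip()
        else None
    )

    df = table.data.reset_index(drop=True)
    total = len(df)

    if filter_node is not None and total:
        mask = _boolean_series(df, filter_node)
        selected = df[mask.to_numpy() == 1.0]
    elif filter_node is not None:
        selected = df
    else:
        selected = df
    matched = len(selected)

    out = selected.copy()
    if sorter_node is not None:
        name = SORTER_COLUMN
        while name in out.columns:
            name += "_"
        out[name] = _numeric_series(out, sorter_node) if matched else pd.Series(dtype=float)
        out = out.sort_values(
            name,
            ascending=not query.descending,
            kind="stable",
            na_position="last",
        )

    if query.maxrows > 0:
        out = out.head(query.maxrows)

    return ResultTable(data=out.reset_index(drop=True), total_scanned=total, matched=matched)
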