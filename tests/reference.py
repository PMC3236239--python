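"""Independent naive reference interpreter and random query sampler.

This is a second, deliberately simple implementation of the query semantics:
per-row recursive AST evaluation with explicit Kleene truth tables, a
reference stable sort, and post-sort truncation. It shares no evaluation
code with the vectorized engine and serves as the oracle in equivalence
tests.
"""

from __future__ import annotations

import math
import random

from exprquery.engine import SORTER_COLUMN, ResultTable
from exprquery.query_language import (
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
)


def _cell(row: dict, name: str):
    v = row.get(name)
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


def naive_eval_num(row: dict, node: ExpressionNode) -> float | None:
    if isinstance(node, NumberLiteral):
        return node.value
    if isinstance(node, ColumnRef):
        v = _cell(row, node.name)
        return None if v is None else float(v)
    if isinstance(node, Neg):
        v = naive_eval_num(row, node.child)
        return None if v is None else -v
    if isinstance(node, Arith):
        a = naive_eval_num(row, node.left)
        b = naive_eval_num(row, node.right)
        if a is None or b is None:
            return None
        if node.op == "+":
            return a + b
        if node.op == "-":
            return a - b
        if node.op == "*":
            return a * b
        if node.op == "/":
            return None if b == 0 else a / b
        raise AssertionError(node.op)
    raise AssertionError(node)


def naive_eval_bool(row: dict, node: ExpressionNode) -> bool | None:
    if isinstance(node, Compare):
        a = naive_eval_num(row, node.left)
        b = naive_eval_num(row, node.right)
        if a is None or b is None:
            return None
        return {
            ">": a > b,
            "<": a < b,
            ">=": a >= b,
            "<=": a <= b,
            "=": a == b,
            "!=": a != b,
        }[node.op]
    if isinstance(node, And):
        a = naive_eval_bool(row, node.left)
        b = naive_eval_bool(row, node.right)
        if a is False or b is False:
            return False
        if a is None or b is None:
            return None
        return True
    if isinstance(node, Or):
        a = naive_eval_bool(row, node.left)
        b = naive_eval_bool(row, node.right)
        if a is True or b is True:
            return True
        if a is None or b is None:
            return None
        return False
    if isinstance(node, Not):
        v = naive_eval_bool(row, node.child)
        return None if v is None else not v
    if isinstance(node, FindCall):
        cell = _cell(row, node.column)
        if cell is None:
            return False
        return node.needle.lower() in str(cell).lower()
    raise AssertionError(node)


def naive_run_query(table, spec: QuerySpec) -> dict:
    """Reference query execution returning a plain comparable structure."""
    rows = table.data.to_dict("records")
    columns = list(table.data.columns)
    total = len(rows)

    if spec.filter_text.strip():
        fnode = parse_filter(spec.filter_text)
        kept = [(i, r) for i, r in enumerate(rows) if naive_eval_bool(r, fnode) is True]
    else:
        kept = list(enumerate(rows))
    matched = len(kept)

    out_columns = list(columns)
    if spec.sorter_text.strip():
        snode = parse_sorter(spec.sorter_text)
        name = SORTER_COLUMN
        while name in out_columns:
            name += "_"
        out_columns.append(name)
        scored = []
        for i, r in kept:
            v = naive_eval_num(r, snode)
            r = dict(r)
            r[name] = v
            scored.append((i, r, v))
        # stable: undefined last, then by value; ties keep input order
        scored.sort(
            key=lambda t: (
                t[2] is None,
                0.0 if t[2] is None else (-t[2] if spec.descending else t[2]),
            )
        )
        kept = [(i, r) for i, r, _ in scored]

    if spec.maxrows > 0:
        kept = kept[: spec.maxrows]

    out_rows = [[_cell(r, c) for c in out_columns] for _, r in kept]
    return {
        "columns": out_columns,
        "rows": out_rows,
        "matched": matched,
        "total_scanned": total,
    }


def result_as_plain(result: ResultTable) -> dict:
    """Convert an engine ResultTable into the same comparable structure."""
    rows = []
    for row in result.data.itertuples(index=False):
        rows.append(
            [None if isinstance(v, float) and math.isnan(v) else v for v in row]
        )
    return {
        "columns": result.columns,
        "rows": rows,
        "matched": result.matched,
        "total_scanned": result.total_scanned,
    }


# ---------------------------------------------------------------------------
# Random well-formed query sampler
# ---------------------------------------------------------------------------

NEEDLES = [
    "hox",
    "dna binding",
    "3677",
    "transcription factor",
    "activator",
    "protein",
    "kinase",
    "no such text",
]
LITERALS = [0.0, 1.0, 5.0, 10.0, 20.0, 50.0, 200.0, 0.5]


def sample_numeric(rng: random.Random, numeric_cols: list[str], depth: int) -> ExpressionNode:
    if depth <= 0 or rng.random() < 0.45:
        if rng.random() < 0.6:
            return ColumnRef(rng.choice(numeric_cols))
        return NumberLiteral(rng.choice(LITERALS))
    roll = rng.random()
    if roll < 0.85:
        op = rng.choice("+-*/")
        return Arith(
            op,
            sample_numeric(rng, numeric_cols, depth - 1),
            sample_numeric(rng, numeric_cols, depth - 1),
        )
    return Neg(sample_numeric(rng, numeric_cols, depth - 1))


def sample_boolean(
    rng: random.Random,
    numeric_cols: list[str],
    annotation_cols: list[str],
    depth: int,
) -> ExpressionNode:
    if depth <= 0 or rng.random() < 0.4:
        if annotation_cols and rng.random() < 0.35:
            return FindCall(rng.choice(NEEDLES), rng.choice(annotation_cols))
        op = rng.choice([">", "<", ">=", "<=", "=", "!="])
        return Compare(
            op,
            sample_numeric(rng, numeric_cols, depth - 1),
            sample_numeric(rng, numeric_cols, depth - 1),
        )
    roll = rng.random()
    if roll < 0.4:
        return And(
            sample_boolean(rng, numeric_cols, annotation_cols, depth - 1),
            sample_boolean(rng, numeric_cols, annotation_cols, depth - 1),
        )
    if roll < 0.8:
        return Or(
            sample_boolean(rng, numeric_cols, annotation_cols, depth - 1),
            sample_boolean(rng, numeric_cols, annotation_cols, depth - 1),
        )
    return Not(sample_boolean(rng, numeric_cols, annotation_cols, depth - 1))


def sample_query(
    rng: random.Random,
    numeric_cols: list[str],
    annotation_cols: list[str],
    depth: int = 5,
) -> QuerySpec:
    from exprquery.query_language import render

    filter_text = render(sample_boolean(rng, numeric_cols, annotation_cols, depth))
    sorter_text = (
        render(sample_numeric(rng, numeric_cols, depth)) if rng.random() < 0.8 else ""
    )
    maxrows = rng.choice([0, 0, 1, 5, 50])
    return QuerySpec(
        filter_text=filter_text,
        sorter_text=sorter_text,
        maxrows=maxrows,
        descending=rng.random() < 0.5,
    )
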