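"""FILTER / SORTER expression language: tokenizer, parser, AST, renderer.

A query against a joined expression table is split into three independent
parts: a boolean FILTER expression selecting rows, a numeric SORTER
expression computed per matching row and used for ordering, and a MAXROWS
limit applied after sorting. This module turns the expression texts into a
validated AST; evaluation lives in :mod:`exprquery.engine`.

Grammar (tightest binding first)::

    parentheses  >  unary NOT / unary -  >  * /  >  + -  >  comparisons  >  AND  >  OR

Keywords (``and``, ``or``, ``not``, ``find``) are case-insensitive; column
identifiers are case-sensitive and must match the table exactly. Equality is
spelled ``=`` or ``==``; inequality ``!=``, with the spaced form ``! =`` also
accepted. String literals take single or double quotes (no escapes).
Comparisons are non-associative: ``a > b > c`` is a syntax error.

``find(needle, column)`` is the text predicate: true iff *needle* occurs
case-insensitively as a substring of the row's annotation cell (description
or goterms).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError

__all__ = [
    "Token",
    "tokenize",
    "parse_filter",
    "parse_sorter",
    "validate_columns",
    "render",
    "QuerySpec",
    "ExpressionNode",
    "And",
    "Or",
    "Not",
    "Compare",
    "Arith",
    "Neg",
    "FindCall",
    "ColumnRef",
    "NumberLiteral",
]


# ---------------------------------------------------------------------------
# AST node types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionNode:
    """Base class for AST nodes. ``pos`` is the source offset (not compared)."""

    pos: int = field(default=-1, compare=False, kw_only=True)


@dataclass(frozen=True)
class NumberLiteral(ExpressionNode):
    value: float


@dataclass(frozen=True)
class ColumnRef(ExpressionNode):
    name: str


@dataclass(frozen=True)
class Arith(ExpressionNode):
    """Binary arithmetic; ``op`` is one of ``+ - * /``."""

    op: str
    left: ExpressionNode
    right: ExpressionNode


@dataclass(frozen=True)
class Neg(ExpressionNode):
    child: ExpressionNode


@dataclass(frozen=True)
class Compare(ExpressionNode):
    """Numeric comparison; ``op`` is one of ``> < >= <= = !=``."""

    op: str
    left: ExpressionNode
    right: ExpressionNode


@dataclass(frozen=True)
class And(ExpressionNode):
    left: ExpressionNode
    right: ExpressionNode


@dataclass(frozen=True)
class Or(ExpressionNode):
    left: ExpressionNode
    right: ExpressionNode


@dataclass(frozen=True)
class Not(ExpressionNode):
    child: ExpressionNode


@dataclass(frozen=True)
class FindCall(ExpressionNode):
    """Case-insensitive substring test of ``needle`` in annotation column ``column``."""

    needle: str
    column: str


# ---------------------------------------------------------------------------
# Query specification
# ---------------------------------------------------------------------------


@dataclass
class QuerySpec:
    """A complete user query.

    Parameters
    ----------
    filter_text:
        Boolean expression; empty string matches every row.
    sorter_text:
        Numeric expression; empty string keeps input order and appends no
        sorter column.
    maxrows:
        Row limit applied after sorting; 0 means unlimited.
    descending:
        Sort direction for the sorter value. Descending (the default) puts
        the largest sorter values first; an "inverted" sorter is ascending.
    """

    filter_text: str = ""
    sorter_text: str = ""
    maxrows: int = 0
    descending: bool = True

    def __post_init__(self) -> None:
        if self.maxrows < 0:
            raise ValueError("maxrows must be >= 0")

    def validate(self) -> None:
        """Parse both expression texts, raising :class:`ParseError` on failure."""
        if self.filter_text.strip():
            parse_filter(self.filter_text)
        if self.sorter_text.strip():
            parse_sorter(self.sorter_text)


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_KEYWORDS = {"and": "AND", "or": "OR", "not": "NOT", "find": "FIND"}

_TOKEN_RE = re.compile(
    r"""
      (?P<WS>\s+)
    | (?P<NUMBER>\d+\.\d*|\.\d+|\d+)
    | (?P<IDENT>[A-Za-z_][A-Za-z0-9_]*)
    | (?P<STRING>"[^"]*"|'[^']*')
    | (?P<GE>>=) | (?P<LE><=) | (?P<EQ>==|=) | (?P<NEQ>!\s*=)
    | (?P<GT>>) | (?P<LT><)
    | (?P<PLUS>\+) | (?P<MINUS>-) | (?P<MUL>\*) | (?P<DIV>/)
    | (?P<LPAREN>\() | (?P<RPAREN>\)) | (?P<COMMA>,)
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class Token:
    kind: str
    value: str
    pos: int


def tokenize(text: str) -> list[Token]:
    """Lex an expression string into tokens.

    Whitespace is insignificant. ``!`` followed by optional whitespace and
    ``=`` lexes as a single not-equal token. Raises :class:`ParseError` with
    the offending position on illegal characters or unterminated strings.
    """
    tokens: list[Token] = []
    i = 0
    n = len(text)
    while i < n:
        m = _TOKEN_RE.match(text, i)
        if m is None:
            ch = text[i]
            if ch in "\"'":
                raise ParseError("unterminated string literal", i)
            if ch == "!":
                raise ParseError("'!' must be followed by '='", i)
            raise ParseError(f"illegal character {ch!r}", i)
        kind = m.lastgroup
        assert kind is not None
        val = m.group()
        if kind == "WS":
            i = m.end()
            continue
        if kind == "IDENT":
            kw = _KEYWORDS.get(val.lower())
            if kw is not None:
                kind = kw
        elif kind == "STRING":
            val = val[1:-1]
        elif kind == "NEQ":
            val = "!="
        elif kind == "EQ":
            val = "="
        tokens.append(Token(kind, val, m.start()))
        i = m.end()
    return tokens


# ---------------------------------------------------------------------------
# Recursive-descent parser
# ---------------------------------------------------------------------------

_COMPARE_OPS = {"GT": ">", "LT": "<", "GE": ">=", "LE": "<=", "EQ": "=", "NEQ": "!="}


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = tokenize(text)
        self.i = 0

    # -- token helpers --

    def _peek(self) -> Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> Token:
        tok = self._peek()
        if tok is None:
            raise ParseError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok

    def _expect(self, kind: str, what: str) -> Token:
        tok = self._peek()
        if tok is None or tok.kind != kind:
            pos = tok.pos if tok is not None else len(self.text)
            raise ParseError(f"expected {what}", pos)
        return self._next()

    # -- grammar rules, loosest binding first --

    def parse_expression(self) -> ExpressionNode:
        node = self.parse_or()
        tok = self._peek()
        if tok is not None:
            raise ParseError(f"unexpected {tok.value!r}", tok.pos)
        return node

    def parse_or(self) -> ExpressionNode:
        node = self.parse_and()
        while (tok := self._peek()) is not None and tok.kind == "OR":
            self._next()
            node = Or(node, self.parse_and(), pos=tok.pos)
        return node

    def parse_and(self) -> ExpressionNode:
        node = self.parse_comparison()
        while (tok := self._peek()) is not None and tok.kind == "AND":
            self._next()
            node = And(node, self.parse_comparison(), pos=tok.pos)
        return node

    def parse_comparison(self) -> ExpressionNode:
        # non-associative: at most one comparison operator per level
        node = self.parse_additive()
        tok = self._peek()
        if tok is not None and tok.kind in _COMPARE_OPS:
            self._next()
            right = self.parse_additive()
            node = Compare(_COMPARE_OPS[tok.kind], node, right, pos=tok.pos)
            nxt = self._peek()
            if nxt is not None and nxt.kind in _COMPARE_OPS:
                raise ParseError("chained comparisons are not supported", nxt.pos)
        return node

    def parse_additive(self) -> ExpressionNode:
        node = self.parse_multiplicative()
        while (tok := self._peek()) is not None and tok.kind in ("PLUS", "MINUS"):
            self._next()
            op = "+" if tok.kind == "PLUS" else "-"
            node = Arith(op, node, self.parse_multiplicative(), pos=tok.pos)
        return node

    def parse_multiplicative(self) -> ExpressionNode:
        node = self.parse_unary()
        while (tok := self._peek()) is not None and tok.kind in ("MUL", "DIV"):
            self._next()
            op = "*" if tok.kind == "MUL" else "/"
            node = Arith(op, node, self.parse_unary(), pos=tok.pos)
        return node

    def parse_unary(self) -> ExpressionNode:
        tok = self._peek()
        if tok is not None and tok.kind == "NOT":
            self._next()
            return Not(self.parse_unary(), pos=tok.pos)
        if tok is not None and tok.kind == "MINUS":
            self._next()
            return Neg(self.parse_unary(), pos=tok.pos)
        return self.parse_atom()

    def parse_atom(self) -> ExpressionNode:
        tok = self._next()
        if tok.kind == "NUMBER":
            return NumberLiteral(float(tok.value), pos=tok.pos)
        if tok.kind == "IDENT":
            return ColumnRef(tok.value, pos=tok.pos)
        if tok.kind == "FIND":
            self._expect("LPAREN", "'(' after find")
            needle = self._expect("STRING", "quoted search string").value
            self._expect("COMMA", "',' between search string and column")
            column = self._expect("IDENT", "annotation column name").value
            self._expect("RPAREN", "')'")
            return FindCall(needle, column, pos=tok.pos)
        if tok.kind == "LPAREN":
            node = self.parse_or()
            self._expect("RPAREN", "')'")
            return node
        raise ParseError(f"unexpected {tok.value!r}", tok.pos)


# ---------------------------------------------------------------------------
# Kind checking (boolean vs numeric)
# ---------------------------------------------------------------------------


def _kind_of(node: ExpressionNode) -> str:
    """Return 'bool' or 'num'; raise ParseError on a kind mismatch."""
    if isinstance(node, (NumberLiteral, ColumnRef)):
        return "num"
    if isinstance(node, (Arith, Neg)):
        children = (node.left, node.right) if isinstance(node, Arith) else (node.child,)
        for c in children:
            if _kind_of(c) != "num":
                raise ParseError("arithmetic requires numeric operands", c.pos)
        return "num"
    if isinstance(node, Compare):
        for c in (node.left, node.right):
            if _kind_of(c) != "num":
                raise ParseError(
                    "comparison operands must be numeric, not boolean", c.pos
                )
        return "bool"
    if isinstance(node, (And, Or)):
        for c in (node.left, node.right):
            if _kind_of(c) != "bool":
                raise ParseError(
                    "AND/OR operands must be boolean (comparisons or find)", c.pos
                )
        return "bool"
    if isinstance(node, Not):
        if _kind_of(node.child) != "bool":
            raise ParseError("NOT requires a boolean operand", node.child.pos)
        return "bool"
    if isinstance(node, FindCall):
        return "bool"
    raise TypeError(f"unknown node {node!r}")


def parse_filter(text: str) -> ExpressionNode:
    """Parse a FILTER expression into a boolean-valued AST."""
    node = _Parser(text).parse_expression()
    if _kind_of(node) != "bool":
        raise ParseError(
            "a filter must be boolean-valued (use a comparison or find)", node.pos
        )
    return node


def parse_sorter(text: str) -> ExpressionNode:
    """Parse a SORTER expression into a purely arithmetic AST.

    Boolean constructs (comparisons, AND/OR/NOT, find) are rejected: a sorter
    produces one number per row, which fills the appended sorter column.
    """
    node = _Parser(text).parse_expression()
    if _contains_boolean(node):
        raise ParseError(
            "sorters are numeric: comparisons, AND/OR/NOT and find() "
            "are not allowed in a sorter",
            node.pos,
        )
    _kind_of(node)
    return node


def _contains_boolean(node: ExpressionNode) -> bool:
    if isinstance(node, (Compare, And, Or, Not, FindCall)):
        return True
    if isinstance(node, Arith):
        return _contains_boolean(node.left) or _contains_boolean(node.right)
    if isinstance(node, Neg):
        return _contains_boolean(node.child)
    return False


# ---------------------------------------------------------------------------
# Column validation and rendering
# ---------------------------------------------------------------------------


def validate_columns(node: ExpressionNode, table) -> list[str]:
    """Check every column reference in ``node`` against a joined table.

    Returns a list of findings (empty means valid): unknown columns by name,
    kind mismatches as ``"name (not an annotation column)"`` /
    ``"name (not a numeric column)"``. ``table`` needs ``numeric_columns``
    and ``annotation_columns`` attributes (see :class:`exprquery.datamodel.JoinedTable`).
    """
    numeric = set(table.numeric_columns)
    annotation = set(table.annotation_columns)
    findings: list[str] = []

    def walk(n: ExpressionNode) -> None:
        if isinstance(n, ColumnRef):
            if n.name in numeric:
                pass
            elif n.name in annotation:
                findings.append(f"{n.name} (not a numeric column)")
            else:
                findings.append(n.name)
        elif isinstance(n, FindCall):
            if n.column in annotation:
                pass
            elif n.column in numeric:
                findings.append(f"{n.column} (not an annotation column)")
            else:
                findings.append(n.column)
        elif isinstance(n, (Arith, Compare, And, Or)):
            walk(n.left)
            walk(n.right)
        elif isinstance(n, (Not, Neg)):
            walk(n.child)

    walk(node)
    return findings


def render(node: ExpressionNode) -> str:
    """Render an AST back to a fully parenthesized expression string.

    ``parse(render(x))`` is structurally identical to ``x``; used for saved
    queries and round-trip testing.
    """
    if isinstance(node, NumberLiteral):
        v = node.value
        return str(int(v)) if float(v).is_integer() else repr(v)
    if isinstance(node, ColumnRef):
        return node.name
    if isinstance(node, Arith):
        return f"({render(node.left)} {node.op} {render(node.right)})"
    if isinstance(node, Neg):
        return f"(-{render(node.child)})"
    if isinstance(node, Compare):
        return f"({render(node.left)} {node.op} {render(node.right)})"
    if isinstance(node, And):
        return f"({render(node.left)} AND {render(node.right)})"
    if isinstance(node, Or):
        return f"({render(node.left)} OR {render(node.right)})"
    if isinstance(node, Not):
        return f"(NOT {render(node.child)})"
    if isinstance(node, FindCall):
        if '"' not in node.needle:
            lit = f'"{node.needle}"'
        elif "'" not in node.needle:
            lit = f"'{node.needle}'"
        else:
            raise ValueError("needle contains both quote characters")
        return f"find({lit},{node.column})"
    raise TypeError(f"unknown node {node!r}")
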