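# Query language reference

A query has three independent parts:

| part    | kind               | empty means            |
|---------|--------------------|------------------------|
| FILTER  | boolean expression | every row matches      |
| SORTER  | numeric expression | keep input order, no sorter column |
| MAXROWS | non-negative int   | 0 = unlimited          |

plus a sort direction (descending by default; "inverted" = ascending).

## Grammar

```
expression  := or_expr
or_expr     := and_expr ( OR and_expr )*
and_expr    := cmp_expr ( AND cmp_expr )*
cmp_expr    := add_expr [ cmp_op add_expr ]          # non-associative
cmp_op      := ">" | "<" | ">=" | "<=" | "=" | "==" | "!="
add_expr    := mul_expr ( ("+" | "-") mul_expr )*
mul_expr    := unary ( ("*" | "/") unary )*
unary       := NOT unary | "-" unary | atom
atom        := NUMBER | IDENT | find_call | "(" expression ")"
find_call   := FIND "(" STRING "," IDENT ")"
```

Binding, tightest first: parentheses, unary `NOT`/`-`, `* /`, `+ -`,
comparisons, `AND`, `OR`.

## Lexical rules

- Keywords `and`, `or`, `not`, `find` are case-insensitive; column
  identifiers are case-sensitive and must match the table's column names
  exactly (`ICAP1` ≠ `icap1`).
- Whitespace is insignificant. `! =` (with space) is accepted as `!=`;
  `==` is accepted as `=`.
- String literals take single or double quotes, no escape sequences.
- Numbers: `10`, `1.5`, `.5` (no exponent notation).

## Semantics

- A FILTER must be boolean-valued; a SORTER must be purely arithmetic —
  comparisons, `AND`/`OR`/`NOT` and `find()` are rejected in sorters, and
  comparing two boolean subexpressions is a parse error.
- `find(needle, column)` is true iff *needle* occurs case-insensitively as
  a substring of the row's annotation cell (`description` or `goterms`).
  An empty or absent cell is a definite non-match.
- Missing numeric cells and division by zero make a subexpression
  *undefined*; comparisons with an undefined operand are undefined, and
  `AND`/`OR`/`NOT` follow Kleene three-valued logic. A row is selected only
  if its filter is definitely true. Undefined sorter values sort after all
  defined values.
- Numeric comparison is exact floating-point comparison (no epsilon).

## Examples

```
sg3>mes1
sg3/mes1>10
sg3>mes1 and mes1>dmrt1binding
sg3/mes1>10 and mes1>5
sg3>mes1 or mes1> dmrt1binding
(sg3>mes1 OR sg3>200) AND (dmrt1binding>20 AND eye<10)
sg3! = mes1
find("hox",description)
find("dna binding",goterms)
find("3677",goterms)
NOT find("DNA",description)
find('transcription factor',goterms) AND find('activator',goterms) AND dmrt1binding>10
```

Sorter examples: `(sg3+mes1)` (inverted, to put the lowest combined
expression first) and `gfp/((notch1+ICAP1)/2)` (control over the mean of
two treatments, descending).

Deliberately excluded: aggregates across rows, subqueries, string
comparison operators, modulo, and any SQL generation — expressions are
evaluated natively over the joined table.
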