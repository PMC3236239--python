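# Methods and design notes

## The model

`exprquery` treats an experiment as a set of delimited text tables, each
keyed by a stable identifier (transcript, gene or probe id) and carrying
numeric sample columns (normalized expression values, binding scores — any
quantitative per-feature measure) plus optional `description` and `goterms`
text annotations. Cross-dataset association is by *pre-joining*: all tables
named in a query are merged on the shared key into one wide table before
any expression is evaluated, so a filter can freely mix columns from
different experiments (`find('activator',goterms) AND dmrt1binding>10`).
A query is then a `WHERE`-like boolean filter, an `ORDER BY`-like numeric
sorter appended as the last result column, and a `LIMIT`-like row cap
applied after sorting.

## Evaluation semantics

Missing data is first-class. Any arithmetic or comparison touching a
missing cell, and any division by zero, yields *undefined*; the boolean
connectives follow Kleene three-valued logic (false dominates `AND`, true
dominates `OR`, `NOT` preserves undefined), mirroring SQL `NULL`
propagation in the database systems this style of querying comes from. A
row is selected only when its filter is definitely true. Two deliberate
asymmetries:

- `find()` is two-valued: a substring search over an absent annotation is a
  definite non-match, not an unknown — an unannotated gene should be
  excluded by `find(...)` and included by `NOT find(...)`.
- Undefined sorter values are not errors; those rows sort after all defined
  values (in either direction), keeping partially-missing data visible.

Numeric comparison is exact IEEE floating-point comparison, with no epsilon:
reproducibility is preferred over forgiveness, and fold-change thresholds on
normalized data do not meaningfully sit within rounding error of the cutoff.
Ties under the sorter keep input order (the sort is stable); truncation
happens strictly after sorting. The engine evaluates expressions vectorized
over pandas columns (booleans as 1.0/0.0/NaN float series); the test suite
checks it row-for-row against an independent naive per-row interpreter.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| join policy | `inner` | key set of the joined table: intersection (like a pre-joined SQL table) or `left` (first dataset's keys, absent cells missing) |
| sort direction | descending | largest sorter values first; ascending ("inverted") surfaces minima |
| maxrows | 0 | row cap after sorting; 0 = unlimited |
| missing tokens | `""`, `NA`, `NaN`, `null` | case-insensitive cell values read as missing |
| loader prefix | none | renames sample columns `<prefix>_<name>` to avoid cross-dataset collisions |

Column collisions between datasets are an error, never silently renamed;
duplicate keys within one dataset are likewise an error rather than being
aggregated, since the data model is one row per feature. Annotation columns
present in several datasets keep the first dataset's copy; later ones are
suffixed with their source name.

## GO annotation storage

A `goterms` cell serializes annotations as `GO:0003677|DNA binding;...` —
`;` between entries, `|` between the zero-padded 7-digit accession and the
name. This single choice makes all three documented GO query styles plain
substring matches on the cell: term text (`find("dna binding",goterms)`),
bare digits (`find("3677",goterms)` matches inside `GO:0003677`), and full
accessions. A separate user-supplied two-column TSV maps accessions to term
names for display (`goterm` command); lookups are total, returning an
"unknown term" sentinel for unmapped IDs. The ontology itself is never
bundled or downloaded.

## Synthetic fixtures

Real datasets of the kind this tool targets (stem-cell line deep-sequencing,
endothelial microarrays) are typically lab-internal, so the package carries
generators that reproduce their *structure* with planted, exactly countable
signal:

- **medaka-like** (defaults: 500 rows, seed 7): log-normal (µ=3, σ=1.5)
  sequencing-like counts for `sg3`, `mes1`, `eye`; exactly 25 planted rows
  carry both a "transcription factor" and an "activator" GO name, and
  exactly 10 of those have `dmrt1binding > 10` in the companion score table
  (the remaining planted rows are forced below 10). Background rows draw
  GO terms from a vocabulary partitioned so they can carry at most one of
  the two signal substrings, never both. About 1–2% of background
  expression cells are missing to exercise three-valued logic; planted rows
  stay complete so the ascending `(sg3+mes1)` sort over them is fully
  defined. The companion table omits five background transcripts so the
  inner join genuinely intersects.
- **huvec-like** (defaults: 400 rows, seed 3): uniform(10, 1000) array-like
  intensities for `notch1` and `ICAP1`; exactly 120 planted rows get
  `gfp` above both (factor 1.05–3 of the larger) and all others get `gfp`
  strictly below both (factor 0.2–0.95 of the smaller); one designated
  planted row's `gfp` is boosted so its `gfp/((notch1+ICAP1)/2)` ratio is a
  strict maximum, pinning the expected top hit of the descending sort.

The planted counts are constructed, not sampled, so recovery tests assert
exact equality, and generation is byte-deterministic given the seed. What
these fixtures do **not** emulate: read-mapping artifacts, normalization
bias, correlated expression, realistic GO co-annotation structure, or
real identifier namespaces. Passing tests therefore demonstrate the
correctness of parsing, joining, evaluation, sorting and serialization —
not any biological claim about real data.

Sizes were chosen to keep the default test run and the acceptance script in
the seconds range while leaving the row counts large enough (hundreds to a
thousand) that sorting, tie-breaking and missing-value paths are all
exercised; the interpreter-equivalence check runs 200 random queries
(AST depth ≤ 5) against a 1000-row fixture.

## Numerical and formatting choices

- Cells are written with full `repr` precision, so CSV/TSV round trips are
  lossless for float64; missing cells are written as empty strings.
- The sorter column is named `sorter_value` (suffixed with `_` in the
  unlikely event of a collision) and is always last.
- Query-store writes are atomic (temp file + rename), so a failed or
  conflicting save leaves the previous store intact.
- The grammar accepts `! =` with interior whitespace as `!=`, and both
  quote characters for string literals, to be maximally tolerant of
  hand-typed and typeset queries; only keywords are case-insensitive,
  identifiers never, to avoid ambiguity with column names like `ICAP1`.
- Unary `NOT` binds tighter than comparisons; since `NOT` requires a
  boolean operand, forms like `NOT sg3>mes1` are rejected with a kind error
  rather than silently reinterpreted — write `NOT (sg3>mes1)`.

## Known limitations

- One join key per joined table; a table cannot be simultaneously keyed by
  gene id and transcript id in the same query.
- No aggregates, subqueries, string comparisons or query optimization;
  tables at desk scale are scanned linearly.
- Plot support extracts per-column numeric series (missing values as gaps);
  rendering is left to the caller's plotting tool.
- The web/user-management layer of the original tool concept (accounts,
  tabbed browser UI, server-side plotting) is deliberately out of scope;
  the CLI subcommands and library functions replace it.
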