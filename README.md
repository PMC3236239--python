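# exprquery

A small query system for normalized transcriptome and microarray tables.
After primary analysis (mapping, normalization, statistics) a bench
scientist is usually handed large per-gene expression lists — and most of
the questions they want to ask are simple: *which transcripts are 10-fold
higher in one cell line than another? which of those are annotated as
transcription factors? which are also predicted targets of a specific
regulator?* `exprquery` answers such questions with a three-part query —
**FILTER**, **SORTER**, **MAXROWS** — evaluated natively over pre-joined
delimited text tables, with no database server, web stack or SQL involved.

Each dataset is a CSV/TSV table keyed by a gene/transcript/probe identifier,
with numeric sample columns and optional `description` / `goterms`
annotation columns. All datasets taking part in a query are first joined on
the shared identifier into one wide table (`inner` by default, `left`
optionally); the query then runs in three steps, equivalent to
`SELECT * WHERE <filter> ORDER BY <sorter> LIMIT <maxrows>`:

- **FILTER** — a boolean expression selecting rows, e.g.
  `sg3/mes1>10 and mes1>5` (fold-change threshold),
  `(sg3>mes1 OR sg3>200) AND (dmrt1binding>20 AND eye<10)`, or text
  predicates `find("dna binding",goterms)`, `NOT find("DNA",description)`.
  `find(needle, column)` is a case-insensitive substring test; GO
  annotations are stored as `GO:0003677|DNA binding;...`, so both
  `find("dna binding",goterms)` and the bare-ID form `find("3677",goterms)`
  work as plain text matches.
- **SORTER** — a numeric expression computed per matching row, appended as
  the last result column (`sorter_value`) and used for ordering, descending
  by default; `--ascending` inverts it, e.g. to surface the
  lowest-expressed candidates first.
- **MAXROWS** — a row limit applied strictly after sorting.

Missing values follow three-valued (Kleene/SQL-NULL) logic: arithmetic or
comparisons touching a missing cell (or a division by zero) are *undefined*,
`AND`/`OR`/`NOT` propagate undefined unless the other operand decides the
outcome, and only rows whose filter is definitely *true* are selected.
`find()` over an absent annotation is a definite non-match.

## Worked example

Generate a small synthetic medaka-like fixture (deep-sequencing counts for
the spermatogonial line `sg3` and embryonic line `mes1`, an `eye` tissue
control, plus a companion `dmrt1binding` score table joined on transcript
id), then ask for lowly-expressed activating transcription factors:

```
$ exprquery fixtures --profile medaka --rows 120 --seed 5 --out demo
$ exprquery query --config demo/registry.json \
    --filter "find('transcription factor',goterms) and find('activator',goterms)" \
    --sorter "(sg3+mes1)" --ascending --maxrows 3
matched 6 out of 115 rows
transcript_id,sg3,mes1,eye,description,goterms,dmrt1binding,sorter_value
ENSORLT00000000034,12.724,9.362,270.288,heat shock protein HSP 90-alpha,GO:0000981|...,13.595,22.086
ENSORLT00000000095,1.277,110.771,74.193,vascular endothelial growth factor receptor 2,GO:0003700|...,28.928,112.048
ENSORLT00000000053,60.768,78.439,7.072,40S ribosomal protein S3,GO:0003700|...,2.723,139.207
```

(`goterms` cells abbreviated here.) The `matched 6 out of 115 rows` report
goes to stderr; the CSV result to stdout or `--out`. The last column is the
computed sorter value — with `--ascending`, the first row is the candidate
with the smallest combined stem-cell expression, the natural pick for a
differentiation-induction screen. Adding `and dmrt1binding>10` to the filter
restricts the hits to transcripts with a high predicted DMRT1 binding score
from the joined companion table. Results can also be emitted as JSON
(`--format json`), and queries saved and replayed:

```
$ exprquery save medaka_tf --store queries.json --filter "..." --sorter "(sg3+mes1)" --ascending
$ exprquery query --config demo/registry.json --saved medaka_tf --store queries.json
```

The same pipeline is available as a library:

```python
from exprquery import QuerySpec, join_datasets, load_dataset, run_query

expr = load_dataset("demo/medaka_expression.tsv", id_column="transcript_id")
bind = load_dataset("demo/dmrt1_binding.tsv", id_column="transcript_id")
table = join_datasets([expr, bind], key="transcript_id")
result = run_query(table, QuerySpec("sg3/mes1>10", "sg3/mes1", maxrows=50))
print(result.matched, "of", result.total_scanned)
```

The query grammar is documented in `docs/query_language.md`, the model and
design notes in `docs/methods.md`.

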