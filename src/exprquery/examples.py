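"""Canonical example expressions of the query language.

These are the documented syntax examples of the language — fold-change
thresholds, AND/OR coupling, not-equal, and text predicates over
descriptions and GO terms — phrased against the medaka-like schema
(``sg3``, ``mes1``, ``dmrt1binding``, ``eye`` numeric; ``description``,
``goterms`` annotation). They double as a conformance suite: every entry
must tokenize, parse, validate against that schema and round-trip through
render → parse unchanged.
"""

from __future__ import annotations

__all__ = ["EXAMPLE_FILTERS", "EXAMPLE_SORTERS", "MEDAKA_SCHEMA_NUMERIC", "MEDAKA_SCHEMA_ANNOTATION"]

#: Documented filter examples (simple comparison, fold change, AND/OR
#: coupling, mixed parenthesized rules, not-equal in the spaced spelling,
#: description/GO-name/GO-id text searches, keyword exclusion, and the
#: combined cross-dataset stem-cell query).
EXAMPLE_FILTERS: list[str] = [
    "sg3>mes1",
    "sg3/mes1>10",
    "sg3>mes1 and mes1>dmrt1binding",
    "sg3/mes1>10 and mes1>5",
    "sg3>mes1 or mes1> dmrt1binding",
    "(sg3>mes1 OR sg3>200) AND (dmrt1binding>20 AND eye<10)",
    "sg3! = mes1",
    'find("hox",description)',
    'find("dna binding",goterms)',
    'find("3677",goterms)',
    'NOT find("DNA",description)',
    "find('transcription factor',goterms) AND find('activator',goterms) AND dmrt1binding>10",
]

#: Documented sorter examples: total stem-cell expression (inverted to put
#: the lowest-expressed candidates first) and the control-over-treatments
#: ratio used on the endothelial arrays.
EXAMPLE_SORTERS: list[str] = [
    "(sg3+mes1)",
    "gfp/((notch1+ICAP1)/2)",
]

MEDAKA_SCHEMA_NUMERIC = ["sg3", "mes1", "dmrt1binding", "eye"]
MEDAKA_SCHEMA_ANNOTATION = ["description", "goterms"]
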