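"""Synthetic expression fixtures with planted, exactly-countable signal.

Two generator profiles emulate the column structure of the tool's two case
studies so every pipeline stage is testable without any download:

* **medaka-like** — deep-sequencing counts for two stem-cell lines
  (``sg3`` spermatogonial, ``mes1`` embryonic) plus an ``eye`` tissue
  control, keyed by transcript id, with ``description``/``goterms``
  annotation; and a companion single-score table (``dmrt1binding``,
  predicted DMRT1 binding likelihood) joinable on the same transcript id.
* **huvec-like** — microarray intensities for three endothelial-cell
  conditions (``gfp`` control, ``notch1``, ``ICAP1``), keyed by probe id.

The planted structure is constructed, not sampled, so the counts are exact:
a chosen set of rows carries both a "transcription factor" and an
"activator" GO name (and a chosen subset of those has ``dmrt1binding > 10``);
a chosen set of HUVEC rows satisfies ``gfp>notch1 and gfp>ICAP1``, with one
designated row holding the strictly largest ``gfp/((notch1+ICAP1)/2)``
ratio. Everything else is drawn from distributions shaped like the real
thing (log-normal for sequencing counts, uniform for array intensities) but
guaranteed not to satisfy the planted predicates. A sidecar manifest records
the planted truth for assertions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, write_dataset
from .errors import FixtureError

__all__ = [
    "FixtureSpec",
    "medaka_spec",
    "huvec_spec",
    "generate_medaka_like",
    "generate_huvec_like",
    "write_fixture",
    "GO_VOCABULARY",
]

# GO vocabulary. The two signal groups exist so the planted queries are
# expressible; "safe" terms contain neither needle substring, so background
# rows can never satisfy the planted conjunction by accident.
_SIGNAL_TF = [
    ("GO:0003700", "transcription factor activity"),
    ("GO:0000981", "RNA polymerase II transcription factor activity"),
]
_SIGNAL_ACTIVATOR = [
    ("GO:0016563", "transcription activator activity"),
    ("GO:0001010", "RNA polymerase II activator recruiting activity"),
]
_SAFE_TERMS = [
    ("GO:0003677", "DNA binding"),
    ("GO:0005515", "protein binding"),
    ("GO:0005634", "nucleus"),
    ("GO:0005737", "cytoplasm"),
    ("GO:0005856", "cytoskeleton"),
    ("GO:0016020", "membrane"),
    ("GO:0005615", "extracellular space"),
    ("GO:0006412", "translation"),
    ("GO:0006397", "mRNA processing"),
    ("GO:0007049", "cell cycle"),
    ("GO:0006915", "apoptotic process"),
    ("GO:0008283", "cell proliferation"),
    ("GO:0007155", "cell adhesion"),
    ("GO:0016477", "cell migration"),
    ("GO:0001525", "angiogenesis"),
    ("GO:0030154", "cell differentiation"),
    ("GO:0007275", "multicellular organism development"),
    ("GO:0016301", "kinase activity"),
    ("GO:0004672", "protein kinase activity"),
    ("GO:0016787", "hydrolase activity"),
    ("GO:0008270", "zinc ion binding"),
    ("GO:0005509", "calcium ion binding"),
    ("GO:0005524", "ATP binding"),
    ("GO:0003723", "RNA binding"),
    ("GO:0045893", "positive regulation of transcription"),
    ("GO:0045892", "negative regulation of transcription"),
    ("GO:0007165", "signal transduction"),
    ("GO:0006810", "transport"),
    ("GO:0055114", "oxidation-reduction process"),
    ("GO:0008152", "metabolic process"),
]

GO_VOCABULARY = _SIGNAL_TF + _SIGNAL_ACTIVATOR + _SAFE_TERMS

_DESCRIPTIONS = [
    "homeobox protein HoxB4",
    "homeobox protein HoxA10",
    "paired box protein Pax6",
    "microphthalmia-associated transcription factor",
    "endothelial cell-specific molecule 1 precursor",
    "matrix metalloproteinase-10 preproprotein",
    "integrin beta-1 binding protein 1",
    "neurogenic locus notch homolog protein 1",
    "doublesex- and mab-3-related transcription factor 1",
    "heat shock protein HSP 90-alpha",
    "40S ribosomal protein S3",
    "tubulin alpha-1A chain",
    "actin, cytoplasmic 1",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "elongation factor 1-alpha",
    "uncharacterized protein, putative",
    "cadherin-5 precursor",
    "vascular endothelial growth factor receptor 2",
    "serine/threonine-protein kinase, putative",
    "zinc finger protein 42",
]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture.

    ``planted`` maps named query shapes to exact row counts; the medaka
    profile reads ``tf_activator`` (rows carrying both signal GO names) and
    ``tf_activator_dmrt1`` (subset of those with ``dmrt1binding > 10``), the
    HUVEC profile reads ``downregulated`` (rows with ``gfp`` above both
    treatment conditions). Generation is deterministic given ``seed``.
    """

    n_rows: int
    seed: int
    planted: dict[str, int] = field(default_factory=dict)
    go_vocabulary: list[tuple[str, str]] = field(default_factory=lambda: list(GO_VOCABULARY))

    def count(self, key: str) -> int:
        return int(self.planted.get(key, 0))

    def validate(self) -> None:
        if self.n_rows < 0:
            raise FixtureError("n_rows must be >= 0")
        for k, v in self.planted.items():
            if v < 0:
                raise FixtureError(f"planted count {k!r} must be >= 0")
            if v > self.n_rows:
                raise FixtureError(
                    f"planted count {k!r}={v} exceeds n_rows={self.n_rows}"
                )
        sub = self.count("tf_activator_dmrt1")
        if sub > self.count("tf_activator"):
            raise FixtureError(
                "tf_activator_dmrt1 cannot exceed tf_activator"
            )


def medaka_spec(n_rows: int = 500, planted: int = 25, planted_binding: int = 10, seed: int = 7) -> FixtureSpec:
    """Default study conditions for the medaka-like fixture."""
    return FixtureSpec(
        n_rows=n_rows,
        seed=seed,
        planted={"tf_activator": planted, "tf_activator_dmrt1": planted_binding},
    )


def huvec_spec(n_rows: int = 400, planted: int = 120, seed: int = 3) -> FixtureSpec:
    """Default study conditions for the HUVEC-like fixture."""
    return FixtureSpec(n_rows=n_rows, seed=seed, planted={"downregulated": planted})


def _goterm_cell(rng: np.random.Generator, terms: list[tuple[str, str]]) -> str:
    return ";".join(f"{gid}|{name}" for gid, name in terms)


def _background_terms(rng: np.random.Generator) -> list[tuple[str, str]]:
    """Background goterms: safe terms plus at most ONE signal group's term."""
    k = int(rng.integers(0, 4))
    idx = rng.choice(len(_SAFE_TERMS), size=k, replace=False)
    terms = [_SAFE_TERMS[i] for i in sorted(idx)]
    roll = rng.random()
    if roll < 0.15:
        terms.append(_SIGNAL_TF[int(rng.integers(0, len(_SIGNAL_TF)))])
    elif roll < 0.30:
        terms.append(_SIGNAL_ACTIVATOR[int(rng.integers(0, len(_SIGNAL_ACTIVATOR)))])
    return terms


def generate_medaka_like(
    spec: FixtureSpec,
) -> tuple[ExpressionDataset, ExpressionDataset, dict]:
    """Build the medaka-like expression table plus the DMRT1 score companion.

    Returns ``(expression, binding, manifest)``. Exactly
    ``planted["tf_activator"]`` rows carry both signal GO names, and exactly
    ``planted["tf_activator_dmrt1"]`` of those have ``dmrt1binding > 10``
    (the remaining planted rows are forced below 10). The companion table
    omits a handful of background transcripts so the inner join is a real
    intersection, never touching planted rows.
    """
    spec.validate()
    n = spec.n_rows
    n_planted = spec.count("tf_activator")
    n_sub = spec.count("tf_activator_dmrt1")
    rng = np.random.default_rng(spec.seed)

    ids = [f"ENSORLT{i + 1:011d}" for i in range(n)]
    sg3 = np.round(rng.lognormal(3.0, 1.5, n), 3)
    mes1 = np.round(rng.lognormal(3.0, 1.5, n), 3)
    eye = np.round(rng.lognormal(3.0, 1.5, n), 3)

    planted_idx = np.sort(rng.choice(n, size=n_planted, replace=False))
    planted_set = set(planted_idx.tolist())
    sub_idx = np.sort(rng.choice(planted_idx, size=n_sub, replace=False)) if n_planted else np.array([], dtype=int)
    sub_set = set(sub_idx.tolist())

    # sequencing dropouts in the background only; planted rows stay complete
    # so the ascending (sg3+mes1) sort over them is fully defined
    for col in (sg3, mes1):
        miss = rng.random(n) < 0.01
        miss[list(planted_set)] = False
        col[miss] = np.nan
    eye_miss = rng.random(n) < 0.02
    eye[eye_miss] = np.nan

    goterms = []
    descriptions = []
    for i in range(n):
        if i in planted_set:
            terms = [
                _SIGNAL_TF[int(rng.integers(0, len(_SIGNAL_TF)))],
                _SIGNAL_ACTIVATOR[int(rng.integers(0, len(_SIGNAL_ACTIVATOR)))],
            ]
            extra = int(rng.integers(0, 2))
            if extra:
                terms.append(_SAFE_TERMS[int(rng.integers(0, len(_SAFE_TERMS)))])
        else:
            terms = _background_terms(rng)
        goterms.append(_goterm_cell(rng, terms))
        descriptions.append(_DESCRIPTIONS[int(rng.integers(0, len(_DESCRIPTIONS)))])

    binding = np.round(rng.uniform(0.0, 30.0, n), 3)
    if n_planted:
        binding[planted_idx] = np.round(rng.uniform(0.0, 9.5, n_planted), 3)
    if n_sub:
        binding[sub_idx] = np.round(rng.uniform(10.5, 40.0, n_sub), 3)

    expression = ExpressionDataset(
        name="medaka_expression",
        id_column="transcript_id",
        data=pd.DataFrame(
            {
                "transcript_id": pd.Series(ids, dtype=object),
                "sg3": pd.Series(sg3, dtype=float),
                "mes1": pd.Series(mes1, dtype=float),
                "eye": pd.Series(eye, dtype=float),
                "description": pd.Series(descriptions, dtype=object),
                "goterms": pd.Series(goterms, dtype=object),
            }
        ),
        sample_columns=["sg3", "mes1", "eye"],
        annotation_columns=["description", "goterms"],
    )

    # companion binding table: drop a few background transcripts so an inner
    # join genuinely intersects
    background = [i for i in range(n) if i not in planted_set]
    n_drop = min(5, len(background))
    drop = set(rng.choice(background, size=n_drop, replace=False).tolist()) if n_drop else set()
    keep = [i for i in range(n) if i not in drop]
    binding_ds = ExpressionDataset(
        name="dmrt1_binding",
        id_column="transcript_id",
        data=pd.DataFrame(
            {
                "transcript_id": pd.Series([ids[i] for i in keep], dtype=object),
                "dmrt1binding": pd.Series(binding[keep], dtype=float),
            }
        ),
        sample_columns=["dmrt1binding"],
    )

    manifest = {
        "profile": "medaka",
        "n_rows": n,
        "seed": spec.seed,
        "planted_tf_activator": [ids[i] for i in planted_idx],
        "planted_tf_activator_dmrt1": [ids[i] for i in sub_idx],
        "dropped_from_binding": sorted(ids[i] for i in drop),
        "counts": {"tf_activator": n_planted, "tf_activator_dmrt1": n_sub},
    }
    return expression, binding_ds, manifest


def generate_huvec_like(spec: FixtureSpec) -> tuple[ExpressionDataset, dict]:
    """Build the HUVEC-like microarray table.

    Exactly ``planted["downregulated"]`` rows satisfy
    ``gfp>notch1 and gfp>ICAP1``; one designated planted row is constructed
    to hold the strictly largest ``gfp/((notch1+ICAP1)/2)`` ratio, so a
    descending sort on that term must list it first.
    """
    spec.validate()
    n = spec.n_rows
    n_planted = spec.count("downregulated")
    rng = np.random.default_rng(spec.seed)

    ids = [f"ILMN_{1000000 + i}" for i in range(n)]
    notch1 = np.round(rng.uniform(10.0, 1000.0, n), 3)
    icap1 = np.round(rng.uniform(10.0, 1000.0, n), 3)

    planted_idx = np.sort(rng.choice(n, size=n_planted, replace=False))
    planted_set = set(planted_idx.tolist())

    gfp = np.empty(n)
    lo = np.minimum(notch1, icap1)
    hi = np.maximum(notch1, icap1)
    up = rng.uniform(1.05, 3.0, n)
    down = rng.uniform(0.2, 0.95, n)
    for i in range(n):
        gfp[i] = hi[i] * up[i] if i in planted_set else lo[i] * down[i]
    gfp = np.round(gfp, 3)

    designated = None
    if n_planted:
        designated = int(planted_idx[0])
        avg = (notch1 + icap1) / 2.0
        ratios = gfp[planted_idx] / avg[planted_idx]
        others = [i for i in planted_idx if i != designated]
        max_other = float(np.max(gfp[others] / avg[others])) if others else 1.05
        boosted = max(avg[designated] * max_other * 1.25, hi[designated] * 1.1)
        gfp[designated] = np.round(boosted, 3)

    goterms = []
    descriptions = []
    for i in range(n):
        goterms.append(_goterm_cell(rng, _background_terms(rng)))
        descriptions.append(_DESCRIPTIONS[int(rng.integers(0, len(_DESCRIPTIONS)))])

    dataset = ExpressionDataset(
        name="huvec_array",
        id_column="probe_id",
        data=pd.DataFrame(
            {
                "probe_id": pd.Series(ids, dtype=object),
                "gfp": pd.Series(gfp, dtype=float),
                "notch1": pd.Series(notch1, dtype=float),
                "ICAP1": pd.Series(icap1, dtype=float),
                "description": pd.Series(descriptions, dtype=object),
                "goterms": pd.Series(goterms, dtype=object),
            }
        ),
        sample_columns=["gfp", "notch1", "ICAP1"],
        annotation_columns=["description", "goterms"],
    )

    manifest = {
        "profile": "huvec",
        "n_rows": n,
        "seed": spec.seed,
        "planted_downregulated": [ids[i] for i in planted_idx],
        "designated_top": ids[designated] if designated is not None else None,
        "counts": {"downregulated": n_planted},
    }
    return dataset, manifest


def write_fixture(out_dir: str | Path, profile: str, spec: FixtureSpec) -> list[Path]:
    """Write a fixture profile to ``out_dir``: TSV tables, the truth manifest
    and a dataset registry ready for the CLI. Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if profile == "medaka":
        expression, binding, manifest = generate_medaka_like(spec)
        tables = [(expression, "medaka_expression.tsv"), (binding, "dmrt1_binding.tsv")]
        key = "transcript_id"
    elif profile == "huvec":
        dataset, manifest = generate_huvec_like(spec)
        tables = [(dataset, "huvec_array.tsv")]
        key = "probe_id"
    else:
        raise FixtureError(f"unknown fixture profile {profile!r}")

    registry = []
    for ds, fname in tables:
        path = out / fname
        write_dataset(ds, path)
        written.append(path)
        registry.append({"name": ds.name, "path": fname, "id_column": key, "delimiter": "\t"})

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    written.append(manifest_path)

    registry_path = out / "registry.json"
    with open(registry_path, "w", encoding="utf-8") as fh:
        json.dump({"datasets": registry}, fh, indent=2)
        fh.write("\n")
    written.append(registry_path)
    return written
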