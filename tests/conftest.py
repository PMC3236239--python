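import pandas as pd
import pytest

from exprquery import (
    ExpressionDataset,
    generate_huvec_like,
    generate_medaka_like,
    huvec_spec,
    join_datasets,
    medaka_spec,
)


@pytest.fixture(scope="session")
def medaka():
    """Default medaka-like fixture: expression + binding datasets + manifest."""
    return generate_medaka_like(medaka_spec())


@pytest.fixture(scope="session")
def medaka_table(medaka):
    expression, binding, _ = medaka
    return join_datasets([expression, binding], key="transcript_id")


@pytest.fixture(scope="session")
def huvec():
    return generate_huvec_like(huvec_spec())


@pytest.fixture(scope="session")
def huvec_table(huvec):
    dataset, _ = huvec
    return join_datasets([dataset], key="probe_id")


def make_dataset(name, id_column, rows, sample_columns, annotation_columns=()):
    """Hand-build a small ExpressionDataset from a list of row dicts."""
    columns = list(rows[0]) if rows else [id_column, *sample_columns, *annotation_columns]
    data = {}
    for c in columns:
        values = [r.get(c) for r in rows]
        if c in sample_columns:
            data[c] = pd.Series(
                [float("nan") if v is None else float(v) for v in values], dtype=float
            )
        else:
            data[c] = pd.Series(["" if v is None else v for v in values], dtype=object)
    return ExpressionDataset(
        name=name,
        id_column=id_column,
        data=pd.DataFrame(data, columns=columns),
        sample_columns=list(sample_columns),
        annotation_columns=list(annotation_columns),
    )


@pytest.fixture
def tiny_table():
    """Five-row joined table with known values, one missing cell, annotations."""
    ds = make_dataset(
        "tiny",
        "transcript_id",
        [
            {"transcript_id": "t1", "sg3": 50.0, "mes1": 4.0, "eye": 1.0,
             "description": "homeobox protein HoxB4",
             "goterms": "GO:0003677|DNA binding"},
            {"transcript_id": "t2", "sg3": 300.0, "mes1": None, "eye": 2.0,
             "description": "kinase, putative",
             "goterms": "GO:0016301|kinase activity"},
            {"transcript_id": "t3", "sg3": 10.0, "mes1": 10.0, "eye": 0.0,
             "description": "", "goterms": ""},
            {"transcript_id": "t4", "sg3": 7.0, "mes1": 2.0, "eye": 5.0,
             "description": "transcription activator",
             "goterms": "GO:0016563|transcription activator activity"},
            {"transcript_id": "t5", "sg3": 50.0, "mes1": 4.0, "eye": 9.0,
             "description": "protein, putative", "goterms": ""},
        ],
        sample_columns=["sg3", "mes1", "eye"],
        annotation_columns=["description", "goterms"],
    )
    return join_datasets([ds], key="transcript_id")
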