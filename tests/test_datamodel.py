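"""Dataset loading, GO annotation handling, joining and record links."""

import math

import pytest

from exprquery.datamodel import (
    DEFAULT_LINK_TEMPLATES,
    UNKNOWN_TERM,
    GoAnnotation,
    goterm_name,
    join_datasets,
    load_dataset,
    load_go_mapping,
    load_registry,
    normalize_go_id,
    parse_goterms,
    record_link,
    serialize_goterms,
    write_dataset,
)
from exprquery.errors import ConfigError, InputError, JoinError, SchemaError

from .conftest import make_dataset

TSV = (
    "transcript_id\tsg3\tmes1\tdescription\tgoterms\n"
    "t1\t50\t4\thomeobox protein HoxB4\tGO:0003677|DNA binding\n"
    "t2\t300\tNA\tkinase, putative\t\n"
    "t3\t10\t10\t\tGO:0016301|kinase activity\n"
)


@pytest.fixture
def tsv_path(tmp_path):
    p = tmp_path / "medaka.tsv"
    p.write_text(TSV)
    return p


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def test_load_detects_numeric_and_annotation_columns(tsv_path):
    ds = load_dataset(tsv_path, id_column="transcript_id")
    assert ds.sample_columns == ["sg3", "mes1"]
    assert ds.annotation_columns == ["description", "goterms"]
    assert ds.keys == ["t1", "t2", "t3"]
    assert ds.data["sg3"].tolist() == [50.0, 300.0, 10.0]


def test_load_na_token_is_missing_but_column_stays_numeric(tsv_path):
    ds = load_dataset(tsv_path, id_column="transcript_id")
    assert "mes1" in ds.sample_columns
    assert math.isnan(ds.data["mes1"].iloc[1])


@pytest.mark.parametrize("token", ["", "NA", "na", "NaN", "null", "NULL"])
def test_missing_tokens_round_trip(tmp_path, token):
    p = tmp_path / "t.csv"
    p.write_text(f"id,x\na,{token}\nb,2\n")
    ds = load_dataset(p, id_column="id")
    assert ds.sample_columns == ["x"]
    assert math.isnan(ds.data["x"].iloc[0])
    # write → load preserves the missing cell and the numeric value
    out = tmp_path / "out.csv"
    write_dataset(ds, out)
    ds2 = load_dataset(out, id_column="id")
    assert math.isnan(ds2.data["x"].iloc[0])
    assert ds2.data["x"].iloc[1] == 2.0


def test_load_write_load_round_trip_preserves_cells_and_order(tsv_path, tmp_path):
    ds = load_dataset(tsv_path, id_column="transcript_id")
    out = tmp_path / "round.tsv"
    write_dataset(ds, out)
    ds2 = load_dataset(out, id_column="transcript_id")
    assert ds2.data.columns.tolist() == ds.data.columns.tolist()
    assert ds2.data.equals(ds.data)


def test_load_missing_id_column_is_schema_error(tsv_path):
    with pytest.raises(SchemaError):
        load_dataset(tsv_path, id_column="gene_id")


def test_load_duplicate_headers_is_schema_error(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text("id,x,x\na,1,2\n")
    with pytest.raises(SchemaError):
        load_dataset(p, id_column="id")


def test_load_empty_file_is_input_error(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("")
    with pytest.raises(InputError):
        load_dataset(p, id_column="id")


def test_load_prefix_renames_sample_columns(tsv_path):
    ds = load_dataset(tsv_path, id_column="transcript_id", prefix="seq")
    assert ds.sample_columns == ["seq_sg3", "seq_mes1"]
    assert ds.annotation_columns == ["description", "goterms"]


def test_annotation_headers_match_case_insensitively(tmp_path):
    p = tmp_path / "caps.csv"
    p.write_text("id,x,Description,GOTERMS\na,1,some protein,GO:0003677|DNA binding\n")
    ds = load_dataset(p, id_column="id")
    assert ds.annotation_columns == ["description", "goterms"]


def test_empty_identifier_is_schema_error(tmp_path):
    p = tmp_path / "noid.csv"
    p.write_text("id,x\na,1\n,2\n")
    with pytest.raises(SchemaError):
        load_dataset(p, id_column="id")


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------


def test_parse_goterms_well_formed_cell():
    cell = "GO:0003677|DNA binding;GO:0045893|positive regulation of transcription"
    anns = parse_goterms(cell)
    assert anns == [
        GoAnnotation("GO:0003677", "DNA binding"),
        GoAnnotation("GO:0045893", "positive regulation of transcription"),
    ]
    assert serialize_goterms(anns) == cell


def test_parse_goterms_empty_cell():
    assert parse_goterms("") == []


def test_parse_goterms_id_substring_is_searchable():
    # the bare-digit GO query works because the id keeps its zero padding
    [ann] = parse_goterms("GO:0003677|DNA binding")
    assert "3677" in ann.serialize()


def test_parse_goterms_malformed_entry_kept_as_name_only(caplog):
    with caplog.at_level("WARNING"):
        anns = parse_goterms("just a term name")
    assert anns == [GoAnnotation(None, "just a term name")]
    assert "malformed" in caplog.text


def test_normalize_go_id():
    assert normalize_go_id("3677") == "GO:0003677"
    assert normalize_go_id("GO:0003677") == "GO:0003677"
    with pytest.raises(ValueError):
        normalize_go_id("not-an-id")


def test_goterm_name_lookup_is_total(tmp_path):
    p = tmp_path / "go.tsv"
    p.write_text("GO:0003677\tDNA binding\n3700\ttranscription factor activity\n")
    mapping = load_go_mapping(p)
    assert goterm_name("GO:0003677", mapping) == "DNA binding"
    assert goterm_name("3677", mapping) == "DNA binding"
    assert goterm_name("3700", mapping) == "transcription factor activity"
    assert goterm_name("GO:9999999", mapping) == UNKNOWN_TERM
    assert goterm_name("garbage", mapping) == UNKNOWN_TERM


# ---------------------------------------------------------------------------
# Joining
# ---------------------------------------------------------------------------


def _ds(name, keys, col, values):
    rows = [{"gene_id": k, col: v} for k, v in zip(keys, values)]
    return make_dataset(name, "gene_id", rows, sample_columns=[col])


def test_inner_join_intersects_key_sets():
    a = _ds("a", ["g1", "g2", "g3"], "x", [1, 2, 3])
    b = _ds("b", ["g2", "g3", "g4"], "y", [20, 30, 40])
    t = join_datasets([a, b], key="gene_id")
    assert t.data["gene_id"].tolist() == ["g2", "g3"]
    assert t.numeric_columns == ["x", "y"]
    assert t.provenance == {"x": "a", "y": "b"}


def test_inner_join_is_order_insensitive_on_rows_and_cells():
    a = _ds("a", ["g1", "g2", "g3"], "x", [1, 2, 3])
    b = _ds("b", ["g3", "g2"], "y", [30, 20])
    t_ab = join_datasets([a, b], key="gene_id")
    t_ba = join_datasets([b, a], key="gene_id")
    rows_ab = {
        r["gene_id"]: (r["x"], r["y"]) for r in t_ab.data.to_dict("records")
    }
    rows_ba = {
        r["gene_id"]: (r["x"], r["y"]) for r in t_ba.data.to_dict("records")
    }
    assert rows_ab == rows_ba


def test_join_size_bounds():
    a = _ds("a", ["g1", "g2", "g3"], "x", [1, 2, 3])
    b = _ds("b", ["g2", "g3", "g4", "g5"], "y", [2, 3, 4, 5])
    assert len(join_datasets([a, b], key="gene_id")) <= min(len(a), len(b))
    assert len(join_datasets([a, b], key="gene_id", policy="left")) == len(a)


def test_left_join_leaves_absent_cells_missing():
    a = _ds("a", ["g1", "g2"], "x", [1, 2])
    b = _ds("b", ["g2"], "y", [20])
    t = join_datasets([a, b], key="gene_id", policy="left")
    assert math.isnan(t.data["y"].iloc[0])
    assert t.data["y"].iloc[1] == 20.0


def test_disjoint_inner_join_is_empty_not_an_error():
    a = _ds("a", ["g1"], "x", [1])
    b = _ds("b", ["g2"], "y", [2])
    t = join_datasets([a, b], key="gene_id")
    assert len(t) == 0
    assert t.columns == ["gene_id", "x", "y"]


def test_join_duplicate_keys_within_dataset_is_error():
    a = _ds("a", ["g1", "g1"], "x", [1, 2])
    with pytest.raises(JoinError):
        join_datasets([a], key="gene_id")


def test_join_colliding_sample_columns_is_error():
    a = _ds("a", ["g1"], "x", [1])
    b = _ds("b", ["g1"], "x", [2])
    with pytest.raises(JoinError):
        join_datasets([a, b], key="gene_id")


def test_join_wrong_key_is_error():
    a = _ds("a", ["g1"], "x", [1])
    with pytest.raises(JoinError):
        join_datasets([a], key="transcript_id")


def test_join_duplicate_annotation_columns_suffixed_with_source():
    rows_a = [{"gene_id": "g1", "x": 1.0, "description": "from a"}]
    rows_b = [{"gene_id": "g1", "y": 2.0, "description": "from b"}]
    a = make_dataset("a", "gene_id", rows_a, ["x"], ["description"])
    b = make_dataset("b", "gene_id", rows_b, ["y"], ["description"])
    t = join_datasets([a, b], key="gene_id")
    assert "description" in t.columns and "description_b" in t.columns
    assert t.data["description"].iloc[0] == "from a"
    assert t.data["description_b"].iloc[0] == "from b"
    assert set(t.annotation_columns) == {"description", "description_b"}


# ---------------------------------------------------------------------------
# Record links and registry
# ---------------------------------------------------------------------------


def test_record_link_substitutes_key():
    url = record_link({"tid": "ENSORLT00000000001"}, "tid", "ensembl")
    assert url == DEFAULT_LINK_TEMPLATES["ensembl"].format(id="ENSORLT00000000001")


def test_record_link_percent_encodes_reserved_characters():
    url = record_link({"tid": "a/b c"}, "tid", "ensembl")
    assert url.endswith("a%2Fb%20c")


def test_record_link_unknown_source_is_config_error():
    with pytest.raises(ConfigError):
        record_link({"tid": "x"}, "tid", "refseq", templates={"ensembl": "u/{id}"})


def test_registry_resolves_relative_paths(tmp_path):
    (tmp_path / "t.csv").write_text("id,x\na,1\n")
    reg = tmp_path / "registry.json"
    reg.write_text('{"datasets": [{"name": "t", "path": "t.csv", "id_column": "id"}]}')
    registry = load_registry(reg)
    assert registry["t"]["path"] == str(tmp_path / "t.csv")
    with pytest.raises(ConfigError):
        load_registry(tmp_path / "missing.json")
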