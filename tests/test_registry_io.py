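import pytest
from hypothesis import given, settings, strategies as st

from sbpkb.fixtures import FixtureConfig, generate
from sbpkb.registry_io import (
    FeatureRecord,
    PartRecord,
    RecordValidationError,
    TableParseError,
    normalize_status,
    read_features_table,
    read_features_xml,
    read_parts_table,
    read_parts_xml,
    validate_records,
    write_features_table,
    write_parts_table,
)

PART_HEADER = (
    "id\tname\ttype\tshort_desc\tlong_desc\tauthor\towner_id\tstatus\t"
    "date\tcategories\tsequence\n"
)
FEATURE_HEADER = "id\tpart_id\tlabel\tfeature_type\tstart\tend\tdirection\n"


def test_parses_registry_style_row(tmp_path):
    """A typical promoter row comes back with all fields normalized."""
    path = tmp_path / "parts.tsv"
    path.write_text(
        PART_HEADER
        + "9598\tBBa_I746365\tRegulatory\tPLL promoter from P4 phage\t"
        "Long text.\tStefan Milde\t2122\tAvailable\t9/11/2007\t"
        "//promoter //regulation/positive\tCGCTTTATTTTGTGAATATTTT\n"
    )
    (record,) = read_parts_table(path)
    assert record.registry_id == 9598
    assert record.name == "BBa_I746365"
    assert record.status == "Available"
    assert record.categories == ("//promoter", "//regulation/positive")
    assert record.dna_sequence == "cgctttattttgtgaatatttt"  # lower-cased


def test_header_only_files_yield_empty_lists(tmp_path):
    p = tmp_path / "p.tsv"
    p.write_text(PART_HEADER)
    f = tmp_path / "f.tsv"
    f.write_text(FEATURE_HEADER)
    assert read_parts_table(p) == []
    assert read_features_table(f) == []


def test_generator_tables_roundtrip_field_by_field(tmp_path):
    """Re-reading emitted tables recovers the generator's records exactly."""
    fx = generate(
        FixtureConfig(n_parts=10, seed=4, mean_features_per_part=2.0),
        tmp_path,
    )
    assert read_parts_table(fx.parts_path) == fx.parts
    assert read_features_table(fx.features_path) == fx.features
    # write(read(T)) re-reads identically as well
    again_p = tmp_path / "again_parts.tsv"
    again_f = tmp_path / "again_features.tsv"
    write_parts_table(read_parts_table(fx.parts_path), again_p)
    write_features_table(read_features_table(fx.features_path), again_f)
    assert read_parts_table(again_p) == fx.parts
    assert read_features_table(again_f) == fx.features


@settings(max_examples=10)
@given(seed=st.integers(min_value=0, max_value=2**20))
def test_parsing_is_total_on_generator_output(seed, tmp_path_factory):
    """Any seed's emitted tables parse with zero errors."""
    out = tmp_path_factory.mktemp("gen")
    fx = generate(FixtureConfig(n_parts=15, seed=seed), out)
    parts = read_parts_table(fx.parts_path)
    features = read_features_table(fx.features_path)
    assert len(parts) == 15
    assert all(p.sequence_is_clean for p in parts)
    assert len(features) == len(fx.features)


def test_malformed_row_names_the_line(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text(PART_HEADER + "1\tBBa_X\tDNA\n")
    with pytest.raises(TableParseError, match="line 2"):
        read_parts_table(path)


def test_duplicate_registry_id_raises(tmp_path):
    row = "7\tBBa_X\tDNA\t\t\ta\t1\tAvailable\t1/1/2005\t\tacgt\n"
    path = tmp_path / "p.tsv"
    path.write_text(PART_HEADER + row + row)
    with pytest.raises(RecordValidationError, match="duplicate registry id 7"):
        read_parts_table(path)


def test_feature_position_errors(tmp_path):
    path = tmp_path / "f.tsv"
    path.write_text(FEATURE_HEADER + "1\t7\tTetR\toperator\t9\t4\tforward\n")
    with pytest.raises(RecordValidationError, match="start <= end"):
        read_features_table(path)
    path.write_text(FEATURE_HEADER + "1\t7\tTetR\toperator\tx\t4\tforward\n")
    with pytest.raises(TableParseError, match="start must be an integer"):
        read_features_table(path)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("available", "Available"),
        ("DELETED", "Deleted"),
        (" Sent ", "Sent"),
        ("Informational", "Informational"),
    ],
)
def test_status_normalization(raw, expected):
    assert normalize_status(raw) == expected


def _part(rid, seq="acgt", status="Available"):
    return PartRecord(
        registry_id=rid, name=f"BBa_{rid}", dna_sequence=seq, status=status
    )


def test_validate_records_counts_directly():
    parts = [_part(1, seq=""), _part(2, seq=""), _part(3), _part(3)]
    features = [
        FeatureRecord(feature_id=9, part_registry_id=99, label="x"),
        FeatureRecord(feature_id=10, part_registry_id=3, label="y"),
    ]
    report = validate_records(parts, features)
    assert report.missing_sequence_ids == (1, 2)
    assert report.orphan_features == (9,)
    assert report.duplicate_ids == (3,)
    assert report.has_defects


def test_validate_flags_nonstandard_status_and_bad_alphabet():
    parts = [_part(1, status="Informational"), _part(2, seq="acgtn")]
    report = validate_records(parts, [])
    assert report.nonstandard_status == ((1, "Informational"),)
    assert report.invalid_sequence_ids == (2,)


def test_report_matches_injected_defect_manifest(tmp_path):
    """The generator's injection manifest is exactly what validation finds."""
    fx = generate(
        FixtureConfig(
            n_parts=40, seed=9, n_orphan_features=3, n_nonstandard_status=2
        ),
        tmp_path,
    )
    parts = read_parts_table(fx.parts_path)
    features = read_features_table(fx.features_path)
    report = validate_records(parts, features)
    defects = fx.manifest["defects"]
    assert sorted(report.orphan_features) == defects["orphan_feature_ids"]
    assert sorted(report.missing_sequence_ids) == defects["missing_sequence_ids"]
    assert sorted(rid for rid, _ in report.nonstandard_status) == defects[
        "nonstandard_status_ids"
    ]
    assert report.duplicate_ids == ()


def test_xml_dump_shape_reads_to_same_records(tmp_path):
    fields_p = {
        "id": "9598", "name": "BBa_I746365", "type": "Regulatory",
        "short_desc": "PLL", "long_desc": "Long.", "author": "Stefan Milde",
        "owner_id": "2122", "status": "Available", "date": "9/11/2007",
        "categories": "//promoter //direction/forward", "sequence": "ACGT",
    }
    def row(cells):
        body = "".join(
            f'<field name="{k}">{v}</field>' for k, v in cells.items()
        )
        return f"<row>{body}</row>"

    px = tmp_path / "parts.xml"
    px.write_text(f"<resultset>{row(fields_p)}</resultset>")
    (record,) = read_parts_xml(px)
    assert record.name == "BBa_I746365"
    assert record.categories == ("//promoter", "//direction/forward")
    assert record.dna_sequence == "acgt"

    fx = tmp_path / "features.xml"
    fields_f = {
        "id": "1", "part_id": "9598", "label": "OR1 lambda",
        "feature_type": "operator", "start": "5", "end": "16",
        "direction": "forward",
    }
    fx.write_text(f"<resultset>{row(fields_f)}</resultset>")
    (feat,) = read_features_xml(fx)
    assert (feat.label, feat.start, feat.end) == ("OR1 lambda", 5, 16)
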