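import pytest
from rdflib import Literal, RDF

from sbpkb.category_ontology import build_tree, parse_category
from sbpkb.fixtures import DESCRIBE_EXAMPLE_PART, FixtureConfig, generate
from sbpkb.registry_io import FeatureRecord, PartRecord
from sbpkb.sbol_model import (
    CORE,
    PR,
    FeatureBoundsWarning,
    UnknownCategoryError,
    build_knowledgebase,
    class_axiom_statements,
    feature_to_statements,
    mint_id,
    mint_uri,
    parse_graph,
    part_to_statements,
    serialize,
)

from conftest import build_fixture_kg


def test_minting_is_deterministic_and_injective():
    assert mint_id("part", 9598, "BBa_I746365") == mint_id(
        "part", 9598, "BBa_I746365"
    )
    assert mint_id("part", 1, "A") != mint_id("part", 2, "A")
    assert mint_id("part", 1, "A") != mint_id("annotation", 1, "A")
    minted = {
        mint_id("part", i, f"BBa_X{i}") for i in range(1, 10_001)
    }
    assert len(minted) == 10_000


def test_minted_ids_are_legal_local_names():
    local = mint_id("feature", 42, "OR1 lambda")
    assert local[0] == "r"
    assert local.isalnum()


@pytest.fixture()
def example_part_and_tree():
    record = PartRecord(**DESCRIBE_EXAMPLE_PART)
    tree = build_tree(parse_category(c) for c in record.categories)
    return record, tree


def test_part_statements_cover_published_types(example_part_and_tree):
    """The DESCRIBE example part gets all five category types plus Part."""
    record, tree = example_part_and_tree
    triples = part_to_statements(record, tree)
    subject = mint_uri("part", record.registry_id, record.name)
    types = {o for s, p, o in triples if s == subject and p == RDF.type}
    assert {
        CORE.Part,
        PR.promoter,
        PR.positive_regulation,
        PR.forward_direction,
        PR.ecoli_prokaryote_chassis,
        PR.sigma70_ecoli_prokaryote_rnap,
    } <= types
    literals = {(p, o) for s, p, o in triples if isinstance(o, Literal)}
    assert (CORE.name, Literal("BBa_I746365")) in literals
    assert (CORE.status, Literal("Available")) in literals
    assert (CORE.id, Literal(9598)) in literals
    assert (CORE.dnaSequence, Literal(record.dna_sequence)) in literals


def test_part_without_categories_or_sequence():
    record = PartRecord(registry_id=5, name="BBa_Y5", dna_sequence="")
    triples = part_to_statements(record, build_tree([]))
    types = [o for _, p, o in triples if p == RDF.type]
    assert types == [CORE.Part]
    assert all(p != CORE.dnaSequence for _, p, _ in triples)


def test_materialization_adds_ancestor_types_monotonically(
    example_part_and_tree,
):
    record, tree = example_part_and_tree
    off = set(part_to_statements(record, tree, materialize=False))
    on = set(part_to_statements(record, tree, materialize=True))
    assert off < on
    subject = mint_uri("part", record.registry_id, record.name)
    assert (subject, RDF.type, PR.regulation) in on - off
    assert (subject, RDF.type, PR.rnap) in on - off


def test_unknown_category_strict_vs_lenient():
    record = PartRecord(
        registry_id=5, name="BBa_Y5", categories=("//mystery/depths",)
    )
    with pytest.raises(UnknownCategoryError, match="mystery"):
        part_to_statements(record, build_tree([]), strict=True)
    tree = build_tree([])
    with pytest.warns(UserWarning, match="auto-inserting"):
        triples = part_to_statements(record, tree, strict=False)
    assert parse_category("//mystery/depths") in tree
    subject = mint_uri("part", 5, "BBa_Y5")
    assert (subject, RDF.type, PR.depths_mystery) in triples


def test_feature_statements_build_annotation_chain():
    part = mint_uri("part", 9598, "BBa_I746365")
    feature = FeatureRecord(
        feature_id=1, part_registry_id=9598, label="OR1 lambda",
        feature_type="operator", start=5, end=16,
    )
    triples = feature_to_statements(feature, part, part_sequence_length=92)
    ann = mint_uri("annotation", 1, "OR1 lambda")
    feat = mint_uri("feature", 1, "OR1 lambda")
    assert (part, CORE.annotation, ann) in triples
    assert (ann, CORE.start, Literal(5)) in triples
    assert (ann, CORE.end, Literal(16)) in triples
    assert (ann, CORE.feature, feat) in triples
    assert (feat, CORE.name, Literal("OR1 lambda")) in triples
    assert (feat, RDF.type, PR.operator) in triples


def test_feature_past_sequence_end_warns_but_emits():
    part = mint_uri("part", 1, "BBa_Z1")
    feature = FeatureRecord(
        feature_id=2, part_registry_id=1, label="TetR", start=1, end=50
    )
    with pytest.warns(FeatureBoundsWarning):
        triples = feature_to_statements(feature, part, part_sequence_length=40)
    assert triples
    # spanning exactly the whole sequence is clean
    whole = FeatureRecord(
        feature_id=3, part_registry_id=1, label="TetR", start=1, end=40
    )
    import warnings as w

    with w.catch_warnings():
        w.simplefilter("error")
        feature_to_statements(whole, part, part_sequence_length=40)


def test_annotation_count_matches_feature_count():
    part = mint_uri("part", 1, "BBa_Z1")
    feats = [
        FeatureRecord(feature_id=i, part_registry_id=1, label=f"site{i}",
                      start=i, end=i + 3)
        for i in range(1, 6)
    ]
    triples = [
        t for f in feats for t in feature_to_statements(f, part)
    ]
    anns = {o for s, p, o in triples if p == CORE.annotation}
    feat_nodes = {o for s, p, o in triples if p == CORE.feature}
    assert len(anns) == len(feat_nodes) == 5


def test_build_is_additive_over_records(tmp_path):
    """Graph = class axioms ∪ per-record emissions, nothing lost or added."""
    fx = generate(FixtureConfig(n_parts=50, seed=2), tmp_path)
    parts, features, tree, kg = build_fixture_kg(fx)
    expected = set(class_axiom_statements(tree))
    uri = {
        p.registry_id: mint_uri("part", p.registry_id, p.name) for p in parts
    }
    for p in parts:
        expected |= set(part_to_statements(p, tree))
    for f in features:
        expected |= set(
            feature_to_statements(f, uri[f.part_registry_id])
        )
    assert kg.statements == expected
    part_subjects = set(kg.graph.subjects(RDF.type, CORE.Part))
    assert len(part_subjects) == len(parts)


def test_serialize_roundtrips_both_formats(tmp_path):
    fx = generate(FixtureConfig(n_parts=30, seed=5), tmp_path)
    kg = build_fixture_kg(fx)[3]
    for fmt, name in (("turtle", "g.ttl"), ("rdfxml", "g.rdf")):
        path = serialize(kg, fmt, tmp_path / name)
        assert parse_graph(path).statements == kg.statements
    with pytest.raises(ValueError, match="unknown format"):
        serialize(kg, "n3", tmp_path / "g.n3")


def test_turtle_output_is_byte_deterministic(tmp_path):
    """Two independent builds from the same tables serialize identically."""
    fx = generate(FixtureConfig(n_parts=30, seed=6), tmp_path / "a")
    kg1 = build_fixture_kg(fx)[3]
    kg2 = build_fixture_kg(fx)[3]
    p1 = serialize(kg1, "turtle", tmp_path / "one.ttl")
    p2 = serialize(kg2, "turtle", tmp_path / "two.ttl")
    assert p1.read_bytes() == p2.read_bytes()


def test_empty_inputs_yield_class_axioms_only(tmp_path):
    tree = build_tree([parse_category("//promoter")])
    kg = build_knowledgebase([], [], tree)
    assert kg.statements == set(class_axiom_statements(tree))
    empty = build_knowledgebase([], [], build_tree([]))
    path = serialize(empty, "turtle", tmp_path / "empty.ttl")
    assert parse_graph(path).statements == empty.statements
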